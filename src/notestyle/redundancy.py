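"""Six-metric redundancy/efficiency profile per note and per-group aggregates.

The metrics quantify repetition and lexical diversity biases in one note:

- ``n_sentences``: sentence count (text segmented by periods or line breaks).
- ``ttr``: type-token ratio, unique tokens / total tokens.
- ``inter_sentence_redundancy``: 1 - mean pairwise cosine distance between
  TF-IDF sentence vectors fitted within the note (equivalently, the mean
  pairwise cosine similarity); 0 when the note has fewer than two sentences.
- ``compression_ratio``: DEFLATE-compressed size / original size of the
  normalized UTF-8 text; repetitive text compresses further (lower ratio).
- ``unique_words_per_sentence``: mean per-sentence unique-token count.
- ``bigram_duplication``: 1 - unique adjacent bigrams / total bigrams
  (0 when the note has fewer than 2 tokens).

The sentence vectorizer is note-local (vocabulary and IDF from that note's
sentences only) and uses smoothed IDF with L2 normalization so that even a
term present in every sentence keeps a nonzero weight.  Compression ratios
depend on the compressor level (zlib level 6 by default) and should only be
compared at a fixed level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import GroupedCorpus, Note

__all__ = ["RedundancyProfile", "RedundancyProfiler",
           "redundancy_profile", "group_redundancy", "METRIC_ORDER"]

METRIC_ORDER = ("n_sentences", "ttr", "inter_sentence_redundancy",
                "compression_ratio", "unique_words_per_sentence",
                "bigram_duplication")


@dataclass(frozen=True)
class RedundancyProfile:
    n_sentences: int
    ttr: float
    inter_sentence_redundancy: float
    compression_ratio: float
    unique_words_per_sentence: float
    bigram_duplication: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_ORDER}


def _inter_sentence_similarity(sentences) -> float:
    if len(sentences) < 2:
        return 0.0
    vec = TfidfVectorizer(analyzer=lambda s: s, lowercase=False,
                          smooth_idf=True, norm="l2")
    mat = vec.fit_transform(list(sentences)).toarray()
    sims = mat @ mat.T
    iu = np.triu_indices(len(sentences), k=1)
    return float(sims[iu].mean())


def redundancy_profile(note: Note, compressor_level: int = 6,
                       unique_words_mode: str = "per_sentence") -> RedundancyProfile:
    """Compute the six redundancy metrics for one note.

    ``unique_words_mode='per_sentence'`` averages each sentence's own unique
    token count; ``'whole_note'`` divides the note-level unique token count by
    the number of sentences.
    """
    if len(note.tokens) == 0:
        raise ValueError(f"note {note.note_id!r} has no tokens")
    if unique_words_mode not in ("per_sentence", "whole_note"):
        raise ValueError(f"unknown unique_words_mode {unique_words_mode!r}")
    tokens = note.tokens
    ttr = len(set(tokens)) / len(tokens)
    bigrams = list(zip(tokens, tokens[1:]))
    dup = 0.0 if len(bigrams) == 0 else 1.0 - len(set(bigrams)) / len(bigrams)
    n_sent = len(note.sentences)
    if unique_words_mode == "per_sentence":
        uws = (float(np.mean([len(set(s)) for s in note.sentences]))
               if n_sent else 0.0)
    else:
        uws = len(set(tokens)) / n_sent if n_sent else 0.0
    raw = note.norm_text.encode("utf-8")
    ratio = len(zlib.compress(raw, level=compressor_level)) / len(raw)
    return RedundancyProfile(
        n_sentences=n_sent,
        ttr=ttr,
        inter_sentence_redundancy=_inter_sentence_similarity(note.sentences),
        compression_ratio=ratio,
        unique_words_per_sentence=uws,
        bigram_duplication=dup,
    )


class RedundancyProfiler(BaseEstimator):
    """Transformer: corpus -> one-row-per-note DataFrame of the six metrics."""

    def __init__(self, compressor_level: int = 6,
                 unique_words_mode: str = "per_sentence"):
        self.compressor_level = compressor_level
        self.unique_words_mode = unique_words_mode

    def fit(self, corpus: GroupedCorpus, y=None) -> "RedundancyProfiler":
        return self  # stateless; provided for pipeline compatibility

    def transform(self, corpus: GroupedCorpus) -> pd.DataFrame:
        rows = []
        for note in corpus.notes:
            prof = redundancy_profile(note, self.compressor_level,
                                      self.unique_words_mode)
            rows.append({"note_id": note.note_id,
                         "group": corpus.group_key(note), **prof.as_dict()})
        return pd.DataFrame(rows).set_index("note_id")

    def fit_transform(self, corpus: GroupedCorpus, y=None) -> pd.DataFrame:
        return self.fit(corpus).transform(corpus)


def group_redundancy(corpus: GroupedCorpus, compressor_level: int = 6,
                     unique_words_mode: str = "per_sentence") -> pd.DataFrame:
    """Per-group mean, SD (ddof=1; 0 for singleton groups) and median of each
    metric, metrics in fixed order."""
    table = RedundancyProfiler(compressor_level, unique_words_mode).fit_transform(corpus)
    rows = []
    for g in corpus.group_labels:
        sub = table[table["group"] == g][list(METRIC_ORDER)]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        for m in METRIC_ORDER:
            vals = sub[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append({"group": g, "metric": m,
                         "mean": float(vals.mean()), "sd": sd,
                         "median": float(np.median(vals)), "n": len(vals)})
    return pd.DataFrame(rows)
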