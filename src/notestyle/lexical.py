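"""Shared-vocabulary TF-IDF over the whole corpus and per-group keyword profiles.

One vectorizer is fitted on the concatenation of all groups so vocabulary and
IDF weights are shared; group profiles are per-term means of the member
documents' TF-IDF scores, ranked to give each group's distinctive vocabulary.

Two weighting variants are provided.  ``paper_formula`` (default) is the plain
textbook weight TF(t,d) * log(N / DF(t)) with raw counts, no smoothing and no
vector normalization — a term present in every document scores exactly 0.
``smoothed_library`` is the scikit-learn default (smoothed IDF, L2-normalized
rows) for comparability with analyses run through TfidfVectorizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

from .corpus import GroupedCorpus, Note

__all__ = ["TokenFilter", "GroupTfidfProfiler", "GroupTermProfile",
           "fit_tfidf", "group_profile"]


@dataclass(frozen=True)
class TokenFilter:
    """Rule-based token preprocessing applied before vectorization.

    ``merge_expressions`` are multiword expressions (token tuples) replaced by
    a single underscore-joined token, longest expression first at each
    position; ``stoplist`` tokens are dropped afterwards.  Default: no merging,
    empty stoplist.
    """

    merge_expressions: tuple[tuple[str, ...], ...] = ()
    stoplist: frozenset[str] = field(default_factory=frozenset)

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        toks = list(tokens)
        if self.merge_expressions:
            exprs = sorted(self.merge_expressions, key=len, reverse=True)
            out: list[str] = []
            i = 0
            while i < len(toks):
                for expr in exprs:
                    k = len(expr)
                    if k and tuple(toks[i:i + k]) == expr:
                        out.append("_".join(expr))
                        i += k
                        break
                else:
                    out.append(toks[i])
                    i += 1
            toks = out
        if self.stoplist:
            toks = [t for t in toks if t not in self.stoplist]
        return toks


@dataclass
class GroupTermProfile:
    """Mean TF-IDF per term for one group plus the top-k ranking
    (descending score, ties broken lexicographically)."""

    group: str
    scores: dict[str, float]
    top_k: list[tuple[str, float]]


class GroupTfidfProfiler(BaseEstimator):
    """Corpus-level TF-IDF model with per-group mean-score profiles.

    Parameters
    ----------
    variant : {"paper_formula", "smoothed_library"}
        Weighting scheme (see module docstring).
    log_base : float or None
        Logarithm base for the paper_formula IDF; None means natural log.
    token_filter : TokenFilter
        Multiword merging + stoplist applied to every document.

    Fitted attributes: ``vocabulary_`` (term -> column), ``doc_freq_``,
    ``n_docs_``, ``idf_``, ``terms_``.
    """

    def __init__(self, variant: str = "paper_formula",
                 log_base: float | None = None,
                 token_filter: TokenFilter = TokenFilter()):
        self.variant = variant
        self.log_base = log_base
        self.token_filter = token_filter

    def _docs(self, corpus: GroupedCorpus) -> list[list[str]]:
        return [self.token_filter(n.tokens) for n in corpus.notes]

    def fit(self, corpus: GroupedCorpus, y=None) -> "GroupTfidfProfiler":
        if self.variant not in ("paper_formula", "smoothed_library"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if len(corpus) == 0:
            raise ValueError("cannot fit TF-IDF on an empty corpus")
        docs = self._docs(corpus)
        self._vectorizer_ = CountVectorizer(
            analyzer=lambda d: d, lowercase=False)
        counts = self._vectorizer_.fit_transform(docs)
        if counts.shape[1] == 0:
            raise ValueError("empty vocabulary after token filtering")
        self.vocabulary_ = dict(self._vectorizer_.vocabulary_)
        self.terms_ = np.asarray(self._vectorizer_.get_feature_names_out())
        self.n_docs_ = counts.shape[0]
        df = np.asarray((counts > 0).sum(axis=0)).ravel()
        self.doc_freq_ = {t: int(df[i]) for t, i in self.vocabulary_.items()}
        if self.variant == "paper_formula":
            idf = np.log(self.n_docs_ / df)
            if self.log_base is not None:
                idf = idf / math.log(self.log_base)
            self.idf_ = idf
        else:
            self._transformer_ = TfidfTransformer(smooth_idf=True, norm="l2")
            self._transformer_.fit(counts)
            self.idf_ = self._transformer_.idf_
        return self

    def transform(self, corpus: GroupedCorpus) -> np.ndarray:
        """Dense (n_notes, n_terms) TF-IDF matrix under the fitted model."""
        self._check_fitted()
        counts = self._vectorizer_.transform(self._docs(corpus))
        if self.variant == "paper_formula":
            return counts.toarray() * self.idf_
        return self._transformer_.transform(counts).toarray()

    def _check_fitted(self) -> None:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("GroupTfidfProfiler is not fitted")

    def group_profile(self, corpus: GroupedCorpus, group: str,
                      k: int = 10) -> GroupTermProfile:
        """Per-term mean TF-IDF over the group's documents, with top-k ranking."""
        self._check_fitted()
        members = corpus.group(group)  # KeyError for unknown group
        idx = [i for i, n in enumerate(corpus.notes)
               if corpus.group_key(n) == group]
        assert len(idx) == len(members)
        sub = GroupedCorpus([corpus.notes[i] for i in idx],
                            group_key=corpus.group_key)
        mat = self.transform(sub)
        means = mat.mean(axis=0)
        scores = {t: float(means[j]) for t, j in self.vocabulary_.items()}
        order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return GroupTermProfile(group=group, scores=scores,
                                top_k=order[:min(k, len(order))])

    def profiles(self, corpus: GroupedCorpus, k: int = 10) -> dict[str, GroupTermProfile]:
        return {g: self.group_profile(corpus, g, k) for g in corpus.group_labels}


def fit_tfidf(corpus: GroupedCorpus, variant: str = "paper_formula",
              token_filter: TokenFilter = TokenFilter(),
              log_base: float | None = None) -> GroupTfidfProfiler:
    """Fit one shared-vocabulary TF-IDF model over the combined corpus."""
    return GroupTfidfProfiler(variant=variant, log_base=log_base,
                              token_filter=token_filter).fit(corpus)


def group_profile(model: GroupTfidfProfiler, corpus: GroupedCorpus,
                  group: str, k: int = 10) -> GroupTermProfile:
    return model.group_profile(corpus, group, k)
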