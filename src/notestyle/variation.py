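"""Medical-term surface-form variation: dictionary matching and lexical entropy.

A variant dictionary maps a clinical concept (e.g. "depressive state") to the
surface forms judged semantically equivalent to it.  Occurrences of each form
are counted in a group's normalized note texts by exact substring matching
with longest-form priority at each position (so "depressive state" is not
double-counted as "depressive"), and the diversity of expression is quantified
as the Shannon entropy H = -sum_i p_i log2 p_i of the form frequencies, in
bits: 0 when one form carries all mass, log2(n) for n equally frequent forms.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import DEFAULT_PUNCTUATION, GroupedCorpus, normalize_text

__all__ = ["VariantDictionary", "VariantDistribution", "extract_variants",
           "lexical_entropy", "group_entropy_table"]


@dataclass
class VariantDictionary:
    """concept -> ordered unique surface forms (no empty strings)."""

    concepts: dict[str, list[str]]

    def __post_init__(self) -> None:
        for concept, forms in self.concepts.items():
            if len(set(forms)) != len(forms):
                raise ValueError(f"duplicate surface forms for concept {concept!r}")
            if any(not f for f in forms):
                raise ValueError(f"empty surface form for concept {concept!r}")

    def __contains__(self, concept: str) -> bool:
        return concept in self.concepts

    def forms(self, concept: str) -> list[str]:
        if concept not in self.concepts:
            raise KeyError(
                f"unknown concept {concept!r}; available: {sorted(self.concepts)}")
        return list(self.concepts[concept])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantDictionary":
        """Two-column TSV: concept <tab> surface_form, one form per row."""
        concepts: dict[str, list[str]] = {}
        with Path(path).open(encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) != 2:
                    raise ValueError(f"expected 2 columns, got {row!r}")
                concepts.setdefault(row[0], []).append(row[1])
        return cls(concepts)

    @classmethod
    def from_json(cls, path: str | Path) -> "VariantDictionary":
        """JSON object {concept: [surface forms]}."""
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.concepts, ensure_ascii=False, indent=2),
            encoding="utf-8")


@dataclass
class VariantDistribution:
    """Per-group frequency table of one concept's surface forms."""

    concept: str
    group: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def probs(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {f: 0.0 for f in self.counts}
        return {f: c / total for f, c in self.counts.items()}


def _count_forms(text: str, forms: list[str]) -> dict[str, int]:
    """Exact substring counts with longest-form priority at each position;
    after a match the scan advances past the matched form."""
    ordered = sorted(forms, key=len, reverse=True)
    counts = {f: 0 for f in forms}
    i, n = 0, len(text)
    while i < n:
        for f in ordered:
            if text.startswith(f, i):
                counts[f] += 1
                i += len(f)
                break
        else:
            i += 1
    return counts


def extract_variants(corpus: GroupedCorpus, dictionary: VariantDictionary,
                     concept: str, group: str, unit: str = "occurrences",
                     punctuation_set=DEFAULT_PUNCTUATION) -> VariantDistribution:
    """Count each surface form of ``concept`` in the group's normalized texts.

    ``unit='occurrences'`` (default) counts every match; ``unit='notes'``
    counts note-level presence.  Forms are normalized with the same rules as
    the note text before matching.
    """
    if unit not in ("occurrences", "notes"):
        raise ValueError(f"unknown unit {unit!r}")
    raw_forms = dictionary.forms(concept)  # KeyError for unknown concept
    norm_forms = {f: normalize_text(f, punctuation_set) for f in raw_forms}
    notes = corpus.group(group)
    totals = {f: 0 for f in raw_forms}
    for note in notes:
        per_note = _count_forms(note.norm_text, list(norm_forms.values()))
        for f in raw_forms:
            c = per_note[norm_forms[f]]
            totals[f] += (1 if c > 0 else 0) if unit == "notes" else c
    return VariantDistribution(concept=concept, group=group, counts=totals)


def lexical_entropy(dist: VariantDistribution) -> float:
    """Shannon entropy of the form distribution, in bits (0 log 0 := 0)."""
    total = dist.total
    if total == 0:
        raise ValueError(
            f"no occurrence of concept {dist.concept!r} in group {dist.group!r}: "
            "entropy undefined")
    p = np.array([c for c in dist.counts.values() if c > 0], dtype=float) / total
    return float(-(p * np.log2(p)).sum())


def group_entropy_table(corpus: GroupedCorpus, dictionary: VariantDictionary,
                        concept: str, unit: str = "occurrences") -> pd.DataFrame:
    """Per-group counts and entropy for one concept.  Groups where no form
    occurs get NaN entropy rather than an error."""
    rows = []
    for g in corpus.group_labels:
        dist = extract_variants(corpus, dictionary, concept, g, unit=unit)
        h = lexical_entropy(dist) if dist.total > 0 else float("nan")
        rows.append({"concept": concept, "group": g, "total": dist.total,
                     "n_forms_observed": sum(c > 0 for c in dist.counts.values()),
                     "entropy_bits": h})
    return pd.DataFrame(rows)
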