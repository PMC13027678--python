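"""Descriptive statistics, classical tests, effect sizes, FDR correction and
the bootstrap downsampling sensitivity analysis.

The sensitivity analysis addresses the severe group-size imbalance between
physician-authored and LLM-generated notes: the large reference group is
repeatedly downsampled (without replacement, by default) to the small group's
size, a statistic (mean by default) is computed per resample, and the small
group's observed value is flagged when it falls outside the empirical 95%
range of the resampled distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .corpus import GroupedCorpus

__all__ = [
    "TestResult", "BootstrapSensitivity", "describe_lengths",
    "anova_oneway", "welch_t", "mann_whitney_u", "cliff_delta", "bh_fdr",
    "bootstrap_downsample", "length_test_table",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    dof: float | tuple[float, float] | None = None
    effect_size: float | None = None
    effect_name: str | None = None


@dataclass(frozen=True)
class BootstrapSensitivity:
    metric_name: str
    n_target: int
    n_replicates: int
    lower95: float
    upper95: float
    observed: float
    outside: bool
    seed: int
    statistic: str = "mean"


def note_length(note, unit: str = "tokens") -> int:
    if unit == "tokens":
        return note.n_tokens
    if unit == "characters":
        return note.n_chars
    raise ValueError(f"unknown length unit {unit!r}")


def describe_lengths(corpus: GroupedCorpus, unit: str = "tokens") -> pd.DataFrame:
    """Per-group mean, median and sample variance (ddof=1) of note length."""
    rows = []
    for g, notes in corpus.groups().items():
        lens = np.array([note_length(n, unit) for n in notes], dtype=float)
        rows.append({
            "group": g, "unit": unit, "n": len(lens),
            "mean": float(lens.mean()),
            "median": float(np.median(lens)),
            "variance": float(lens.var(ddof=1)) if len(lens) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def _check_nonempty(*samples) -> list[np.ndarray]:
    out = []
    for s in samples:
        arr = np.asarray(list(s), dtype=float)
        if arr.size == 0:
            raise ValueError("samples must be non-empty")
        out.append(arr)
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across two or more groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrs = _check_nonempty(*groups)
    pooled = np.concatenate(arrs)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("degenerate input: all pooled values identical")
    f, p = sps.f_oneway(*arrs)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    return TestResult("anova_oneway", float(f), float(p), dof=(k - 1, n - k))


def welch_t(a: Sequence[float], b: Sequence[float], pooled: bool = False) -> TestResult:
    """Two-sided two-sample t test; Welch (unequal variance) by default,
    pooled-variance variant behind ``pooled=True``."""
    x, y = _check_nonempty(a, b)
    both = np.concatenate([x, y])
    if np.allclose(both, both[0]):
        raise ValueError("degenerate input: all pooled values identical")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult("student_t" if pooled else "welch_t",
                      float(res.statistic), float(res.pvalue),
                      dof=float(res.df))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when min(n, m) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    x, y = _check_nonempty(a, b)
    no_ties = len(set(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(f"mann_whitney_u[{method}]",
                      float(res.statistic), float(min(res.pvalue, 1.0)),
                      effect_size=cliff_delta(x, y), effect_name="cliff_delta")


def cliff_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """Cliff delta effect size by direct pair counting:
    (#{x > y} - #{x < y}) / (n * m), in [-1, 1]; positive when ``a`` tends to
    exceed ``b``."""
    x, y = _check_nonempty(a, b)
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).mean())


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_downsample(
    reference_values: Sequence[float],
    observed: float,
    n_target: int,
    B: int = 1000,
    seed: int = 0,
    statistic: str = "mean",
    replace: bool = False,
    metric_name: str = "metric",
) -> BootstrapSensitivity:
    """Downsampling sensitivity: is ``observed`` inside the 95% range of the
    statistic over ``B`` size-``n_target`` resamples of the reference sample?

    Resampling is without replacement by default (true downsampling); set
    ``replace=True`` for a conventional bootstrap.  Bit-reproducible under a
    fixed seed.
    """
    ref = np.asarray(list(reference_values), dtype=float)
    if not 1 <= n_target <= ref.size:
        raise ValueError(
            f"n_target must be in [1, {ref.size}], got {n_target}")
    if B < 100:
        raise ValueError("B must be >= 100 for a stable 95% range")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    if replace:
        samples = rng.choice(ref, size=(B, n_target), replace=True)
    else:
        # B independent subsamples without replacement, vectorised:
        # per replicate take the first n_target entries of a random permutation.
        keys = rng.random((B, ref.size))
        idx = np.argsort(keys, axis=1)[:, :n_target]
        samples = ref[idx]
    stat = np.mean(samples, axis=1) if statistic == "mean" else np.median(samples, axis=1)
    lower, upper = np.percentile(stat, [2.5, 97.5])
    outside = bool(observed < lower or observed > upper)
    return BootstrapSensitivity(
        metric_name=metric_name, n_target=n_target, n_replicates=B,
        lower95=float(lower), upper95=float(upper),
        observed=float(observed), outside=outside, seed=seed,
        statistic=statistic)


def length_test_table(corpus: GroupedCorpus, unit: str = "tokens") -> pd.DataFrame:
    """Omnibus ANOVA plus all pairwise Mann-Whitney comparisons of note length
    with Cliff delta and BH-adjusted p-values."""
    groups = corpus.groups()
    if len(groups) < 2:
        raise ValueError("length tests require at least two groups")
    lens = {g: [note_length(n, unit) for n in notes] for g, notes in groups.items()}
    rows = []
    an = anova_oneway(list(lens.values()))
    rows.append({"test": an.test_name, "groups": "all", "statistic": an.statistic,
                 "dof": str(an.dof), "p": an.p_value,
                 "effect_size": np.nan, "effect_name": ""})
    pairwise = []
    for ga, gb in combinations(lens, 2):
        mw = mann_whitney_u(lens[ga], lens[gb])
        pairwise.append({"test": mw.test_name, "groups": f"{ga} vs {gb}",
                         "statistic": mw.statistic, "dof": "", "p": mw.p_value,
                         "effect_size": mw.effect_size,
                         "effect_name": mw.effect_name})
    adj = bh_fdr([r["p"] for r in pairwise])
    for r, q in zip(pairwise, adj):
        r["p_adjusted"] = float(q)
    rows[0]["p_adjusted"] = np.nan
    return pd.DataFrame(rows + pairwise)
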