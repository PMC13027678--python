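"""Statistical layer: descriptives, classical tests, Cliff delta, BH FDR and
the bootstrap downsampling sensitivity analysis."""

import itertools
import math

import numpy as np
import pytest

from notestyle import (
    anova_oneway,
    bh_fdr,
    bootstrap_downsample,
    cliff_delta,
    describe_lengths,
    length_test_table,
    mann_whitney_u,
    welch_t,
)

from conftest import corpus_of


def exact_mwu_two_sided_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p by enumerating all
    C(n+m, n) assignments of the pooled values to the two samples."""
    pooled = list(a) + list(b)
    n = len(a)
    nm = len(a) * len(b)

    def u_stat(sample_a, sample_b):
        return sum((x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b)

    u_obs = u_stat(a, b)
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        sel = set(idx)
        xa = [pooled[i] for i in sel]
        xb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = u_stat(xa, xb)
        total += 1
        if u <= lo + 1e-12 or u >= hi - 1e-12:
            count += 1
    return min(count / total, 1.0)


def cliff_delta_loop_oracle(a, b):
    gt = sum(x > y for x in a for y in b)
    lt = sum(x < y for x in a for y in b)
    return (gt - lt) / (len(a) * len(b))


class TestDescribeLengths:
    def test_hand_counted_statistics(self):
        c = corpus_of([["a", "b"], ["a", "b", "c", "d"],
                       ["a", "b", "c", "d", "e", "f"]])
        df = describe_lengths(c).set_index("group")
        row = df.loc["psychiatry_human"]
        assert row["mean"] == 4.0
        assert row["median"] == 4.0
        assert row["variance"] == 4.0  # sample variance of {2,4,6}

    def test_identical_notes_zero_variance(self):
        c = corpus_of([["a", "b"]] * 3)
        assert describe_lengths(c)["variance"].iloc[0] == 0.0

    def test_character_unit(self):
        c = corpus_of([["ab", "c"]])  # norm_text "ab c" -> 4 characters
        df = describe_lengths(c, unit="characters")
        assert df["mean"].iloc[0] == 4.0


class TestClassicalTests:
    def test_anova_equal_means_f_near_zero(self):
        a = [1.0, 2.0, 3.0]
        res = anova_oneway([a, a, a])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_anova_degenerate_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])

    def test_welch_t_separated_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01 and res.statistic < 0

    def test_pooled_variant_dof(self):
        # pooled t on n=4 vs n=4 gives df = 6 exactly
        res = welch_t([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 6.0], pooled=True)
        assert res.dof == pytest.approx(6.0)
        assert res.test_name == "student_t"

    def test_mwu_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_mwu_exact_matches_enumeration_for_separated_case(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney_u(a, b)
        assert "exact" in res.test_name
        assert res.p_value == pytest.approx(exact_mwu_two_sided_p(a, b))
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank assignments

    def test_mwu_exact_matches_enumeration_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(2, 9 - n))
            vals = rng.permutation(20)[: n + m].astype(float)  # distinct, no ties
            a, b = list(vals[:n]), list(vals[n:])
            res = mann_whitney_u(a, b)
            assert res.p_value == pytest.approx(exact_mwu_two_sided_p(a, b))

    def test_mwu_ties_use_corrected_normal_approximation(self):
        res = mann_whitney_u([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
        assert "asymptotic" in res.test_name
        assert 0.0 <= res.p_value <= 1.0


class TestCliffDelta:
    @pytest.mark.parametrize("a,b,expected", [
        ([5.0, 6.0], [1.0, 2.0], 1.0),     # complete separation
        ([1.0, 2.0], [1.0, 2.0], 0.0),     # identical samples
        ([1.0, 3.0], [2.0, 2.0], 0.0),     # hand pair count: 2 gt, 2 lt
    ])
    def test_examples(self, a, b, expected):
        assert cliff_delta(a, b) == pytest.approx(expected)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = list(rng.normal(0, 1, rng.integers(2, 10)))
            b = list(rng.normal(0.5, 1, rng.integers(2, 10)))
            assert cliff_delta(a, b) == pytest.approx(cliff_delta_loop_oracle(a, b))

    def test_antisymmetry(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 0.0]
        assert cliff_delta(a, b) == pytest.approx(-cliff_delta(b, a))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_stay_equal(self):
        out = bh_fdr([0.03, 0.03, 0.03])
        assert np.allclose(out, 0.03)

    def test_hand_applied_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_order_equivariant_and_monotone(self):
        p = [0.3, 0.01, 0.2, 0.04]
        once = bh_fdr(p)
        perm = [2, 0, 3, 1]
        permuted = bh_fdr([p[i] for i in perm])
        assert np.allclose(permuted, [once[i] for i in perm])
        # step-up output is monotone nondecreasing in the sorted order
        order = np.argsort(p)
        assert (np.diff(np.asarray(once)[order]) >= -1e-12).all()
        assert (once <= 1.0).all() and (once >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestBootstrapDownsample:
    def test_constant_sample_observed_inside(self):
        res = bootstrap_downsample([5.0] * 10, observed=5.0, n_target=4,
                                   B=200, seed=0)
        assert not res.outside
        assert res.lower95 == res.upper95 == 5.0

    def test_far_observed_outside(self):
        res = bootstrap_downsample(list(range(10)), observed=1e6, n_target=4,
                                   B=200, seed=0)
        assert res.outside

    def test_bit_reproducible(self):
        ref = list(np.random.default_rng(3).normal(0, 1, 30))
        r1 = bootstrap_downsample(ref, 0.1, 4, B=500, seed=42)
        r2 = bootstrap_downsample(ref, 0.1, 4, B=500, seed=42)
        assert (r1.lower95, r1.upper95) == (r2.lower95, r2.upper95)

    def test_with_replacement_mode(self):
        ref = list(np.random.default_rng(4).normal(0, 1, 30))
        res = bootstrap_downsample(ref, 0.0, 4, B=500, seed=1, replace=True)
        assert res.lower95 < res.upper95

    def test_median_statistic(self):
        ref = list(range(20))
        res = bootstrap_downsample(ref, 9.5, 5, B=300, seed=0,
                                   statistic="median")
        assert res.statistic == "median" and not res.outside

    def test_validation(self):
        with pytest.raises(ValueError):
            bootstrap_downsample([1.0, 2.0], 1.0, n_target=3, B=200, seed=0)
        with pytest.raises(ValueError):
            bootstrap_downsample([1.0, 2.0], 1.0, n_target=1, B=50, seed=0)


def test_length_test_table_structure(study_corpus):
    df = length_test_table(study_corpus)
    assert df["test"].iloc[0] == "anova_oneway"
    pairwise = df[df["test"] != "anova_oneway"]
    assert len(pairwise) == 6  # 4 choose 2 group pairs
    assert (pairwise["p_adjusted"] >= pairwise["p"] - 1e-12).all()
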