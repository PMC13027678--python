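"""Pairwise metrics: TER/edit ops, BLEU, ROUGE-L, embedding F1, matrices,
Ward clustering and group edit summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from notestyle import (
    GroupedCorpus,
    HashEmbeddingBackend,
    WardClusterer,
    bleu,
    edit_ops,
    embed_similarity,
    group_edit_summary,
    pairwise_matrix,
    rouge_l,
    ter,
    ward_cluster,
)
from notestyle.similarity import FixedEmbeddingBackend

from conftest import corpus_of, note_of


def brute_force_edit_distance(a, b):
    """Independent plain-python Levenshtein DP (no numpy, no backtrace)."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (x != y)))
        prev = cur
    return prev[len(b)]


token_seq = st.lists(st.sampled_from(["a", "b", "c", "d"]), min_size=0, max_size=8)


class TestEditOps:
    def test_identity(self):
        score, ops = ter(["a", "b", "c"], ["a", "b", "c"])
        assert score == 0
        assert (ops.insertions, ops.deletions, ops.substitutions) == (0, 0, 0)

    def test_extra_hypothesis_token_is_deletion(self):
        score, ops = ter(["a", "b", "c", "d"], ["a", "b", "c"])
        assert score == pytest.approx(1 / 3)
        assert (ops.insertions, ops.deletions, ops.substitutions) == (0, 1, 0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ter(["a"], [])

    def test_score_can_exceed_one(self):
        score, _ = ter(list("abcdefgh"), ["x"])
        assert score > 1

    def test_oracle_equivalence_random_pairs(self):
        """Total edits equal an independently coded DP distance on 200 pairs."""
        rng = np.random.default_rng(42)
        alphabet = ["a", "b", "c", "d"]
        for _ in range(200):
            hyp = [alphabet[k] for k in rng.integers(0, 4, rng.integers(0, 9))]
            ref = [alphabet[k] for k in rng.integers(0, 4, rng.integers(1, 9))]
            ops = edit_ops(hyp, ref)
            assert ops.total == brute_force_edit_distance(hyp, ref)
            assert ops.insertions - ops.deletions == len(ref) - len(hyp)

    def test_agrees_with_edlib(self):
        """Cross-check distances against the edlib C library on random pairs."""
        import edlib

        rng = np.random.default_rng(7)
        letters = "abcdefgh"
        for _ in range(100):
            x = "".join(letters[k] for k in rng.integers(0, 8, rng.integers(1, 30)))
            y = "".join(letters[k] for k in rng.integers(0, 8, rng.integers(1, 30)))
            assert edit_ops(list(x), list(y)).total == \
                edlib.align(x, y, task="distance")["editDistance"]

    @given(token_seq, token_seq)
    @settings(derandomize=True, max_examples=150)
    def test_balance_invariant(self, hyp, ref):
        ops = edit_ops(hyp, ref)
        assert ops.insertions - ops.deletions == len(ref) - len(hyp)
        assert ops.total >= abs(len(ref) - len(hyp))
        rev = ops.reversed()
        assert (rev.insertions, rev.deletions) == (ops.deletions, ops.insertions)


class TestBleu:
    def test_identical_is_one(self):
        assert bleu(list("abcdef"), list("abcdef")) == pytest.approx(1.0)

    def test_disjoint_is_zero_without_smoothing(self):
        assert bleu(["a", "b"], ["c", "d"], smoothing="none") == 0.0

    def test_hand_computed_value(self):
        # p1 = 2/3, p2 = 1/2, BP = 1 -> sqrt(1/3)
        got = bleu(["a", "b", "c"], ["a", "b", "d"], max_n=2, smoothing="none")
        assert got == pytest.approx(math.sqrt(1 / 3))

    def test_brevity_penalty(self):
        # hyp is a 2-token prefix of a 4-token ref: p1=1, p2=1, BP=exp(1-2)
        got = bleu(["a", "b"], ["a", "b", "c", "d"], max_n=2, smoothing="none")
        assert got == pytest.approx(math.exp(-1.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bleu([], ["a"])


class TestRougeL:
    def test_identical_is_one(self):
        assert rouge_l(["a", "b"], ["a", "b"]) == 1.0

    def test_disjoint_is_zero(self):
        assert rouge_l(["a"], ["b"]) == 0.0

    def test_hand_computed_f1(self):
        # LCS=2, precision 1.0, recall 2/3 -> F1 = 0.8
        assert rouge_l(["a", "b", "c"], ["a", "c"]) == pytest.approx(0.8)

    def test_recall_weighting(self):
        # beta -> large weights recall: value approaches recall = 2/3
        assert rouge_l(["a", "b", "c"], ["a", "c"], beta=10.0) == \
            pytest.approx(2 / 3, abs=0.01)


class TestEmbedSimilarity:
    def test_self_similarity(self):
        backend = HashEmbeddingBackend(dim=32)
        note = note_of(["x", "y", "z"])
        assert embed_similarity(note, note, backend) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        backend = FixedEmbeddingBackend({"a": [1, 0], "b": [0, 1]})
        assert embed_similarity(["a"], ["b"], backend) == pytest.approx(0.0)

    def test_hand_traced_greedy_matching(self):
        # a=[u,v,v], b=[u,w]; cos(u,w)=0, cos(v,w)=1 (w==v direction)
        # recall: u->u (1), v->w (1), v->w (1) -> 1.0
        # precision: u->u (1), w->v (1) -> 1.0  => F1 = 1.0
        backend = FixedEmbeddingBackend({"u": [1, 0], "v": [0, 1], "w": [0, 2]})
        assert embed_similarity(["u", "v", "v"], ["u", "w"], backend) == \
            pytest.approx(1.0)
        # a=[u,v] vs b=[u]: recall over b? precision = 1 matches of b tokens
        # P (hyp=b side) = 1.0, R = mean(1, 0) = 0.5 -> F1 = 2/3
        got = embed_similarity(["u", "v"], ["u"],
                               FixedEmbeddingBackend({"u": [1, 0], "v": [0, 1]}))
        assert got == pytest.approx(2 / 3)

    def test_backend_failure_propagates_identity(self):
        backend = FixedEmbeddingBackend({}, name="empty-backend")
        with pytest.raises(RuntimeError, match="empty-backend"):
            embed_similarity(["a"], ["b"], backend)


class TestPairwiseMatrix:
    def test_identical_notes_have_zero_ter(self):
        c = corpus_of([["a", "b"], ["a", "b"]])
        mat = pairwise_matrix(c, "ter")
        assert mat.values[0, 1] == 0.0
        assert mat.polarity == "distance"

    def test_symmetry_and_diagonal(self, study_corpus):
        small = GroupedCorpus(study_corpus.notes[:6])
        for metric in ("ter", "bleu", "rouge_l"):
            mat = pairwise_matrix(small, metric)
            assert np.allclose(mat.values, mat.values.T)
            expected_diag = 0.0 if metric == "ter" else 1.0
            assert np.allclose(np.diag(mat.values), expected_diag)

    def test_hand_computed_disjoint_vocab_ter(self):
        # lengths 2, 4, 8 with disjoint vocabularies: D = max(len)
        c = corpus_of([["a", "b"], ["c", "d", "e", "f"],
                       ["g", "h", "i", "j", "k", "l", "m", "n"]])
        mat = pairwise_matrix(c, "ter")
        lens = [2, 4, 8]
        for i, j in itertools.combinations(range(3), 2):
            d = max(lens[i], lens[j])
            expected = 0.5 * (d / lens[i] + d / lens[j])
            assert mat.values[i, j] == pytest.approx(expected)

    def test_embed_requires_backend(self):
        c = corpus_of([["a"], ["b"]])
        with pytest.raises(ValueError, match="backend"):
            pairwise_matrix(c, "embed_f1")

    def test_offending_pair_reported(self):
        c = corpus_of([["a"], ["b"], []])
        with pytest.raises(ValueError, match="n2"):
            pairwise_matrix(c, "ter")


class TestWardClustering:
    def test_two_separated_pairs(self):
        c = corpus_of([["a", "b"], ["a", "b"], ["x", "y", "z"], ["x", "y", "z"]])
        mat = pairwise_matrix(c, "ter")
        _, labels = ward_cluster(mat, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_duplicates_form_single_cluster(self):
        c = corpus_of([["a", "b"]] * 4)
        mat = pairwise_matrix(c, "ter")
        _, labels = ward_cluster(mat, 2)
        assert len(set(labels)) == 1

    def test_permutation_invariance(self, study_corpus):
        rng = np.random.default_rng(0)
        notes = study_corpus.notes[:30]
        perm = rng.permutation(len(notes))
        c1 = GroupedCorpus(list(notes))
        c2 = GroupedCorpus([notes[i] for i in perm])
        l1 = ward_cluster(pairwise_matrix(c1, "ter"), 3)[1]
        l2 = ward_cluster(pairwise_matrix(c2, "ter"), 3)[1]
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            WardClusterer(2).fit(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            WardClusterer(2).fit(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_similarity_polarity_converted(self):
        c = corpus_of([["a", "b", "c"], ["a", "b", "c"], ["x", "y"], ["x", "y"]])
        mat = pairwise_matrix(c, "rouge_l")
        _, labels = ward_cluster(mat, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_exports(self):
        c = corpus_of([["a", "b"], ["a", "c"], ["x", "y"]])
        clusterer, _ = ward_cluster(pairwise_matrix(c, "ter"), 2)
        newick = clusterer.to_newick()
        assert newick.endswith(";") and "n0" in newick
        d = clusterer.to_dict()
        assert "children" in d and d["height"] >= 0

    def test_get_set_params(self):
        cl = WardClusterer(4)
        assert cl.get_params() == {"n_clusters": 4}
        cl.set_params(n_clusters=2)
        assert cl.n_clusters == 2


class TestGroupEditSummary:
    def test_identical_within_group_is_zero(self):
        c = corpus_of([["a", "b"]] * 3)
        s = group_edit_summary(c, ("psychiatry_human", "psychiatry_human"))
        assert (s.mean_rel_insertions, s.mean_rel_deletions,
                s.mean_rel_substitutions) == (0.0, 0.0, 0.0)

    def test_superset_group_asymmetry(self):
        """Long notes = short notes + 10 extra tokens: with the short group as
        reference, the 10 extra hypothesis tokens are deletions (10/5 = 2.0)."""
        short = [f"t{i}" for i in range(5)]
        long = short + [f"x{i}" for i in range(10)]
        c = corpus_of([short, short, long, long],
                      generators=["human", "human", "llm", "llm"])
        s = group_edit_summary(c, ("psychiatry_human", "psychiatry_llm"),
                               direction="a_as_reference")
        assert s.mean_rel_deletions == pytest.approx(2.0)
        assert s.mean_rel_insertions == 0.0
        rev = group_edit_summary(c, ("psychiatry_human", "psychiatry_llm"),
                                 direction="b_as_reference")
        assert rev.mean_rel_insertions == pytest.approx(10 / 15)
        assert rev.mean_rel_deletions == 0.0

    def test_symmetrized_is_mean_of_directions(self):
        c = corpus_of([["a", "b", "c"], ["a", "x", "c", "d"]],
                      generators=["human", "llm"])
        pair = ("psychiatry_human", "psychiatry_llm")
        a = group_edit_summary(c, pair, "a_as_reference")
        b = group_edit_summary(c, pair, "b_as_reference")
        s = group_edit_summary(c, pair, "symmetrized")
        assert s.mean_rel_insertions == pytest.approx(
            (a.mean_rel_insertions + b.mean_rel_insertions) / 2)
        assert s.mean_rel_deletions == pytest.approx(
            (a.mean_rel_deletions + b.mean_rel_deletions) / 2)

    def test_unknown_group_rejected(self):
        c = corpus_of([["a"], ["b"]])
        with pytest.raises(KeyError):
            group_edit_summary(c, ("psychiatry_human", "missing"))
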