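"""Pairwise note similarity: TER with edit-operation decomposition, BLEU,
ROUGE-L, pluggable embedding similarity, symmetric matrices and Ward clustering.

TER (translation edit rate) is the number of word-level edit operations
(insertion, deletion, substitution — no shift/reorder operation) in a minimal
script transforming the *hypothesis* into the *reference*, divided by the
reference length; lower means structurally more similar.  The edit script is
computed by a row-vectorised Levenshtein dynamic program with a deterministic
backtrace (ties broken match/substitution > deletion > insertion), so the
insertion/deletion/substitution decomposition is canonical and reproducible.

Directional metrics are averaged over both directions to give a symmetric
note x note matrix; similarity-polarity metrics are converted to distances as
1 - score before Ward agglomerative clustering.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .corpus import GroupedCorpus, Note

__all__ = [
    "EditOps", "SimilarityMatrix", "GroupEditSummary",
    "edit_ops", "ter", "bleu", "rouge_l",
    "EmbeddingBackend", "HashEmbeddingBackend", "embed_similarity",
    "pairwise_matrix", "WardClusterer", "ward_cluster",
    "group_edit_summary", "all_group_edit_summaries",
]

METRICS = ("ter", "bleu", "rouge_l", "embed_f1")

# ------------------------------------------------------------------ edit ops


@dataclass(frozen=True)
class EditOps:
    """Insertion/deletion/substitution counts of a minimal word-level edit
    script transforming a hypothesis into a reference (shifts excluded)."""

    insertions: int
    deletions: int
    substitutions: int
    ref_length: int
    hyp_length: int

    @property
    def total(self) -> int:
        return self.insertions + self.deletions + self.substitutions

    def reversed(self) -> "EditOps":
        """Ops for the direction-reversed pair (insertions and deletions swap,
        substitutions and total distance are direction-invariant)."""
        return EditOps(
            insertions=self.deletions,
            deletions=self.insertions,
            substitutions=self.substitutions,
            ref_length=self.hyp_length,
            hyp_length=self.ref_length,
        )


def _encode_pair(hyp: Sequence[str], ref: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    codes: dict[str, int] = {}
    h = np.fromiter((codes.setdefault(t, len(codes)) for t in hyp), dtype=np.int64,
                    count=len(hyp))
    r = np.fromiter((codes.setdefault(t, len(codes)) for t in ref), dtype=np.int64,
                    count=len(ref))
    return h, r


def _levenshtein_table(h: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Full (len(h)+1, len(r)+1) unit-cost edit-distance table.

    Row i is filled from row i-1 with the within-row insertion dependency
    resolved by the min-plus prefix-scan identity
    ``cur[j] = min_k<=j (base[k] + (j-k))``.
    """
    n, m = len(h), len(r)
    table = np.empty((n + 1, m + 1), dtype=np.int64)
    idx = np.arange(m + 1)
    table[0] = idx
    base = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        prev = table[i - 1]
        base[0] = i
        np.minimum(prev[:-1] + (h[i - 1] != r), prev[1:] + 1, out=base[1:])
        table[i] = np.minimum.accumulate(base - idx) + idx
    return table


def edit_ops(hyp: Sequence[str], ref: Sequence[str]) -> EditOps:
    """Minimal word-level edit script transforming ``hyp`` into ``ref``.

    Backtrace tie-break: match/substitution preferred over deletion, deletion
    over insertion, making the decomposition canonical.  Deleting a hypothesis
    token is a deletion; inserting a reference token is an insertion, so
    ``insertions - deletions == len(ref) - len(hyp)`` always holds.
    """
    h, r = _encode_pair(hyp, ref)
    table = _levenshtein_table(h, r)
    i, j = len(h), len(r)
    ins = dele = sub = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if h[i - 1] == r[j - 1] else 1
            if table[i, j] == table[i - 1, j - 1] + cost:
                sub += cost
                i -= 1
                j -= 1
                continue
        if i > 0 and table[i, j] == table[i - 1, j] + 1:
            dele += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return EditOps(ins, dele, sub, ref_length=len(ref), hyp_length=len(hyp))


def ter(hyp: Sequence[str], ref: Sequence[str]) -> tuple[float, EditOps]:
    """Translation edit rate of ``hyp`` against ``ref`` plus the edit script.

    Score = (insertions + deletions + substitutions) / reference length; may
    exceed 1.  Shift operations are not considered.
    """
    if len(ref) == 0:
        raise ValueError("TER is undefined for an empty reference")
    ops = edit_ops(hyp, ref)
    return ops.total / ops.ref_length, ops


def _edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Distance only (symmetric in its arguments)."""
    h, r = _encode_pair(a, b)
    if len(h) == 0:
        return len(r)
    return int(_levenshtein_table(h, r)[-1, -1])


# ---------------------------------------------------------------- bleu/rouge


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def bleu(
    hyp: Sequence[str],
    ref: Sequence[str],
    max_n: int = 4,
    smoothing: str = "epsilon",
    epsilon: float = 0.1,
) -> float:
    """Sentence-level BLEU: geometric mean of modified n-gram precisions up to
    ``max_n``, times the brevity penalty.

    ``smoothing='epsilon'`` replaces a zero n-gram match count by ``epsilon``
    before dividing (so sparse high-order matches do not zero the score);
    ``smoothing='none'`` returns 0.0 whenever any precision is zero.  Orders
    longer than either sequence are skipped.
    """
    if len(hyp) == 0 or len(ref) == 0:
        raise ValueError("BLEU is undefined for empty sequences")
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if smoothing not in ("epsilon", "none"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    log_precisions: list[float] = []
    for n in range(1, max_n + 1):
        denom = len(hyp) - n + 1
        if denom <= 0 or len(ref) - n + 1 <= 0:
            break
        hyp_counts = _ngrams(hyp, n)
        ref_counts = _ngrams(ref, n)
        clipped = sum(min(c, ref_counts[g]) for g, c in hyp_counts.items())
        if clipped == 0:
            if smoothing == "none":
                return 0.0
            clipped = epsilon
        log_precisions.append(math.log(clipped / denom))
    if not log_precisions:
        return 0.0
    geo = math.exp(sum(log_precisions) / len(log_precisions))
    c, r = len(hyp), len(ref)
    bp = 1.0 if c >= r else math.exp(1.0 - r / c)
    return bp * geo


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    h, r = _encode_pair(a, b)
    m = len(r)
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, len(h) + 1):
        ai = h[i - 1]
        for j in range(1, m + 1):
            if ai == r[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev, cur = cur, prev
    return int(prev[m])


def rouge_l(a: Sequence[str], b: Sequence[str], beta: float = 1.0) -> float:
    """LCS-based F-measure between reference ``a`` and hypothesis ``b``.

    precision = LCS/|b|, recall = LCS/|a|; F_beta weights recall by beta
    (beta=1 gives the symmetric F1).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ROUGE-L is undefined for empty sequences")
    lcs = _lcs_length(a, b)
    if lcs == 0:
        return 0.0
    precision = lcs / len(b)
    recall = lcs / len(a)
    b2 = beta * beta
    return (1 + b2) * precision * recall / (recall + b2 * precision)


# ------------------------------------------------------------ embedding sim


class EmbeddingBackend(Protocol):
    """Per-token embedding provider: token sequence -> (n_tokens, dim) array."""

    name: str

    def embed(self, tokens: Sequence[str]) -> np.ndarray: ...


class HashEmbeddingBackend:
    """Deterministic offline backend: each token maps to a unit vector drawn
    from a generator seeded by the token's SHA-256 digest.  Identical tokens
    get identical vectors; distinct tokens are near-orthogonal at high dim.
    Intended for tests and offline runs; carries no semantics.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self.name = f"hash-{dim}d-seed{seed}"
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        rows = []
        for t in tokens:
            v = self._cache.get(t)
            if v is None:
                digest = hashlib.sha256(f"{self.seed}:{t}".encode()).digest()
                rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
                v = rng.standard_normal(self.dim)
                v /= np.linalg.norm(v)
                self._cache[t] = v
            rows.append(v)
        return np.asarray(rows)


class FixedEmbeddingBackend:
    """Lookup-table backend (token -> vector); for hand-traced tests."""

    def __init__(self, table: dict[str, Sequence[float]], name: str = "fixed"):
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        self.name = name

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self.table[t] for t in tokens])
        except KeyError as e:
            raise KeyError(f"backend {self.name!r} has no vector for token {e}") from e


def embed_similarity(a: Note | Sequence[str], b: Note | Sequence[str],
                     backend: EmbeddingBackend) -> float:
    """Greedy max-cosine token-matching F1 (BERTScore contract, no baseline
    rescaling): recall matches each token of ``a`` to its best in ``b``,
    precision the reverse; F1 is their harmonic mean."""
    tok_a = a.tokens if isinstance(a, Note) else a
    tok_b = b.tokens if isinstance(b, Note) else b
    if len(tok_a) == 0 or len(tok_b) == 0:
        raise ValueError("embedding similarity is undefined for empty notes")
    try:
        ea = np.asarray(backend.embed(tok_a), dtype=float)
        eb = np.asarray(backend.embed(tok_b), dtype=float)
    except Exception as e:
        raise RuntimeError(
            f"embedding backend {getattr(backend, 'name', backend)!r} failed: {e}"
        ) from e
    ea = ea / np.maximum(np.linalg.norm(ea, axis=1, keepdims=True), 1e-12)
    eb = eb / np.maximum(np.linalg.norm(eb, axis=1, keepdims=True), 1e-12)
    sim = ea @ eb.T
    recall = float(sim.max(axis=1).mean())
    precision = float(sim.max(axis=0).mean())
    if precision + recall <= 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# --------------------------------------------------------------- matrices


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise note-level scores for one metric."""

    note_ids: list[str]
    values: np.ndarray
    metric: str
    polarity: str  # "distance" or "similarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.note_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match note_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    def to_distance(self) -> "SimilarityMatrix":
        """Distance-polarity view: TER is already a distance; similarity
        metrics (scores in [0,1]) are converted as 1 - score."""
        if self.polarity == "distance":
            return self
        vals = 1.0 - self.values
        np.fill_diagonal(vals, 0.0)
        return SimilarityMatrix(self.note_ids, np.clip(vals, 0.0, None),
                                self.metric, "distance")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.note_ids, columns=self.note_ids)


def pairwise_matrix(corpus: GroupedCorpus, metric: str = "ter",
                    backend: EmbeddingBackend | None = None,
                    **params) -> SimilarityMatrix:
    """Bidirectionally averaged pairwise matrix over all notes.

    For directional metrics the (i, j) entry is the mean of metric(i->j) and
    metric(j->i), so the matrix is symmetric by construction.  For TER both
    directions share the same minimal edit distance D, so the averaged entry
    is D/2 * (1/len_i + 1/len_j) and each pair is solved once.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    notes = corpus.notes
    if len(notes) < 2:
        raise ValueError("pairwise matrix requires at least 2 notes")
    n = len(notes)
    vals = np.zeros((n, n))
    if metric == "ter":
        polarity = "distance"
        for i, j in itertools.combinations(range(n), 2):
            a, b = notes[i], notes[j]
            if not a.tokens or not b.tokens:
                raise ValueError(
                    f"TER undefined for empty note in pair ({a.note_id!r}, {b.note_id!r})")
            d = _edit_distance(a.tokens, b.tokens)
            vals[i, j] = vals[j, i] = 0.5 * d * (1 / len(a.tokens) + 1 / len(b.tokens))
    else:
        polarity = "similarity"
        if metric == "embed_f1" and backend is None:
            raise ValueError("embed_f1 requires an embedding backend")
        for i, j in itertools.combinations(range(n), 2):
            a, b = notes[i], notes[j]
            try:
                if metric == "bleu":
                    s = 0.5 * (bleu(a.tokens, b.tokens, **params)
                               + bleu(b.tokens, a.tokens, **params))
                elif metric == "rouge_l":
                    s = 0.5 * (rouge_l(a.tokens, b.tokens, **params)
                               + rouge_l(b.tokens, a.tokens, **params))
                else:
                    s = embed_similarity(a, b, backend)
            except ValueError as e:
                raise ValueError(
                    f"pair ({a.note_id!r}, {b.note_id!r}): {e}") from e
            vals[i, j] = vals[j, i] = s
        np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix([n_.note_id for n_ in notes], vals, metric, polarity)


# ---------------------------------------------------------------- clustering


class WardClusterer:
    """Ward agglomerative clustering of a note-level distance matrix.

    scikit-learn-style estimator: ``fit`` accepts a :class:`SimilarityMatrix`
    (similarity polarity is converted to 1 - score first) or a square distance
    array, and exposes ``linkage_``, ``labels_`` and ``note_ids_``.

    Each note is represented by its *distance profile* — its row of the
    pairwise matrix — and Ward linkage is computed on the Euclidean distances
    between profiles (the embedding a square distance matrix receives in the
    standard scipy/sklearn workflow).  Profiles average each note's relation
    to the whole corpus, which makes the grouping far more stable under the
    severe group-size imbalance this package targets than linking on the raw
    pairwise distances directly.  The merge sequence is deterministic given
    the matrix (scipy's linkage breaks ties by the lowest pair index in its
    candidate ordering).
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters}

    def set_params(self, **params) -> "WardClusterer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: SimilarityMatrix | np.ndarray, y=None) -> "WardClusterer":
        if isinstance(X, SimilarityMatrix):
            dist = X.to_distance()
            mat = dist.values
            self.note_ids_ = list(dist.note_ids)
        else:
            mat = np.asarray(X, dtype=float)
            self.note_ids_ = [str(i) for i in range(len(mat))]
        n = mat.shape[0]
        if mat.ndim != 2 or mat.shape != (n, n) or n < 2:
            raise ValueError("expected a square distance matrix with n >= 2")
        if not np.allclose(mat, mat.T):
            raise ValueError("distance matrix must be symmetric")
        if (mat < 0).any():
            raise ValueError("distance matrix must be nonnegative")
        # Euclidean distances between distance-profile rows, then Ward.
        condensed = pdist(mat)
        self.linkage_ = hierarchy.linkage(condensed, method="ward")
        self.labels_ = hierarchy.fcluster(
            self.linkage_, t=self.n_clusters, criterion="maxclust") - 1
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def _check_fitted(self) -> None:
        if not hasattr(self, "linkage_"):
            raise RuntimeError("WardClusterer is not fitted")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with note ids as leaf labels and
        merge heights as branch lengths."""
        self._check_fitted()
        tree = hierarchy.to_tree(self.linkage_)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) if parent_height else 0.0
            if node.is_leaf():
                return f"{self.note_ids_[node.id]}:{parent_height - 0.0:.6g}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(tree.get_left(), tree.dist)
        right = rec(tree.get_right(), tree.dist)
        return f"({left},{right});"

    def to_dict(self) -> dict:
        """Dendrogram as a nested-JSON-style dict."""
        self._check_fitted()
        tree = hierarchy.to_tree(self.linkage_)

        def rec(node) -> dict:
            if node.is_leaf():
                return {"note_id": self.note_ids_[node.id], "height": 0.0}
            return {
                "height": float(node.dist),
                "children": [rec(node.get_left()), rec(node.get_right())],
            }

        return rec(tree)


def ward_cluster(matrix: SimilarityMatrix, k: int) -> tuple[WardClusterer, np.ndarray]:
    """Convenience wrapper: fitted clusterer plus flat labels at ``k``."""
    clusterer = WardClusterer(n_clusters=k).fit(matrix)
    return clusterer, clusterer.labels_


# ---------------------------------------------------------- edit summaries


@dataclass(frozen=True)
class GroupEditSummary:
    """Mean edit-operation counts normalized by reference length, over all
    note pairs between (or within) two author groups."""

    group_a: str
    group_b: str
    mean_rel_insertions: float
    mean_rel_deletions: float
    mean_rel_substitutions: float
    direction: str  # a_as_reference | b_as_reference | symmetrized
    n_pairs: int


def _mean_rel(ops_and_refs: list[tuple[EditOps, int]]) -> tuple[float, float, float]:
    ins = np.mean([o.insertions / r for o, r in ops_and_refs])
    dele = np.mean([o.deletions / r for o, r in ops_and_refs])
    sub = np.mean([o.substitutions / r for o, r in ops_and_refs])
    return float(ins), float(dele), float(sub)


def group_edit_summary(corpus: GroupedCorpus, pair: tuple[str, str],
                       direction: str = "symmetrized") -> GroupEditSummary:
    """Average relative insertions/deletions/substitutions for one group pair.

    ``a_as_reference``: group-a notes serve as the TER reference (group-b notes
    are the hypothesis being edited into them); ``b_as_reference`` the reverse;
    ``symmetrized`` averages both directions.  Within-group summaries run over
    all unordered distinct pairs.  Ratios are normalized by the reference
    length of each pair.
    """
    if direction not in ("a_as_reference", "b_as_reference", "symmetrized"):
        raise ValueError(f"unknown direction {direction!r}")
    ga, gb = pair
    notes_a = corpus.group(ga)
    notes_b = corpus.group(gb)
    if not notes_a or not notes_b:
        raise ValueError(f"empty group in pair {pair!r}")
    within = ga == gb
    if within:
        pairs = list(itertools.combinations(notes_a, 2))
    else:
        pairs = list(itertools.product(notes_a, notes_b))
    if not pairs:
        raise ValueError(f"group {ga!r} has fewer than 2 notes for a within-group summary")

    a_ref: list[tuple[EditOps, int]] = []
    b_ref: list[tuple[EditOps, int]] = []
    for x, y in pairs:  # x from group a, y from group b
        ops = edit_ops(hyp=y.tokens, ref=x.tokens)
        a_ref.append((ops, len(x.tokens)))
        b_ref.append((ops.reversed(), len(y.tokens)))
    if direction == "a_as_reference":
        chosen = a_ref
    elif direction == "b_as_reference":
        chosen = b_ref
    else:
        chosen = a_ref + b_ref
    ins, dele, sub = _mean_rel(chosen)
    return GroupEditSummary(ga, gb, ins, dele, sub, direction,
                            n_pairs=len(pairs))


def all_group_edit_summaries(corpus: GroupedCorpus,
                             directions: Sequence[str] = (
                                 "a_as_reference", "b_as_reference", "symmetrized")):
    """Table-shaped summaries for every unordered group pair (including
    within-group) in every requested direction."""
    labels = corpus.group_labels
    out: list[GroupEditSummary] = []
    for ia, ga in enumerate(labels):
        for gb in labels[ia:]:
            if ga == gb and len(corpus.group(ga)) < 2:
                continue
            for d in directions:
                out.append(group_edit_summary(corpus, (ga, gb), d))
    return out
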