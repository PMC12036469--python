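"""Distributional-distance consensus clustering of variable-length embeddings.

Recordings differ in epoch count, so their embedding matrices cannot be fed
to k-means directly.  Instead, each embedding dimension of a recording is
treated as an empirical distribution over epochs; two recordings are
compared per dimension with a distribution distance (energy distance or 1-D
earth mover's distance) and the per-dimension distances are averaged.  The
resulting N x N distance-projection matrix gives every sample an N-vector of
distances to all samples, and those feature vectors feed k-means, silhouette
model selection, subsampled consensus matrices with Ward ordering, and an
a-posteriori ordinal risk-group labeling by observed mortality.

Both distance kernels run in O(n log n) per pair via sorted-array
prefix-sum identities; they agree with the brute-force double-sum /
CDF-integral definitions to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import ClusterSolution, ConsensusMatrix, EmbeddingMatrix

METRICS = ("energy", "earth_mover")


@dataclass
class DistanceProjection:
    """Symmetric hollow N x N pairwise-distance matrix with sample ids.

    Row i is sample i's feature vector for k-means (the self-entry 0 is
    retained; it is constant across samples and harmless to clustering).
    """

    matrix: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("projection matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("projection matrix must be symmetric")
        if (m < -1e-12).any():
            raise ValueError("projection matrix must be non-negative")

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])


# ---------------------------------------------------------------------------
# distance kernels
# ---------------------------------------------------------------------------

def _batch_counts_leq(a_sorted: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-row counts of ``a_sorted[d] <= q[d, j]`` via one flat searchsorted.

    Rows are made disjoint by adding per-row offsets larger than the global
    value range, letting a single sorted lookup serve all rows at once.
    """
    d, n = a_sorted.shape
    lo = min(a_sorted.min(), q.min())
    hi = max(a_sorted.max(), q.max())
    span = (hi - lo) + 1.0
    off = np.arange(d)[:, None] * span
    pos = np.searchsorted(
        (a_sorted - lo + off).ravel(), (q - lo + off).ravel(), side="right"
    )
    return pos.reshape(d, q.shape[1]) - np.arange(d)[:, None] * n


def _within_sum_sorted(a_sorted: np.ndarray) -> np.ndarray:
    """``sum_{i,j} |x_i - x_j|`` per row of a row-sorted matrix."""
    n = a_sorted.shape[1]
    w = 2.0 * np.arange(1, n + 1) - n - 1
    return 2.0 * (a_sorted * w).sum(axis=1)


def _cross_sum_sorted(a_sorted: np.ndarray, b_sorted: np.ndarray) -> np.ndarray:
    """``sum_{i,j} |x_i - y_j|`` per row for two row-sorted matrices."""
    d, n = a_sorted.shape
    m = b_sorted.shape[1]
    k = _batch_counts_leq(a_sorted, b_sorted)
    cum = np.concatenate(
        [np.zeros((d, 1)), np.cumsum(a_sorted, axis=1)], axis=1
    )
    gathered = np.take_along_axis(cum, k, axis=1)
    total = cum[:, -1]
    return (b_sorted * (2.0 * k - n)).sum(axis=1) - 2.0 * gathered.sum(axis=1) \
        + m * total


def energy_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Energy distance between two 1-D empirical samples.

    ``D = 2 E|X - Y| - E|X - X'| - E|Y - Y'|`` with all expectations over
    ordered pairs (self-pairs included).  Non-negative, zero iff the two
    multisets are identical; handles unequal sample sizes.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("energy distance requires non-empty samples")
    xs, ys = np.sort(x)[None, :], np.sort(y)[None, :]
    if x.size == y.size and np.array_equal(xs, ys):
        return 0.0  # identical multisets: exactly zero, no float residue
    cross = _cross_sum_sorted(xs, ys)[0] / (x.size * y.size)
    wx = _within_sum_sorted(xs)[0] / x.size**2
    wy = _within_sum_sorted(ys)[0] / y.size**2
    return float(max(2.0 * cross - wx - wy, 0.0))


def earth_mover_distance_1d(x: np.ndarray, y: np.ndarray) -> float:
    """1-D earth mover's (Wasserstein-1) distance: L1 area between CDFs."""
    from scipy.stats import wasserstein_distance

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("earth mover's distance requires non-empty samples")
    return float(wasserstein_distance(x, y))


def _emd_rows_sorted(a_sorted: np.ndarray, b_sorted: np.ndarray) -> np.ndarray:
    """Per-row 1-D EMD between row-sorted matrices (vectorized over rows)."""
    d, n = a_sorted.shape
    m = b_sorted.shape[1]
    z = np.sort(np.concatenate([a_sorted, b_sorted], axis=1), axis=1)
    grid = z[:, :-1]
    fa = _batch_counts_leq(a_sorted, grid) / n
    fb = _batch_counts_leq(b_sorted, grid) / m
    return (np.abs(fa - fb) * np.diff(z, axis=1)).sum(axis=1)


@dataclass
class _SortedEmbedding:
    """Per-dimension sorted values and prefix statistics of one embedding."""

    sorted: np.ndarray  # (d, n) row-sorted
    within_mean: np.ndarray  # (d,) mean |x - x'| incl. self-pairs

    @classmethod
    def from_matrix(cls, emb: EmbeddingMatrix) -> "_SortedEmbedding":
        s = np.sort(np.asarray(emb.values, dtype=float), axis=1)
        return cls(sorted=s, within_mean=_within_sum_sorted(s) / s.shape[1] ** 2)


def _pair_distance(a: _SortedEmbedding, b: _SortedEmbedding, metric: str) -> float:
    n, m = a.sorted.shape[1], b.sorted.shape[1]
    if n == m and np.array_equal(a.sorted, b.sorted):
        return 0.0  # identical per-dimension multisets
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "energy":
        cross = _cross_sum_sorted(a.sorted, b.sorted) / (n * m)
        per_dim = 2.0 * cross - a.within_mean - b.within_mean
        return float(np.maximum(per_dim, 0.0).mean())
    if metric == "earth_mover":
        return float(_emd_rows_sorted(a.sorted, b.sorted).mean())
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def embedding_pair_distance(
    a: EmbeddingMatrix, b: EmbeddingMatrix, metric: str = "energy"
) -> float:
    """Mean over embedding dimensions of the per-dimension distribution
    distance between two recordings' epoch embeddings.

    Each embedding dimension contributes one distance between its value
    distribution over epochs in ``a`` and in ``b`` (epoch counts may
    differ); the per-dimension distances are averaged into one scalar.
    """
    if a.embed_dim != b.embed_dim:
        raise ValueError(
            f"embedding dimension mismatch: {a.embed_dim} vs {b.embed_dim}"
        )
    return _pair_distance(
        _SortedEmbedding.from_matrix(a), _SortedEmbedding.from_matrix(b), metric
    )


def project_samples(
    embeddings: list[EmbeddingMatrix], metric: str = "energy"
) -> DistanceProjection:
    """Full pairwise-distance matrix over a collection of recordings."""
    if len(embeddings) < 2:
        raise ValueError("projection requires at least 2 samples")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    dims = {e.embed_dim for e in embeddings}
    if len(dims) != 1:
        raise ValueError(f"embeddings must share embed_dim; saw {sorted(dims)}")
    summaries = [_SortedEmbedding.from_matrix(e) for e in embeddings]
    n = len(embeddings)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pair_distance(summaries[i], summaries[j], metric)
    ids = [e.recording_id or f"sample{i}" for i, e in enumerate(embeddings)]
    return DistanceProjection(matrix=mat, sample_ids=ids, metric=metric)


def project_onto_reference(
    embeddings: list[EmbeddingMatrix],
    reference: list[EmbeddingMatrix],
    metric: str = "energy",
) -> pd.DataFrame:
    """Feature vectors of distances to a restricted reference set.

    Variant of :func:`project_samples` in which each sample's feature
    vector holds distances to ``reference`` samples only (e.g. a held-out
    test subset) rather than to the full collection.  Returns a DataFrame
    of shape (n_samples, n_reference).
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    s_emb = [_SortedEmbedding.from_matrix(e) for e in embeddings]
    s_ref = [_SortedEmbedding.from_matrix(e) for e in reference]
    mat = np.array(
        [[_pair_distance(a, b, metric) for b in s_ref] for a in s_emb]
    )
    return pd.DataFrame(
        mat,
        index=[e.recording_id or f"sample{i}" for i, e in enumerate(embeddings)],
        columns=[e.recording_id or f"ref{i}" for i, e in enumerate(reference)],
    )


# ---------------------------------------------------------------------------
# k-means, silhouette, consensus
# ---------------------------------------------------------------------------

def _kmeans_labels(features: np.ndarray, k: int, seed: int,
                   n_init: int = 10, max_iter: int = 300) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    return km.fit_predict(features)


def _safe_silhouette(features: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels)) < 2:
        return 0.0  # degenerate single-cluster convention
    return float(silhouette_score(features, labels))


def cluster_k(projection: DistanceProjection, k: int, seed: int = 0) -> ClusterSolution:
    """k-means on the distance-projection feature vectors.

    Euclidean k-means with 10 seeded restarts, keeping the best-inertia
    partition; the silhouette is computed on the same feature vectors.
    """
    if not 2 <= k < projection.n:
        raise ValueError(f"k must satisfy 2 <= k < N={projection.n}, got {k}")
    labels = _kmeans_labels(projection.matrix, k, seed)
    return ClusterSolution(
        k=k,
        assignment=dict(zip(projection.sample_ids, (int(c) for c in labels))),
        silhouette=_safe_silhouette(projection.matrix, labels),
        seed=seed,
    )


def silhouette_by_k(
    projection: DistanceProjection, k_range, seed: int = 0
) -> pd.DataFrame:
    """Mean silhouette of the k-means partition for each candidate k."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    rows = [
        {"k": k, "silhouette": cluster_k(projection, k, seed).silhouette}
        for k in k_range
    ]
    return pd.DataFrame(rows)


def consensus_analysis(
    projection: DistanceProjection,
    k: int,
    n_iterations: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusMatrix:
    """Subsampled co-clustering frequencies with Ward leaf ordering.

    Each iteration draws ``subsample_fraction`` of samples and of feature
    columns without replacement, runs k-means, and records co-assignments.
    ``values[i, j]`` normalizes by the number of iterations in which i and j
    were co-sampled (not by ``n_iterations``), so rarely co-sampled pairs
    are not deflated; never-co-sampled pairs are 0 and flagged undefined.
    """
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError(f"subsample_fraction must be in (0, 1], got {subsample_fraction}")
    n = projection.n
    n_sub = int(round(subsample_fraction * n))
    if n_sub < k:
        raise ValueError(f"subsample of {n_sub} cannot support k={k}")
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n), dtype=np.int64)
    both = np.zeros((n, n), dtype=np.int64)
    for it in range(n_iterations):
        samp = rng.choice(n, size=n_sub, replace=False)
        feats = rng.choice(n, size=n_sub, replace=False)
        sub = projection.matrix[np.ix_(samp, feats)]
        labels = _kmeans_labels(sub, k, int(rng.integers(2**31 - 1)), n_init=3)
        both[np.ix_(samp, samp)] += 1
        for c in range(k):
            members = samp[labels == c]
            co[np.ix_(members, members)] += 1
    values = np.divide(co, both, out=np.zeros((n, n)), where=both > 0)
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="ward"))
    return ConsensusMatrix(
        values=values,
        co_occurrence_counts=both,
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        sample_ids=projection.sample_ids,
        ward_order=order,
    )


# ---------------------------------------------------------------------------
# risk-group labeling and cross-solution flow
# ---------------------------------------------------------------------------

def label_risk_groups(
    solution: ClusterSolution, subjects: pd.DataFrame
) -> ClusterSolution:
    """Assign ordinal risk labels RG1..RGk by crude mortality rate.

    ``subjects`` must be indexed by sample id with ``event`` and
    ``time_years`` columns.  Clusters are ordered by deaths per person-year
    ascending (RG1 = lowest risk); ties break by cluster id.
    """
    missing = [s for s in solution.assignment if s not in subjects.index]
    if missing:
        raise ValueError(f"missing outcome data for samples: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    rates = {}
    for c in sorted(set(solution.assignment.values())):
        ids = [s for s, ci in solution.assignment.items() if ci == c]
        sub = subjects.loc[ids]
        person_years = float(sub["time_years"].sum())
        rates[c] = float(sub["event"].sum()) / person_years if person_years else 0.0
    ordered = sorted(rates, key=lambda c: (rates[c], c))
    risk_labels = {c: f"RG{rank + 1}" for rank, c in enumerate(ordered)}
    return ClusterSolution(
        k=solution.k,
        assignment=dict(solution.assignment),
        silhouette=solution.silhouette,
        seed=solution.seed,
        risk_labels=risk_labels,
    )


def cross_solution_flow(solutions: list[ClusterSolution]) -> pd.DataFrame:
    """Sample counts flowing between clusters of consecutive solutions.

    Returns a table with columns ``(level, k_from, cluster_from, k_to,
    cluster_to, count)`` suitable for Sankey rendering.  All solutions must
    share the same sample set.
    """
    if len(solutions) < 2:
        raise ValueError("need at least two solutions")
    base = set(solutions[0].assignment)
    for s in solutions[1:]:
        if set(s.assignment) != base:
            raise ValueError("solutions do not share the same sample set")
    rows = []
    for level, (a, b) in enumerate(zip(solutions[:-1], solutions[1:])):
        counts: dict[tuple[int, int], int] = {}
        for sid in a.assignment:
            key = (a.assignment[sid], b.assignment[sid])
            counts[key] = counts.get(key, 0) + 1
        for (cf, ct), cnt in sorted(counts.items()):
            rows.append(
                {"level": level, "k_from": a.k, "cluster_from": cf,
                 "k_to": b.k, "cluster_to": ct, "count": cnt}
            )
    return pd.DataFrame(rows)
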