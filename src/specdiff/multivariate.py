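"""Unsupervised structure: correspondence analysis, hierarchical clustering
and K-medians partitioning of spectral-count profiles.

Correspondence analysis operates on raw counts (it is defined on count
tables).  Hierarchical clustering and K-medians operate on a transformed
matrix — by convention log2(count+1) followed by per-protein z-scoring,
see :func:`log_zscore` — because raw spectral counts are heavily
right-skewed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .io import CountMatrix, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "CAEmbedding",
    "Dendrogram",
    "PartitionResult",
    "log_zscore",
    "correspondence_analysis",
    "hierarchical_cluster",
    "kmedians",
    "match_partition_to_labels",
]


@dataclass(frozen=True)
class CAEmbedding:
    """Principal-coordinate embedding of a count table."""

    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    sample_coordinates: np.ndarray  # samples x k
    protein_coordinates: np.ndarray  # proteins x k
    axis_inertias: np.ndarray  # k, non-increasing
    total_inertia: float


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree: (node, node, height) triples.

    Nodes 0..n-1 are leaves; merge i creates node n+i.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]
    leaf_labels: tuple[str, ...]
    linkage_name: str
    distance_name: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Leaf cluster labels after keeping the last n_clusters-1 merges unmade."""
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self._scipy_linkage(), t=n_clusters, criterion="maxclust")

    def _scipy_linkage(self) -> np.ndarray:
        z = np.zeros((len(self.merges), 4))
        sizes = {i: 1 for i in range(self.n_leaves)}
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + i] = size
            z[i] = [a, b, h, size]
        return z


@dataclass(frozen=True)
class PartitionResult:
    """K-medians clustering outcome."""

    assignments: np.ndarray  # n points -> cluster id
    medians: np.ndarray  # k x features
    objective: float  # total L1 distance to assigned medians
    n_iterations: int
    seed: int | None
    restarts: int
    point_ids: tuple[str, ...] = ()


def log_zscore(counts: np.ndarray) -> np.ndarray:
    """log2(count+1) then per-row z-score; constant rows map to zeros."""
    x = np.log2(np.asarray(counts, dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)


def correspondence_analysis(matrix: CountMatrix, n_axes: int = 3) -> CAEmbedding:
    """Classical correspondence analysis of a protein x sample count table.

    All-zero rows/columns are dropped with a warning.  Principal coordinates
    (mass-weighted, inertia-scaled) are reported for both axes; the sign of
    each axis is fixed so the largest-magnitude sample coordinate is positive.
    """
    counts = matrix.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("grand total of the count matrix is 0")
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all():
        logger.warning("dropping %d all-zero protein rows", int((~row_keep).sum()))
    if not col_keep.all():
        logger.warning("dropping %d all-zero sample columns", int((~col_keep).sum()))
    counts = counts[np.ix_(row_keep, col_keep)]
    protein_ids = tuple(p for p, k in zip(matrix.protein_ids, row_keep) if k)
    sample_ids = tuple(s for s, k in zip(matrix.sample_ids, col_keep) if k)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 non-zero rows and 2 non-zero columns")

    p = counts / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s, full_matrices=False)

    total_inertia = float((sv**2).sum())
    k = min(n_axes, sv.size)
    # guard against numerically-zero trailing axes
    k = max(1, min(k, int((sv > 1e-12).sum()) or 1))
    u, sv, v = u[:, :k], sv[:k], vt[:k].T

    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = (v * sv) / np.sqrt(c)[:, None]
    for axis in range(k):
        pivot = np.argmax(np.abs(col_coords[:, axis]))
        if col_coords[pivot, axis] < 0:
            col_coords[:, axis] *= -1
            row_coords[:, axis] *= -1
    return CAEmbedding(
        sample_ids=sample_ids,
        protein_ids=protein_ids,
        sample_coordinates=col_coords,
        protein_coordinates=row_coords,
        axis_inertias=sv**2,
        total_inertia=total_inertia,
    )


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; zero-variance rows get distance 1."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance rows: correlation distance set to 1", int(degenerate.sum())
        )
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    matrix: np.ndarray,
    labels: tuple[str, ...] | None = None,
    distance: Literal["correlation", "euclidean", "cityblock"] = "correlation",
    method: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``matrix``.

    Default distance is 1 - Pearson correlation with average linkage.  To
    cluster both axes (two-dimensional clustering) call once on the matrix
    and once on its transpose.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if labels is None:
        labels = tuple(str(i) for i in range(x.shape[0]))
    if distance == "correlation":
        condensed = _correlation_distance(x)
    else:
        condensed = pdist(x, metric=distance)
    z = linkage(condensed, method=method)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in z)
    return Dendrogram(
        merges=merges,
        leaf_order=tuple(int(i) for i in leaves_list(z)),
        leaf_labels=labels,
        linkage_name=method,
        distance_name=distance,
    )


def _l1_assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # ties go to the lowest cluster index (argmin is first-match)
    dists = np.abs(points[:, None, :] - centers[None, :, :]).sum(axis=2)
    return np.argmin(dists, axis=1)


def _l1_objective(points: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(np.abs(points - centers[assign]).sum())


def kmedians(
    matrix: np.ndarray,
    k: int = 2,
    n_restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 200,
    point_ids: tuple[str, ...] = (),
) -> PartitionResult:
    """K-medians over the rows of ``matrix`` (points x features).

    Lloyd-style alternation: L1 assignment, coordinate-wise median update.
    Best of ``n_restarts`` random initializations (k distinct data points)
    by total L1 objective; deterministic under a fixed seed.  A cluster that
    empties is re-seeded at the point farthest from its assigned center.
    """
    points = np.asarray(matrix, dtype=float)
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    rng = np.random.default_rng(seed)

    best: PartitionResult | None = None
    for _ in range(max(1, n_restarts)):
        centers = points[rng.choice(n, size=k, replace=False)].copy()
        assign = _l1_assign(points, centers)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            for c in range(k):
                members = points[assign == c]
                if members.size == 0:
                    farthest = np.argmax(
                        np.abs(points - centers[assign]).sum(axis=1)
                    )
                    logger.info("k-medians: re-seeding empty cluster %d", c)
                    centers[c] = points[farthest]
                else:
                    centers[c] = np.median(members, axis=0)
            new_assign = _l1_assign(points, centers)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
        objective = _l1_objective(points, centers, assign)
        if best is None or objective < best.objective:
            best = PartitionResult(
                assignments=assign.copy(),
                medians=centers.copy(),
                objective=objective,
                n_iterations=n_iter,
                seed=seed,
                restarts=max(1, n_restarts),
                point_ids=point_ids,
            )
    assert best is not None
    return best


def match_partition_to_labels(
    partition: PartitionResult, design: StudyDesign
) -> tuple[float, dict[int, str]]:
    """Accuracy of a 2-cluster partition against a two-group design.

    Uses the better of the two cluster-to-group mappings, so the result is
    invariant to cluster numbering.
    """
    group_a, group_b = design.require_two_groups()
    if not partition.point_ids:
        raise ValueError("partition carries no point ids to match against the design")
    truth = np.array([design.assignments[s] for s in partition.point_ids])
    assign = partition.assignments
    clusters = np.unique(assign)
    if len(clusters) > 2:
        raise ValueError("label matching requires a 2-cluster partition")
    mapping_1 = {0: group_a, 1: group_b}
    mapping_2 = {0: group_b, 1: group_a}
    accs = []
    for mapping in (mapping_1, mapping_2):
        predicted = np.array([mapping[int(c)] for c in assign])
        accs.append(float((predicted == truth).mean()))
    best = int(np.argmax(accs))
    return accs[best], (mapping_1, mapping_2)[best]
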