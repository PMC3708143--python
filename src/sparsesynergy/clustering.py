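"""Associative clustering of EMG bursts in the (onset, offset) phase plane.

Each burst is summarized by its centroid P = (mean onset, mean offset) and
SD vector S = (sd onset, sd offset), i.e. by the +/-1 SD rectangle around P.
Two bursts are *adjacent* when the projections of their SD rectangles onto
the inter-centroid axis overlap:

    q = proj_a + proj_b - ||P_a - P_b||  >  0

where ``proj`` is the largest projection of a rectangle's vertex vector
(+/-sigma_x, +/-sigma_y) onto the unit inter-centroid direction.  Clusters
(synergies) are the equivalence classes (connected components) of the
adjacency graph, renumbered so that mean onsets ascend.  A burst belongs to
exactly one cluster: the method associates bursts rather than decomposing
them into weighted combinations.

Two protocols are supported:

* *two-stage* (unconstrained): the richest data subset is clustered alone,
  then additional bursts join an existing multi-member cluster only if they
  overlap at least two of its members (one suffices for a singleton).
* *constrained*: membership is frozen to a reference solution (typically
  unobstructed locomotion); only bursts absent from the reference are placed
  via the adjacency rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidClusterError

logger = logging.getLogger(__name__)

#: sentinel for coincident centroids (adjacent by convention)
Q_COINCIDENT = math.inf


# ---------------------------------------------------------------------------
# burst summaries


@dataclass(frozen=True)
class BurstStatistics:
    """Phase-plane summary of one burst: centroid, SDs, correlation, n."""

    label: str
    x: float  # mean onset phase
    y: float  # mean offset phase
    sx: float  # SD of onset
    sy: float  # SD of offset
    rho: float  # onset/offset correlation across trials
    n: int  # trial count

    def __post_init__(self) -> None:
        if not self.y > self.x:
            raise InvalidClusterError(
                f"{self.label}: mean offset {self.y} <= mean onset {self.x}"
            )
        if self.sx < 0 or self.sy < 0:
            raise InvalidClusterError(f"{self.label}: negative SD")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidClusterError(f"{self.label}: rho {self.rho} outside [-1, 1]")
        if self.n < 2:
            raise InsufficientDataError(f"{self.label}: n={self.n} < 2 trials")

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.x, self.y])


def screen_outliers(
    points: np.ndarray, margin: float = 2.0, max_fraction: float = 0.10
) -> tuple[np.ndarray, int]:
    """Iterative outlier screen on one burst's (onset, offset) trials.

    Repeatedly removes the single trial whose onset *or* offset deviates
    most from the current mean, in SD units recomputed after each removal,
    while that deviation exceeds ``margin`` SDs.  At most
    ``ceil(max_fraction * n)`` trials are removed.  Samples with fewer than
    3 trials are returned unchanged.

    Returns ``(retained_points, n_removed)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n0 = pts.shape[0]
    if n0 < 3:
        logger.info("outlier screen skipped: only %d trial(s)", n0)
        return pts, 0
    cap = math.ceil(max_fraction * n0)
    removed = 0
    while removed < cap and pts.shape[0] >= 3:
        mean = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(pts - mean) / sd
        dev[:, sd == 0] = 0.0
        worst = dev.max(axis=1)
        i = int(np.argmax(worst))  # ties -> lowest index, deterministic
        if worst[i] <= margin:
            break
        pts = np.delete(pts, i, axis=0)
        removed += 1
    return pts, removed


def summarize_burst(label: str, points: np.ndarray) -> BurstStatistics:
    """Sample mean, SD (n-1 denominator) and correlation of one burst.

    ``rho`` is defined as 0 when either coordinate has zero variance.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n < 2:
        raise InsufficientDataError(f"{label}: n={n} < 2 trials")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0, ddof=1)
    if sd[0] > 0 and sd[1] > 0:
        cov = float(np.cov(pts[:, 0], pts[:, 1], ddof=1)[0, 1])
        rho = cov / (sd[0] * sd[1])
        rho = float(np.clip(rho, -1.0, 1.0))
    else:
        rho = 0.0
    return BurstStatistics(
        label=label,
        x=float(mean[0]),
        y=float(mean[1]),
        sx=float(sd[0]),
        sy=float(sd[1]),
        rho=rho,
        n=n,
    )


# ---------------------------------------------------------------------------
# adjacency


def adjacency_q(a: BurstStatistics, b: BurstStatistics) -> float:
    """Overlap margin q between two bursts' SD rectangles (phase units).

    With d = P_a - P_b and unit direction d_hat, q is the maximum over the
    16 vertex sign choices of the projections of both rectangles' vertex
    vectors onto d_hat, minus the centroid distance; q > 0 means the two
    rectangles' projections on the inter-centroid axis overlap.  Coincident
    centroids return +inf (adjacent by convention).
    """
    d = a.centroid - b.centroid
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0:
        return Q_COINCIDENT
    ux, uy = abs(d[0] / norm), abs(d[1] / norm)
    proj_a = a.sx * ux + a.sy * uy
    proj_b = b.sx * ux + b.sy * uy
    return proj_a + proj_b - norm


@dataclass
class AdjacencyMatrix:
    """Boolean adjacency of bursts under the q > 0 criterion.

    Stored as a full symmetric matrix with a true diagonal; the informative
    content is the upper triangle.
    """

    labels: tuple[str, ...]
    entries: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)


def build_adjacency(stats: Sequence[BurstStatistics]) -> AdjacencyMatrix:
    """Evaluate the pairwise adjacency criterion over all burst pairs."""
    labels = tuple(s.label for s in stats)
    if len(set(labels)) != len(labels):
        raise InvalidClusterError("duplicate burst labels in adjacency input")
    n = len(stats)
    B = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency_q(stats[i], stats[j]) > 0:
                B[i, j] = B[j, i] = True
    return AdjacencyMatrix(labels=labels, entries=B)


def equivalence_classes(adj: AdjacencyMatrix) -> list[set[str]]:
    """Partition burst labels into connected components (union-find).

    Implements weighted union with path compression; equivalent to the
    transitive closure of the adjacency relation.
    """
    n = adj.n
    parent = list(range(n))
    size = [1] * n

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri == rj:
            return
        if size[ri] < size[rj]:
            ri, rj = rj, ri
        parent[rj] = ri
        size[ri] += size[rj]

    for i in range(n):
        for j in range(i + 1, n):
            if adj.entries[i, j]:
                union(i, j)

    groups: dict[int, set[str]] = {}
    for i, label in enumerate(adj.labels):
        groups.setdefault(find(i), set()).add(label)
    return list(groups.values())


# ---------------------------------------------------------------------------
# clusters and solutions


@dataclass(frozen=True)
class PooledStats:
    """Trial-weighted (onset, offset) statistics pooled over member bursts."""

    x: float
    sx: float
    y: float
    sy: float
    rho: float
    n: int


def pool_statistics(members: Sequence[BurstStatistics]) -> PooledStats:
    """Pool per-burst moments into exact all-trial statistics.

    Uses the standard combination of within- and between-burst sums of
    squares (and cross-products via rho), so the result equals what one
    would compute from the concatenated raw trials.
    """
    ns = np.array([m.n for m in members], dtype=float)
    N = int(ns.sum())
    xs = np.array([m.x for m in members])
    ys = np.array([m.y for m in members])
    X = float(np.sum(ns * xs) / N)
    Y = float(np.sum(ns * ys) / N)
    ssx = float(np.sum((ns - 1) * np.array([m.sx for m in members]) ** 2
                       + ns * (xs - X) ** 2))
    ssy = float(np.sum((ns - 1) * np.array([m.sy for m in members]) ** 2
                       + ns * (ys - Y) ** 2))
    sxy = float(np.sum((ns - 1) * np.array([m.rho * m.sx * m.sy for m in members])
                       + ns * (xs - X) * (ys - Y)))
    if N < 2:
        raise InsufficientDataError("pooled statistics need >= 2 trials")
    sx = math.sqrt(ssx / (N - 1))
    sy = math.sqrt(ssy / (N - 1))
    if sx > 0 and sy > 0:
        rho = float(np.clip(sxy / (N - 1) / (sx * sy), -1.0, 1.0))
    else:
        rho = 0.0
    return PooledStats(x=X, sx=sx, y=Y, sy=sy, rho=rho, n=N)


@dataclass(frozen=True)
class Cluster:
    """An ordered synergy: member burst labels plus pooled phase statistics.

    ``centroid`` is the unweighted mean of member burst centroids (as used
    for inter-cluster distances); ``pooled`` is trial-weighted and feeds the
    direct-component and ellipse summaries.
    """

    id: int
    members: tuple[str, ...]
    centroid: tuple[float, float]
    pooled: PooledStats

    def centroid_array(self) -> np.ndarray:
        return np.array(self.centroid)


@dataclass
class ClusterSolution:
    """A complete partition of bursts into synergies."""

    clusters: tuple[Cluster, ...]
    mode: str = "unconstrained"  # or "constrained"
    reference: "ClusterSolution | None" = None
    absent_labels: tuple[str, ...] = ()

    def partition(self) -> dict[str, int]:
        return {m: c.id for c in self.clusters for m in c.members}

    def label_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(c.members) for c in self.clusters)

    def __getitem__(self, cluster_id: int) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(cluster_id)


def _make_cluster(cid: int, members: Iterable[str],
                  stats_by_label: Mapping[str, BurstStatistics]) -> Cluster:
    ms = tuple(sorted(members))
    member_stats = [stats_by_label[m] for m in ms]
    cx = float(np.mean([s.x for s in member_stats]))
    cy = float(np.mean([s.y for s in member_stats]))
    return Cluster(id=cid, members=ms, centroid=(cx, cy),
                   pooled=pool_statistics(member_stats))


def order_clusters(
    partition: Iterable[Iterable[str]],
    stats: Sequence[BurstStatistics],
    mode: str = "unconstrained",
) -> ClusterSolution:
    """Number clusters 1..K by ascending mean onset of member centroids.

    Ties in mean onset are broken by the lexicographically first member
    label, which makes the numbering invariant to input order.
    """
    by_label = {s.label: s for s in stats}
    groups = [tuple(sorted(g)) for g in partition]
    keyed = sorted(
        groups,
        key=lambda g: (float(np.mean([by_label[m].x for m in g])), g[0]),
    )
    clusters = tuple(
        _make_cluster(cid, g, by_label) for cid, g in enumerate(keyed, start=1)
    )
    return ClusterSolution(clusters=clusters, mode=mode)


def cluster_bursts(stats: Sequence[BurstStatistics]) -> ClusterSolution:
    """Single-stage unconstrained clustering: adjacency -> components -> order."""
    stats = sorted(stats, key=lambda s: s.label)
    adj = build_adjacency(stats)
    return order_clusters(equivalence_classes(adj), stats)


def cluster_two_stage(
    primary_stats: Sequence[BurstStatistics],
    additional_stats: Sequence[BurstStatistics],
) -> ClusterSolution:
    """Two-substage protocol for multi-subject datasets.

    Stage 1 clusters ``primary_stats`` (the richest subset) alone.  Stage 2
    processes ``additional_stats`` in ascending mean-onset order: a burst
    joins an existing cluster with more than one member only if it overlaps
    (q > 0) at least two of its members; a single overlap suffices for a
    singleton cluster.  Candidates are ranked by overlap count then by
    centroid distance.  Bursts joining nothing are clustered among
    themselves; final ids are reordered by mean onset.
    """
    primary = sorted(primary_stats, key=lambda s: s.label)
    labels_p = {s.label for s in primary}
    if labels_p & {s.label for s in additional_stats}:
        raise InvalidClusterError("primary and additional label sets overlap")
    if primary:
        stage1 = cluster_bursts(primary)
        groups: list[set[str]] = [set(c.members) for c in stage1.clusters]
    else:
        groups = []
    by_label = {s.label: s for s in primary}

    leftovers: list[BurstStatistics] = []
    for s in sorted(additional_stats, key=lambda t: (t.x, t.label)):
        candidates: list[tuple[int, float, int]] = []
        for gi, g in enumerate(groups):
            overlaps = sum(
                1 for m in g if adjacency_q(s, by_label[m]) > 0
            )
            needed = 2 if len(g) > 1 else 1
            if overlaps >= needed:
                cx = float(np.mean([by_label[m].x for m in g]))
                cy = float(np.mean([by_label[m].y for m in g]))
                dist = float(np.hypot(s.x - cx, s.y - cy))
                candidates.append((-overlaps, dist, gi))
        if candidates:
            _, _, gi = min(candidates)
            groups[gi].add(s.label)
            by_label[s.label] = s
        else:
            leftovers.append(s)

    if leftovers:
        sub = cluster_bursts(leftovers)
        for c in sub.clusters:
            groups.append(set(c.members))
        for s in leftovers:
            by_label[s.label] = s

    all_stats = list(by_label.values())
    return order_clusters(groups, all_stats)


def assign_constrained(
    condition_stats: Sequence[BurstStatistics],
    reference: ClusterSolution,
) -> ClusterSolution:
    """Re-analyse a condition with membership frozen to a reference solution.

    Bursts whose label exists in the reference keep their reference cluster
    id regardless of where the condition moved them.  Novel bursts (present
    only in this condition) are assigned to the cluster with the greatest
    number of adjacent (q > 0) members, ties broken by smallest centroid
    distance; a burst adjacent to no cluster goes to the nearest-centroid
    cluster with a logged warning.  Pooled statistics are recomputed from
    the condition's own trials; reference cluster ids are preserved.
    """
    by_label = {s.label: s for s in condition_stats}
    ref_partition = reference.partition()
    groups: dict[int, set[str]] = {c.id: set() for c in reference.clusters}
    absent = tuple(sorted(set(ref_partition) - set(by_label)))
    if absent:
        logger.info("reference burst(s) absent in condition: %s", ", ".join(absent))

    novel: list[BurstStatistics] = []
    for s in sorted(condition_stats, key=lambda t: t.label):
        if s.label in ref_partition:
            groups[ref_partition[s.label]].add(s.label)
        else:
            novel.append(s)

    for s in sorted(novel, key=lambda t: (t.x, t.label)):
        best: tuple[int, float, int] | None = None
        for cid, g in sorted(groups.items()):
            present = [by_label[m] for m in g]
            if not present:
                continue
            overlaps = sum(1 for m in present if adjacency_q(s, m) > 0)
            cx = float(np.mean([m.x for m in present]))
            cy = float(np.mean([m.y for m in present]))
            dist = float(np.hypot(s.x - cx, s.y - cy))
            key = (-overlaps, dist, cid)
            if best is None or key < best:
                best = key
        if best is None:
            raise InvalidClusterError("constrained assignment needs a non-empty reference")
        if -best[0] == 0:
            logger.warning(
                "novel burst %s adjacent to no cluster; assigned to nearest centroid",
                s.label,
            )
        groups[best[2]].add(s.label)
        by_label[s.label] = s

    clusters = tuple(
        _make_cluster(cid, g, by_label)
        for cid, g in sorted(groups.items())
        if g
    )
    return ClusterSolution(
        clusters=clusters,
        mode="constrained",
        reference=reference,
        absent_labels=absent,
    )


def centroid_distance(c1: Cluster, c2: Cluster) -> float:
    """Euclidean distance between two cluster centroids in the phase plane."""
    return float(np.hypot(c1.centroid[0] - c2.centroid[0],
                          c1.centroid[1] - c2.centroid[1]))
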