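"""Cascade k-means over retained ordination axes with Calinski-Harabasz
model selection.

For each k in a contiguous range, the best of many restarted Lloyd runs
(lowest within-cluster sum of squares) is scored by the Calinski-Harabasz
criterion CH(k) = (B/(k-1)) / (W/(n-k)), where W is the within-cluster and
B the between-cluster sum of squares.  The selected group count is the
smallest k that is a local maximum of CH (edges compared one-sided); when
CH is monotone over the range the selection falls on an edge and the
``boundary_flag`` is raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import MorphodispError


@dataclass
class PartitionResult:
    k: int
    assignment: np.ndarray  # per-point cluster index, 0..k-1
    within_ss: float
    ch: float

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        counts = np.bincount(self.assignment, minlength=self.k)
        if np.any(counts == 0):
            raise MorphodispError(f"k={self.k}: empty cluster in partition")
        if self.within_ss < -1e-9:
            raise MorphodispError("negative within-cluster sum of squares")


@dataclass
class CascadeResult:
    partitions: dict[int, PartitionResult]
    chosen_k: int
    boundary_flag: bool

    @property
    def best(self) -> PartitionResult:
        return self.partitions[self.chosen_k]

    def ch_sequence(self) -> dict[int, float]:
        return {k: p.ch for k, p in sorted(self.partitions.items())}


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    return arr.reshape(-1, 1) if arr.ndim == 1 else arr


def calinski_harabasz(assignment, points) -> float:
    """Calinski-Harabasz score of a partition; +inf when W = 0.

    ``assignment`` may be a label array or a :class:`PartitionResult`.
    Undefined (raises) for k = 1 or k = n.
    """
    if isinstance(assignment, PartitionResult):
        assignment = assignment.assignment
    points = _as_points(points)
    assignment = np.asarray(assignment, dtype=int)
    n = points.shape[0]
    labels = np.unique(assignment)
    k = len(labels)
    if k < 2 or k >= n:
        raise MorphodispError(f"CH undefined for k={k} with n={n}")
    w = 0.0
    for lab in labels:
        sub = points[assignment == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    total = float(((points - points.mean(axis=0)) ** 2).sum())
    b = total - w
    if w <= 1e-300:
        return math.inf
    return (b / (k - 1)) / (w / (n - k))


def kmeans_restarts(
    points: np.ndarray, k: int, restarts: int = 100, seed: int = 0
) -> PartitionResult:
    """Best of ``restarts`` Lloyd runs from random-point initial centroids.

    Deterministic given ``seed``; empty clusters are repaired by relocating
    the centroid to the point farthest from its own.
    """
    points = _as_points(points)
    n = points.shape[0]
    if not 2 <= k <= n - 1:
        raise MorphodispError(f"k={k} outside valid range 2..{n - 1}")
    if restarts < 1:
        raise MorphodispError("restarts must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        max_iter=300,
        algorithm="lloyd",
        random_state=int(seed) % (2**31 - 1),
    ).fit(points)
    labels = km.labels_.astype(int)
    return PartitionResult(
        k=k,
        assignment=labels,
        within_ss=float(km.inertia_),
        ch=calinski_harabasz(labels, points),
    )


def cascade_select(
    points: np.ndarray,
    k_min: int = 3,
    k_max: int = 7,
    restarts: int = 100,
    seed: int = 0,
) -> CascadeResult:
    """Run k-means for k in [k_min, k_max] and pick the first CH optimum.

    The chosen k is the smallest local maximum of CH over the cascade
    (ties break toward smaller k); if no interior two-sided optimum exists
    the edge optimum is returned with ``boundary_flag=True``.
    """
    points = _as_points(points)
    n = points.shape[0]
    if not (2 <= k_min < k_max <= n - 1):
        raise MorphodispError(
            f"invalid cascade range {k_min}..{k_max} for n={n}"
        )
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=k_max - k_min + 1)
    partitions = {
        k: kmeans_restarts(points, k, restarts=restarts, seed=int(s))
        for k, s in zip(range(k_min, k_max + 1), sub_seeds)
    }
    ks = sorted(partitions)
    chosen_i, boundary = first_local_max([partitions[k].ch for k in ks])
    return CascadeResult(
        partitions=partitions,
        chosen_k=ks[chosen_i],
        boundary_flag=boundary,
    )


def first_local_max(ch: "list[float]") -> tuple[int, bool]:
    """Index of the first local maximum of a CH sequence, plus boundary flag.

    A position is a local maximum when its CH is >= both neighbours (edges
    compared one-sided); ties break toward the smaller index.  The flag is
    True when no *interior* two-sided optimum exists, i.e. the sequence is
    monotone and the optimum falls on an edge.
    """
    local_max = []
    for i in range(len(ch)):
        left_ok = i == 0 or ch[i] >= ch[i - 1]
        right_ok = i == len(ch) - 1 or ch[i] >= ch[i + 1]
        if left_ok and right_ok:
            local_max.append(i)
    interior = any(0 < i < len(ch) - 1 for i in local_max)
    return local_max[0], not interior
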