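"""Principal coordinates analysis (classical metric scaling).

The dissimilarity matrix D is squared, double-centered to the Gram matrix
B = -1/2 J D^2 J (J = I - 11'/n), and eigendecomposed.  Coordinates are the
eigenvectors scaled by the square roots of their (positive) eigenvalues.
Gower dissimilarities need not be Euclidean, so negative eigenvalues can
occur; they are dropped from both the coordinates and the variance-explained
denominator (no Cailliez/Lingoes correction), matching the default behaviour
of the classical-scaling routines used in morphometric practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import MorphodispError
from .gower import DissimilarityMatrix

#: relative eigenvalue tolerance: |lambda| <= EIG_RTOL * max|lambda| is zero
EIG_RTOL = 1e-9


@dataclass
class OrdinationResult:
    """PCoA scores, eigenvalues, variance shares and the retained-axis count."""

    taxa: list[str]
    coordinates: np.ndarray  # n_taxa x n_positive_axes
    eigenvalues: np.ndarray  # all n eigenvalues, non-increasing
    variance_explained: np.ndarray  # per positive axis, sums to 1
    n_retained: int

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise MorphodispError("eigenvalues not sorted non-increasing")
        if self.coordinates.shape[1] != len(self.variance_explained):
            raise MorphodispError("coordinate axes != variance shares")
        if len(self.variance_explained) and abs(self.variance_explained.sum() - 1) > 1e-9:
            raise MorphodispError("variance shares do not sum to 1")
        if self.n_retained > self.coordinates.shape[1]:
            raise MorphodispError(
                f"n_retained={self.n_retained} exceeds "
                f"{self.coordinates.shape[1]} positive axes"
            )

    @property
    def retained(self) -> np.ndarray:
        """Scores on the retained axes only (taxa x n_retained)."""
        return self.coordinates[:, : self.n_retained]

    def scores_for(self, taxa: list[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa]
        return self.retained[idx]


def double_center(d: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    """Gram matrix B = -1/2 J D^2 J of a dissimilarity matrix."""
    dd = d.d if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)
    n = dd.shape[0]
    a = -0.5 * dd**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DissimilarityMatrix, n_retained: int | None = None) -> OrdinationResult:
    """Classical-scaling ordination of a dissimilarity matrix (n >= 3).

    ``n_retained`` defaults to all positive axes; use :func:`retain_axes`
    to apply a retention policy afterwards.
    """
    if d.n < 3:
        raise MorphodispError(f"PCoA requires >= 3 taxa, got {d.n}")
    b = double_center(d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = EIG_RTOL * max(np.max(np.abs(eigval)), 1e-300)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total = eigval[pos].sum()
    shares = eigval[pos] / total if total > 0 else eigval[pos]
    k = int(pos.sum()) if n_retained is None else int(n_retained)
    return OrdinationResult(
        taxa=list(d.taxa),
        coordinates=coords,
        eigenvalues=eigval,
        variance_explained=shares,
        n_retained=k,
    )


def retain_axes(
    o: OrdinationResult,
    n_axes: int | None = None,
    scree_ratio: float | None = None,
) -> OrdinationResult:
    """Set the retained-axis count by a fixed-k or scree-drop policy.

    ``n_axes`` retains exactly that many positive axes.  ``scree_ratio=r``
    retains axes up to (and including) the first axis whose variance share
    exceeds its successor's by a factor >= r; if no such drop occurs, all
    positive axes are retained.
    """
    if (n_axes is None) == (scree_ratio is None):
        raise MorphodispError("specify exactly one of n_axes / scree_ratio")
    n_pos = o.coordinates.shape[1]
    if n_axes is not None:
        if not 1 <= n_axes <= n_pos:
            raise MorphodispError(
                f"fixed axis count {n_axes} outside 1..{n_pos} positive axes"
            )
        return replace(o, n_retained=int(n_axes))
    shares = o.variance_explained
    k = n_pos
    for i in range(n_pos - 1):
        if shares[i + 1] > 0 and shares[i] / shares[i + 1] >= scree_ratio:
            k = i + 1
            break
        if shares[i + 1] == 0:
            k = i + 1
            break
    return replace(o, n_retained=k)


def write_ordination(o: OrdinationResult, scores_path, eigen_path) -> None:
    """Dump taxon scores and the eigenvalue table as TSVs."""
    import pandas as pd

    axes = [f"axis{i + 1}" for i in range(o.coordinates.shape[1])]
    pd.DataFrame(o.coordinates, index=o.taxa, columns=axes).to_csv(
        scores_path, sep="\t"
    )
    tab = pd.DataFrame({"eigenvalue": o.eigenvalues})
    ve = np.full(len(o.eigenvalues), np.nan)
    ve[: len(o.variance_explained)] = o.variance_explained
    tab["variance_explained"] = ve
    tab.to_csv(eigen_path, sep="\t", index=False)
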