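"""Generalized Gower dissimilarity for mixed-type character data.

For taxa *i*, *j* and characters *k* the dissimilarity is

    d_ij = sum_k w_ijk * delta_ijk / sum_k w_ijk

where ``delta_ijk`` is the per-character partial dissimilarity and ``w_ijk``
is 0 when the pair is not comparable on character *k* (either state missing,
or joint absence of an asymmetric binary character) and 1 otherwise.
Per-type partial dissimilarities:

* numeric:  |a - b| / R_k with R_k the observed range of the column;
* ordinal:  states replaced by their rank among the column's declared levels,
  then treated as numeric over the observed rank range;
* nominal / binary: 0 on match, 1 on mismatch.

All column weights are 1 by default; an optional per-character weight vector
is accepted for sensitivity work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .errors import MorphodispError, NoComparableCharactersError
from .matrix_io import MISSING, CharacterMatrix, CharacterSpec


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise Gower dissimilarities in [0, 1].

    ``comparable_weight[i, j]`` is the summed character weight actually used
    for the pair — the effective number of comparable characters.
    """

    taxa: list[str]
    d: np.ndarray
    comparable_weight: np.ndarray
    #: Gower dissimilarities live in [0, 1]; set False to carry a general
    #: non-negative dissimilarity (e.g. Euclidean distances) into PCoA.
    unit_interval: bool = True

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.comparable_weight = np.asarray(self.comparable_weight, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise MorphodispError(f"dissimilarity shape {self.d.shape} for {n} taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise MorphodispError("dissimilarity matrix not symmetric")
        if np.any(self.d < -1e-12):
            raise MorphodispError("negative dissimilarities")
        if self.unit_interval and np.any(self.d > 1 + 1e-12):
            raise MorphodispError("dissimilarities outside [0, 1]")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise MorphodispError("nonzero self-dissimilarity")
        off = ~np.eye(n, dtype=bool)
        if np.any(self.comparable_weight[off] <= 0):
            i, j = np.argwhere((self.comparable_weight <= 0) & off)[0]
            raise NoComparableCharactersError(
                f"taxa {self.taxa[i]!r} and {self.taxa[j]!r} share no "
                "comparable character"
            )

    @property
    def n(self) -> int:
        return len(self.taxa)


def _rank(state: Any, spec: CharacterSpec) -> float:
    return float(spec.levels.index(str(state)))  # type: ignore[union-attr]


def partial_dissimilarity(
    a: Any, b: Any, spec: CharacterSpec, range_: float | None = None
) -> tuple[float, int]:
    """Per-character (delta, weight) for one taxon pair.

    ``range_`` is the observed column range (numeric: max-min of values;
    ordinal: max-min of level ranks) and is required for those kinds.
    Returns weight 0 when either state is MISSING, or when the character is
    asymmetric-binary and both states are its "absent" (first) level.
    """
    if a is MISSING or b is MISSING:
        return (0.0, 0)
    kind = spec.kind
    if kind == "binary_asymmetric":
        absent = spec.levels[0]  # type: ignore[index]
        if str(a) == absent and str(b) == absent:
            return (0.0, 0)
        return (0.0 if str(a) == str(b) else 1.0, 1)
    if kind in ("nominal", "binary_symmetric"):
        return (0.0 if str(a) == str(b) else 1.0, 1)
    # numeric / ordinal
    if kind == "ordinal":
        va, vb = _rank(a, spec), _rank(b, spec)
    else:
        va, vb = float(a), float(b)
    if range_ is None:
        raise MorphodispError(f"character {spec.name!r}: range required for {kind}")
    if range_ <= 0:
        if va != vb:
            raise MorphodispError(
                f"character {spec.name!r}: zero range with differing values"
            )
        return (0.0, 1)
    return (min(abs(va - vb) / range_, 1.0), 1)


def column_range(values: Sequence[Any], spec: CharacterSpec) -> float | None:
    """Observed range of a numeric/ordinal column (None for other kinds)."""
    if spec.kind == "numeric":
        obs = [float(v) for v in values if v is not MISSING]
    elif spec.kind == "ordinal":
        obs = [_rank(v, spec) for v in values if v is not MISSING]
    else:
        return None
    return max(obs) - min(obs) if obs else 0.0


def gower_matrix(
    m: CharacterMatrix, weights: Sequence[float] | None = None
) -> DissimilarityMatrix:
    """Pairwise generalized Gower dissimilarities over all characters.

    Raises :class:`NoComparableCharactersError` if any taxon pair has zero
    total comparable weight.
    """
    n = m.n_taxa
    if weights is None:
        weights = [1.0] * m.n_characters
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j, spec in enumerate(m.specs):
        col = m.column(j)
        miss = np.array([v is MISSING for v in col])
        if spec.kind in ("numeric", "ordinal"):
            vals = np.array(
                [
                    (_rank(v, spec) if spec.kind == "ordinal" else float(v))
                    if not mi
                    else np.nan
                    for v, mi in zip(col, miss)
                ]
            )
            rng = column_range(col, spec)
            diff = np.abs(vals[:, None] - vals[None, :])
            delta = diff / rng if rng > 0 else np.zeros((n, n))
            np.clip(delta, 0.0, 1.0, out=delta)
            w = np.outer(~miss, ~miss).astype(float)
            delta = np.where(w > 0, np.nan_to_num(delta), 0.0)
        else:
            labels = np.array([str(v) if not mi else "" for v, mi in zip(col, miss)])
            delta = (labels[:, None] != labels[None, :]).astype(float)
            w = np.outer(~miss, ~miss).astype(float)
            if spec.kind == "binary_asymmetric":
                absent = labels == spec.levels[0]  # type: ignore[index]
                w *= 1.0 - np.outer(absent, absent)
            delta *= w
        num += weights[j] * delta * w
        den += weights[j] * w
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(n, dtype=bool)
    if np.any(den[off] <= 0):
        i, j = np.argwhere((den <= 0) & off)[0]
        raise NoComparableCharactersError(
            f"taxa {m.taxa[i]!r} and {m.taxa[j]!r} share no comparable character"
        )
    return DissimilarityMatrix(taxa=list(m.taxa), d=d, comparable_weight=den)


def write_dissimilarity(dm: DissimilarityMatrix, path) -> None:
    """Dump the square dissimilarity matrix as TSV with taxon labels."""
    import pandas as pd

    pd.DataFrame(dm.d, index=dm.taxa, columns=dm.taxa).to_csv(path, sep="\t")
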