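"""Character-axis association via binned contingency tables.

Each retained ordination axis is cut into ``n_bins`` intervals of equal
length over its realized score range; for every character, the observed
(non-missing) states are cross-tabulated against the bins, and the table is
summarized by an uncorrected Pearson chi-square test and Cramér's V

    V = sqrt(chi2 / (n * (min(r, c) - 1)))

— the categorical analogue of a PCA loading.  Rows/columns with zero margin
are dropped before testing; a table reduced below 2x2 yields an UNDEFINED
cell (``v`` and ``p`` set to None), which is propagated, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContinuousCharacterError, DegenerateAxisError, MorphodispError
from .matrix_io import MISSING, CharacterMatrix
from .pcoa import OrdinationResult


@dataclass
class AssociationCell:
    """One character x axis association entry (a machine-readable table cell)."""

    character: str
    axis: int  # 1-based retained-axis index
    v: float | None
    chi2: float | None
    df: int | None
    p: float | None
    n_used: int
    significant: bool

    @property
    def defined(self) -> bool:
        return self.v is not None


@dataclass
class AssociationReport:
    cells: list[AssociationCell]
    alpha: float
    n_bins: int

    def cell(self, character: str, axis: int) -> AssociationCell:
        for c in self.cells:
            if c.character == character and c.axis == axis:
                return c
        raise KeyError((character, axis))

    def v_table(self) -> pd.DataFrame:
        """Characters x axes grid of Cramér's V (NaN where undefined)."""
        return self._pivot("v")

    def p_table(self) -> pd.DataFrame:
        return self._pivot("p")

    def _pivot(self, attr: str) -> pd.DataFrame:
        rows: dict[str, dict[str, float]] = {}
        for c in self.cells:
            val = getattr(c, attr)
            rows.setdefault(c.character, {})[f"axis{c.axis}"] = (
                math.nan if val is None else val
            )
        chars = list(dict.fromkeys(c.character for c in self.cells))
        return pd.DataFrame.from_dict(rows, orient="index").loc[chars]

    def significant_on(self, axis: int) -> list[AssociationCell]:
        """Cells significant on an axis — the numbers behind a per-axis
        influence summary (relative p and V shares)."""
        return [c for c in self.cells if c.axis == axis and c.significant]


def bin_axis(scores, n_bins: int = 4) -> np.ndarray:
    """Assign each score to one of ``n_bins`` equal-length intervals (1-based).

    Intervals are left-closed right-open except the last, which is closed;
    constant scores raise :class:`DegenerateAxisError`.
    """
    scores = np.asarray(scores, dtype=float)
    if n_bins < 2:
        raise MorphodispError("n_bins must be >= 2")
    lo, hi = scores.min(), scores.max()
    if hi <= lo:
        raise DegenerateAxisError("axis scores are constant; cannot bin")
    width = (hi - lo) / n_bins
    bins = np.floor((scores - lo) / width).astype(int) + 1
    return np.clip(bins, 1, n_bins)


def _drop_zero_margins(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def chi_square_p(table) -> tuple[float, int, float] | None:
    """Uncorrected Pearson chi-square (statistic, df, p) of a count table.

    Zero-margin rows/columns are dropped first; returns None (UNDEFINED)
    when fewer than two rows or columns remain.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or table.sum() <= 0:
        raise MorphodispError("contingency table must be non-negative, non-empty")
    t = _drop_zero_margins(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        return None
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def cramers_v(table) -> float | None:
    """Cramér's V of a count table; None (UNDEFINED) for degenerate tables."""
    res = chi_square_p(table)
    if res is None:
        return None
    chi2, _, _ = res
    t = _drop_zero_margins(np.asarray(table, dtype=float))
    n = t.sum()
    v = math.sqrt(chi2 / (n * (min(t.shape) - 1)))
    return min(v, 1.0)


def _discrete_states(values: list[Any], spec) -> list[Any]:
    """Observed states as hashable categories; rejects continuous numerics."""
    if spec.kind != "numeric":
        return [str(v) for v in values]
    out = []
    for v in values:
        r = round(float(v))
        if abs(float(v) - r) > 1e-9:
            raise ContinuousCharacterError(
                f"character {spec.name!r}: non-discrete numeric value {v!r}; "
                "binned association requires discrete states"
            )
        out.append(int(r))
    return out


def associate_all(
    m: CharacterMatrix,
    o: OrdinationResult,
    n_bins: int = 4,
    alpha: float = 0.05,
    correction: str = "none",
) -> AssociationReport:
    """Cross-tabulate every character against every retained axis.

    Bin edges come from the realized score range over all ordinated taxa;
    taxa missing a character are dropped pairwise for that character's
    tables (``n_used`` records the drop).  ``correction="holm"`` flags
    significance on Holm-adjusted p-values instead of raw ones (off by
    default).
    """
    if m.taxa != o.taxa:
        raise MorphodispError("matrix and ordination taxa differ")
    if correction not in ("none", "holm"):
        raise MorphodispError(f"unknown correction {correction!r}")
    axis_bins = {
        ax: bin_axis(o.retained[:, ax], n_bins) for ax in range(o.n_retained)
    }
    cells: list[AssociationCell] = []
    for j, spec in enumerate(m.specs):
        col = m.column(j)
        present = [i for i, v in enumerate(col) if v is not MISSING]
        states = _discrete_states([col[i] for i in present], spec)
        for ax in range(o.n_retained):
            bins = axis_bins[ax][present]
            tab = pd.crosstab(pd.Series(states), pd.Series(bins)).to_numpy()
            res = chi_square_p(tab) if tab.size else None
            if res is None:
                cells.append(
                    AssociationCell(spec.name, ax + 1, None, None, None, None,
                                    len(present), False)
                )
            else:
                chi2, df, p = res
                cells.append(
                    AssociationCell(spec.name, ax + 1, cramers_v(tab), chi2, df,
                                    p, len(present), p <= alpha)
                )
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        defined = [c for c in cells if c.p is not None]
        if defined:
            reject, _, _, _ = multipletests(
                [c.p for c in defined], alpha=alpha, method="holm"
            )
            for c, r in zip(defined, reject):
                c.significant = bool(r)
    return AssociationReport(cells=cells, alpha=alpha, n_bins=n_bins)


def write_association_table(report: AssociationReport, path) -> None:
    """Dump the report as a wide TSV: V per axis then p per axis."""
    v = report.v_table().add_prefix("V_")
    p = report.p_table().add_prefix("p_")
    pd.concat([v, p], axis=1).to_csv(path, sep="\t", index_label="character")
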