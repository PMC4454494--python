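"""Per-group disparity from retained-axis score variances.

For each group the sample variance (n-1 divisor) of its members' scores is
taken on every retained ordination axis.  The per-axis variance list is then
summarized by its median, its sum (total variance, the classical disparity
measure) and its own sample variance — the variance of variances, which
quantifies how unevenly a group's plasticity is distributed across the main
directions of the morphospace.

Note on geometry: the sum of variances is invariant under rigid rotation of
the retained axes (trace invariance), but the median and the variance of
variances are axis-dependent by design — they measure spread *across* the
ordination's own axes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np

from .errors import MorphodispError
from .matrix_io import GroupScheme
from .pcoa import OrdinationResult


@dataclass
class GroupDisparity:
    axis_variances: list[float] | None  # None when n_members < 2
    median_v: float | None
    sum_v: float | None
    vov: float | None  # variance (n-1) of the axis-variance list
    n_members: int


@dataclass
class DisparityReport:
    scheme: str
    per_group: dict[str, GroupDisparity]
    excluded: list[str]

    def ranking(self, by: str = "median_v") -> list[str]:
        """Group labels sorted by a summary statistic, largest first."""
        defined = {
            g: getattr(d, by)
            for g, d in self.per_group.items()
            if getattr(d, by) is not None
        }
        return sorted(defined, key=lambda g: -defined[g])


def group_axis_variances(
    o: OrdinationResult, scheme: GroupScheme
) -> dict[str, np.ndarray | None]:
    """Sample variance of member scores per retained axis, per group.

    EXCLUDED taxa are omitted; groups with fewer than two members map to
    None rather than raising.
    """
    known = set(o.taxa)
    out: dict[str, np.ndarray | None] = {}
    for group, members in scheme.groups().items():
        missing = [t for t in members if t not in known]
        if missing:
            raise MorphodispError(
                f"group {group!r}: taxa {missing} absent from ordination"
            )
        if len(members) < 2:
            out[group] = None
            continue
        scores = o.scores_for(members)
        out[group] = scores.var(axis=0, ddof=1)
    return out


def disparity_summary(
    variances: dict[str, np.ndarray | None],
    scheme: GroupScheme | None = None,
    scheme_name: str = "",
) -> DisparityReport:
    """Summarize per-group axis variances into a DisparityReport."""
    if not any(v is not None for v in variances.values()):
        raise MorphodispError("no group with computable variances")
    members = scheme.groups() if scheme is not None else {}
    per_group: dict[str, GroupDisparity] = {}
    for group, v in variances.items():
        n = len(members.get(group, []))  # 0 when the scheme is unknown
        if v is None:
            per_group[group] = GroupDisparity(None, None, None, None, n)
            continue
        vals = [float(x) for x in v]
        vov = statistics.variance(vals) if len(vals) >= 2 else 0.0
        per_group[group] = GroupDisparity(
            axis_variances=vals,
            median_v=statistics.median(vals),
            sum_v=float(sum(vals)),
            vov=vov,
            n_members=n,
        )
    return DisparityReport(
        scheme=scheme.name if scheme is not None else scheme_name,
        per_group=per_group,
        excluded=scheme.excluded() if scheme is not None else [],
    )


def write_disparity_table(report: DisparityReport, path) -> None:
    """One row per group: axis variances, median, sum, vov, n."""
    import pandas as pd

    rows = []
    for group, d in report.per_group.items():
        row: dict[str, object] = {"group": group, "n": d.n_members}
        if d.axis_variances is not None:
            for i, v in enumerate(d.axis_variances):
                row[f"var_axis{i + 1}"] = v
        row.update(median=d.median_v, sum=d.sum_v, vov=d.vov)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
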