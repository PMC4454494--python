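"""Config-driven end-to-end morphospace/disparity run.

Stages, in order: matrix validation -> Gower dissimilarity -> PCoA ->
axis retention -> cascade k-means -> character-axis association -> per-group
disparity (one report per grouping scheme, including the scheme derived from
the chosen k-means partition).  Defaults encode the standard analysis
configuration for a discrete appendage matrix: 4 retained axes, k cascade
3..7 with 100 restarts, 4 bins, alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import __version__
from .association import AssociationReport, associate_all, write_association_table
from .clustering import CascadeResult, cascade_select
from .disparity import (
    DisparityReport,
    disparity_summary,
    group_axis_variances,
    write_disparity_table,
)
from .errors import MorphodispError, PipelineStageError, ValidationError
from .gower import gower_matrix, write_dissimilarity
from .matrix_io import (
    DEFAULT_MISSING_TOKENS,
    EXCLUDED,
    CharacterMatrix,
    GroupScheme,
    read_groups,
    read_matrix,
)

log = logging.getLogger("morphodisp")


@dataclass
class PipelineConfig:
    matrix_path: str
    spec_path: str
    out_dir: str
    groups_path: str | None = None
    n_retained: int | None = 4  # None -> scree policy
    scree_ratio: float | None = None
    k_min: int = 3
    k_max: int = 7
    restarts: int = 100
    n_bins: int = 4
    alpha: float = 0.05
    seed: int = 0
    missing_tokens: tuple[str, ...] = tuple(sorted(DEFAULT_MISSING_TOKENS))
    kmeans_excluded: tuple[str, ...] = ()  # taxa EXCLUDED from the k-means scheme

    def __post_init__(self):
        if not (2 <= self.k_min < self.k_max):
            raise MorphodispError("need 2 <= k_min < k_max")
        if self.n_bins < 2 or not 0 < self.alpha < 1 or self.restarts < 1:
            raise MorphodispError("n_bins, alpha or restarts out of range")
        if (self.n_retained is None) == (self.scree_ratio is None):
            raise MorphodispError("set exactly one of n_retained / scree_ratio")


@dataclass
class PipelineReport:
    """Self-describing result bundle with a provenance block."""

    ordination_summary: dict
    cascade: CascadeResult
    association: AssociationReport
    disparity: dict[str, DisparityReport]
    provenance: dict


def derive_kmeans_scheme(
    cascade: CascadeResult, taxa: list[str], excluded: Iterable[str] = ()
) -> GroupScheme:
    """GroupScheme from the chosen cascade partition, honoring exclusions.

    Excluded taxa keep their morphospace position and cluster membership but
    are flagged EXCLUDED so disparity omits them (the treatment given to
    taxa of uncertain affinity attached to a cluster).
    """
    excluded = set(excluded)
    assignment = {
        t: EXCLUDED if t in excluded else f"k{c + 1}"
        for t, c in zip(taxa, cascade.best.assignment)
    }
    return GroupScheme(name="kmeans", assignment=assignment)


def analyse(
    matrix: CharacterMatrix,
    schemes: Iterable[GroupScheme] = (),
    config: PipelineConfig | None = None,
    **overrides,
) -> PipelineReport:
    """Run the full analysis on an in-memory matrix; the library-side core.

    ``schemes`` are a-priori grouping schemes (e.g. body plans); the scheme
    derived from the chosen k-means partition is always appended.
    """
    from .pcoa import pcoa, retain_axes

    if config is None:
        config = PipelineConfig(
            matrix_path="<memory>", spec_path="<memory>", out_dir="<memory>",
            **overrides,
        )
    stage = "gower"
    try:
        dm = gower_matrix(matrix)
        stage = "pcoa"
        ord_full = pcoa(dm)
        if config.n_retained is not None:
            ordination = retain_axes(ord_full, n_axes=config.n_retained)
        else:
            ordination = retain_axes(ord_full, scree_ratio=config.scree_ratio)
        stage = "clustering"
        t0 = time.perf_counter()
        cascade = cascade_select(
            ordination.retained,
            k_min=config.k_min,
            k_max=config.k_max,
            restarts=config.restarts,
            seed=config.seed,
        )
        log.info("cascade: chose k=%d in %.2fs (CH=%s)", cascade.chosen_k,
                 time.perf_counter() - t0, cascade.ch_sequence())
        stage = "association"
        association = associate_all(
            matrix, ordination, n_bins=config.n_bins, alpha=config.alpha
        )
        for c in association.cells:
            if not c.defined:
                log.info("association: %s x axis %d UNDEFINED "
                         "(degenerate table, n_used=%d)", c.character, c.axis,
                         c.n_used)
        stage = "disparity"
        all_schemes = list(schemes) + [
            derive_kmeans_scheme(cascade, matrix.taxa, config.kmeans_excluded)
        ]
        disparity = {}
        for scheme in all_schemes:
            variances = group_axis_variances(ordination, scheme)
            disparity[scheme.name] = disparity_summary(variances, scheme)
    except MorphodispError as exc:
        raise PipelineStageError(stage, exc) from exc
    provenance = {
        "config": {
            f.name: list(v) if isinstance(v := getattr(config, f.name), tuple) else v
            for f in dataclasses.fields(config)
        },
        "seed": config.seed,
        "version": __version__,
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
    }
    ordination_summary = {
        "eigenvalues": [float(x) for x in ordination.eigenvalues],
        "variance_explained": [float(x) for x in ordination.variance_explained],
        "n_retained": ordination.n_retained,
        "taxa": ordination.taxa,
        "retained_scores": [[float(x) for x in row] for row in ordination.retained],
    }
    return PipelineReport(
        ordination_summary=ordination_summary,
        cascade=cascade,
        association=association,
        disparity=disparity,
        provenance=provenance,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """File-to-file pipeline: read inputs, analyse, write all reports.

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineStageError` naming the stage is raised.
    """
    from .matrix_io import write_report
    from .pcoa import pcoa, retain_axes, write_ordination

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    stage = "read"
    try:
        matrix = read_matrix(cfg.matrix_path, cfg.spec_path, cfg.missing_tokens)
        schemes: list[GroupScheme] = []
        if cfg.groups_path:
            schemes.append(read_groups(cfg.groups_path, matrix))
    except ValidationError as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        report = analyse(matrix, schemes, config=cfg)
        dm = gower_matrix(matrix)  # cheap; re-derived for the dump
        p = out / "dissimilarity.tsv"
        write_dissimilarity(dm, p)
        written.append(p)
        o = pcoa(dm)
        o = (retain_axes(o, n_axes=cfg.n_retained) if cfg.n_retained is not None
             else retain_axes(o, scree_ratio=cfg.scree_ratio))
        write_ordination(o, out / "ordination_scores.tsv", out / "eigenvalues.tsv")
        written += [out / "ordination_scores.tsv", out / "eigenvalues.tsv"]
        for name, obj in (
            ("cascade.json", report.cascade),
            ("association.json", report.association),
            ("pipeline_report.json", report),
        ):
            write_report(obj, out / name)
            written.append(out / name)
        write_association_table(report.association, out / "association_table.tsv")
        written.append(out / "association_table.tsv")
        for scheme_name, disp in report.disparity.items():
            write_report(disp, out / f"disparity_{scheme_name}.json")
            write_disparity_table(disp, out / f"disparity_{scheme_name}.tsv")
            written += [out / f"disparity_{scheme_name}.json",
                        out / f"disparity_{scheme_name}.tsv"]
    except PipelineStageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return report
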