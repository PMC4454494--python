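"""Per-group disparity: axis variances, their median, sum and spread.

Compares an a-priori body-plan grouping with the data-driven k-means
grouping.  Disparity is summarized per group as the median, sum and
variance (vov) of the per-axis score variances; vov measures how unevenly
a group's plasticity is spread across the morphospace axes.
"""

from morphodisp import (
    cascade_select,
    derive_kmeans_scheme,
    disparity_summary,
    gower_matrix,
    group_axis_variances,
    pcoa,
    retain_axes,
    synthetic_reference,
)

matrix, body_plan, _ = synthetic_reference()
ordination = retain_axes(pcoa(gower_matrix(matrix)), n_axes=4)

cascade = cascade_select(ordination.retained, 3, 7, restarts=100, seed=1)
kmeans_scheme = derive_kmeans_scheme(cascade, matrix.taxa,
                                     excluded=body_plan.excluded())

for scheme in (body_plan, kmeans_scheme):
    report = disparity_summary(group_axis_variances(ordination, scheme),
                               scheme)
    print(f"\nscheme: {scheme.name} "
          f"(excluded: {', '.join(report.excluded) or 'none'})")
    print(f"{'group':<8}{'n':>3}{'median':>10}{'sum':>10}{'vov':>12}")
    for group, d in sorted(report.per_group.items()):
        if d.axis_variances is None:
            print(f"{group:<8}{d.n_members:>3}{'--':>10}")
            continue
        print(f"{group:<8}{d.n_members:>3}{d.median_v:>10.4f}"
              f"{d.sum_v:>10.4f}{d.vov:>12.3e}")
    ranking = report.ranking("median_v")
    print(f"median-disparity ranking: {' > '.join(ranking)}")

print("\nThe body-plan group uniting two distinct morphotype clusters (DIN) "
      "shows the\nlargest median disparity; data-driven clusters are more "
      "homogeneous by design.")
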