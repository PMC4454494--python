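"""Cascade k-means over the morphospace with Calinski-Harabasz selection.

Runs restarted k-means for k = 3..7 on the four retained PCoA axes of the
reference matrix and selects the first CH optimum; then compares the chosen
partition with the known latent morphotype clusters.
"""

from morphodisp import (
    adjusted_rand,
    cascade_select,
    gower_matrix,
    pcoa,
    retain_axes,
    synthetic_reference,
)

matrix, _, clusters = synthetic_reference()
ordination = retain_axes(pcoa(gower_matrix(matrix)), n_axes=4)

cascade = cascade_select(ordination.retained, k_min=3, k_max=7,
                         restarts=100, seed=1)
print("Calinski-Harabasz by k:")
for k, ch in cascade.ch_sequence().items():
    marker = "  <- first optimum" if k == cascade.chosen_k else ""
    print(f"  k={k}: CH={ch:7.2f}{marker}")
print(f"\nchosen k = {cascade.chosen_k} "
      f"(boundary_flag={cascade.boundary_flag})")

labels = {t: f"k{c}" for t, c in zip(matrix.taxa, cascade.best.assignment)}
ari = adjusted_rand(labels, clusters.assignment)
print(f"adjusted Rand vs latent clusters: {ari:.3f} "
      "(1 = perfect recovery of the six morphotypes)")
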