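"""Cluster-recovery benchmark on generated matrices with known structure.

Generates mixed-type matrices with three latent groups at a 5-sd separation
and 10% missing data, runs the full ordination + cascade pipeline, and
scores recovery of the true group count and labels.
"""

import numpy as np

from morphodisp import (
    SyntheticSpec,
    adjusted_rand,
    cascade_select,
    generate_matrix,
    gower_matrix,
    pcoa,
    retain_axes,
)

n_runs = 10
hits, aris = 0, []
for seed in range(n_runs):
    spec = SyntheticSpec(
        n_taxa=60,
        char_counts={"numeric": 3, "ordinal": 3, "nominal": 3,
                     "binary_symmetric": 3},
        n_groups=3,
        separation=5.0,
        missing_rate=0.1,
        seed=seed,
    )
    matrix, truth = generate_matrix(spec)
    ordination = retain_axes(pcoa(gower_matrix(matrix)), n_axes=4)
    cascade = cascade_select(ordination.retained, 2, 7, restarts=100,
                             seed=seed)
    hits += cascade.chosen_k == 3
    labels = {t: f"k{c}" for t, c in
              zip(matrix.taxa, cascade.partitions[3].assignment)}
    aris.append(adjusted_rand(labels, truth.assignment))
    print(f"seed {seed}: chosen k = {cascade.chosen_k}, "
          f"ARI at k=3: {aris[-1]:.3f}")

print(f"\ntrue k recovered in {hits}/{n_runs} runs; "
      f"mean ARI {np.mean(aris):.3f}")
print("ARI of 1 means the partition at the true k matches the latent "
      "labels exactly;\n0 means chance-level agreement.")
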