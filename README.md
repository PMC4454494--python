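# morphodisp

Morphospace occupancy and disparity analysis for mixed-type morphological
character matrices, built for discrete (often fossil) datasets such as
arthropod appendage characters: taxa scored on a handful of numeric counts,
ordinal, nominal and binary characters, with missing entries.

The pipeline chains five classical phenetic steps:

1. **Generalized Gower dissimilarity** — for taxa *i*, *j*:
   `d_ij = Σ_k w_ijk δ_ijk / Σ_k w_ijk`, with per-character partial
   dissimilarities δ (numeric/ordinal: `|a−b|/range`, ordinal states taken
   as level ranks; nominal/binary: 0/1 mismatch) and weights w_ijk = 0 for
   missing states or joint absence of an asymmetric binary character.
2. **Principal coordinates analysis** — classical scaling of the
   dissimilarity matrix via the double-centered Gram matrix
   `B = −½ J D² J`; negative eigenvalues (Gower need not be Euclidean) are
   dropped; a fixed number of axes (default 4) or a scree rule is retained.
3. **Cascade k-means** — restarted Lloyd k-means for k over a range
   (default 3..7), each k scored by the Calinski-Harabasz criterion
   `CH(k) = (B/(k−1)) / (W/(n−k))`; the smallest local CH maximum is the
   chosen group count.
4. **Character-axis association** — each retained axis is cut into four
   equal-length intervals; characters are cross-tabulated against the bins
   and summarized by Cramér's V, `V = √(χ² / (n·(min(r,c)−1)))`, with
   uncorrected chi-square p-values — the categorical analogue of loadings.
5. **Disparity** — per group, the sample variance of scores on each
   retained axis; summarized by the median, the sum (total variance) and
   the *variance of variances*, which measures how unevenly a group's
   plasticity spreads across axes.

A synthetic-data module generates mixed-type matrices with known latent
group structure, effect size and missingness, so every stage is testable
without external data; `morphodisp.datasets.synthetic_reference()` builds a
36×12 six-cluster reference matrix emulating the statistical shape of a
frontalmost-appendage dataset (the original is only available as a
word-processor supplement, so the bundled matrix is synthetic by
construction and labelled as such).

## Worked example

```python
from morphodisp import (adjusted_rand, cascade_select, gower_matrix,
                        pcoa, retain_axes, synthetic_reference)

matrix, body_plan, clusters = synthetic_reference()
ordination = retain_axes(pcoa(gower_matrix(matrix)), n_axes=4)
cascade = cascade_select(ordination.retained, 3, 7, restarts=100, seed=1)
print(cascade.ch_sequence(), cascade.chosen_k)
```

prints (see `examples/02_cascade_clusters.py`):

```
Calinski-Harabasz by k:
  k=3: CH=  20.40
  k=4: CH=  23.27
  k=5: CH=  31.27
  k=6: CH=  32.62  <- first optimum
  k=7: CH=  30.98

chosen k = 6 (boundary_flag=False)
adjusted Rand vs latent clusters: 0.942 (1 = perfect recovery of the six morphotypes)
```

CH rises to a first local maximum at k = 6 — the cascade recovers the six
latent morphotype clusters — and the chosen partition agrees with the truth
at ARI 0.94.  The other scripts in `examples/` walk through the Gower/PCoA
step, the Cramér's V association table, the two disparity schemes
(body-plan vs k-means, including an excluded "problematica" taxon), and the
cluster-recovery benchmark.

Command-line use on transcribed data:

```sh
morphodisp run --matrix matrix.tsv --spec characters.yaml \
    --groups bodyplans.tsv --axes 4 --k-min 3 --k-max 7 --out results/
morphodisp simulate --out sim/ --n-taxa 60 --n-groups 3 --separation 5
```

Input dialect: UTF-8 TSV (first column taxon id, header naming characters),
a YAML character specification (name, kind, levels), optional two-column
taxon→group TSV; missing tokens default to `NA`, `?` and empty.

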