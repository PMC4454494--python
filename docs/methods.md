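# Methods

## Scope and model

`morphodisp` quantifies how a sample of taxa occupies a morphospace built
from discrete, mixed-type characters, and how morphological variation
(disparity) is distributed among taxon groups.  The intended data are
small matrices — tens of taxa, on the order of a dozen characters — where
characters are numeric counts, ordinal grades, nominal states or binary
presence/absence, and where missing entries are unavoidable (fossils
preserve incompletely).  Nothing in the pipeline assumes a phylogeny;
groups are either supplied a priori (e.g. body plans) or derived from the
data by clustering.

## Dissimilarity

The generalized Gower coefficient averages per-character partial
dissimilarities over the characters observed for both taxa:

    d_ij = Σ_k w_ijk δ_ijk / Σ_k w_ijk

- numeric: δ = |a − b| / R_k, with R_k the observed (non-missing) range of
  column k, recomputed per dataset;
- ordinal: states are replaced by their rank in the declared level order
  and then treated as numeric over the observed rank range (the standard
  generalized-Gower convention; equal spacing between adjacent levels is
  an assumption, not a fact about the characters);
- nominal and symmetric binary: δ = 0 on match, 1 on mismatch;
- asymmetric binary: as symmetric, except joint absence gets weight 0 —
  shared absence of a structure is treated as non-information;
- any missing state gives that character weight 0 for the pair.

Column weights are all 1 by default (a per-character weight hook exists
but is not used by the pipeline).  A taxon pair with no comparable
character is an error, not a guess.  The implementation is verified
against a per-cell brute-force oracle and against the reference mixed-Gower
routine in R (`cluster::daisy`) in the test suite.

## Ordination

Classical scaling (PCoA): B = −½ J D² J is eigendecomposed; coordinates
are eigenvectors scaled by √λ.  Gower matrices need not be Euclidean, so
negative eigenvalues occur; they are dropped from both the coordinates and
the variance-explained denominator, with no Cailliez or Lingoes
correction — matching the default of the classical-scaling routines in
common statistical environments.  Eigenvalues with |λ| ≤ 1e−9·max|λ| are
treated as zero.

Axis retention is a policy, not an inference: the default for analysing a
real matrix is a fixed four axes (the number a scree inspection of this
kind of dataset typically supports); a scree-drop rule (retain axes up to
the first ≥r-fold drop in variance share) is available for synthetic work
but is sensitive to near-ties in the spectrum and is not the default.

## Clustering and group-count selection

For each k in a contiguous range (default 3..7) the best of 100 restarted
Lloyd runs (random-point initialization, ≤300 iterations, empty clusters
repaired by relocation to far points; `scikit-learn`'s KMeans provides the
engine) is scored by Calinski-Harabasz.  The chosen k is the smallest
local maximum of CH over the cascade — the "first optimum" stopping rule —
with edges compared one-sided and ties broken toward smaller k (fewer
groups is the more parsimonious reading).  When CH is monotone over the
range the selection necessarily falls on an edge and the result carries a
`boundary_flag` so the user knows the optimum was not interior.  A
partition with zero within-group variance gets CH = +INF.

## Character-axis association

Each retained axis is divided into four intervals of equal length over the
realized score range (left-closed, right-open, last closed).  For each
character, taxa missing that character are dropped pairwise (`n_used`
records the drop), the remaining states are cross-tabulated against the
bins, zero-margin rows/columns are removed, and the table is summarized by
the uncorrected Pearson chi-square and Cramér's V.  Tables reduced below
2×2 yield UNDEFINED cells, propagated rather than raised.  V and the
significance flag are carried independently: with small usable samples a
V near 1 can still be non-significant.  No multiple-testing correction is
applied by default (the association grid is descriptive, loading-like);
Holm adjustment of the significance flags is available as an option.
Characters must be discrete-valued to cross-tabulate; a numeric character
with non-integer observed values is rejected with a clear error rather
than silently binned.

## Disparity

Per group, the sample variance (n−1) of member scores on each retained
axis.  Summaries per group: median of the axis variances, their sum, and
their sample variance ("variance of variances", vov).  The sum is
invariant under rigid rotation of the retained axes (trace invariance);
the median and vov are deliberately axis-dependent — they describe how
unevenly variation is spread across the ordination's own axes, which is
the quantity of interest when axes carry interpretable character
associations.  Groups with fewer than two members get null entries, and
taxa flagged EXCLUDED in a scheme are carried through the pipeline but
omitted from variance computations (the treatment used for a taxon of
uncertain affinity attached to a cluster).  Both an a-priori scheme and
the scheme derived from the chosen k-means partition are first-class.

## Synthetic data

`generate_matrix` draws matrices with known structure: taxa are split
near-evenly among `n_groups`; numeric characters place group centers on an
equally spaced grid with step `separation` (assignment permuted per
character) and add unit-variance noise, so adjacent groups differ by
exactly `separation` within-group standard deviations; categorical
characters give each group a modal state with mixture weight
(1+s)/(L+s) over L levels, the remainder uniform — at s = 0 every kind is
uninformative, which the tests verify via near-zero adjusted Rand index.
Numeric draws are integer-rounded (count-like) so generated matrices pass
the discrete-state requirement of the association stage.  Entries are
masked missing completely at random.  All draws come from one seeded
generator in documented order (groups, then characters in matrix order,
then the missingness mask).

The generator emulates group structure, kind mixture and MCAR missingness.
It does **not** emulate phylogenetically correlated character evolution,
character-character correlation beyond group membership, or
taphonomically biased (non-random) missingness — so passing recovery tests
demonstrate the pipeline's behaviour under clean clustered signal, not
robustness to those real-data features.

### The bundled reference matrix

`datasets.synthetic_reference()` is a fixed synthetic 36-taxon × 12-character
instance emulating the statistical shape of a published frontalmost-appendage
dataset whose deposited matrix exists only as a word-processor document and
is therefore not redistributable as text.  Six hand-designed cluster
archetypes (lobopod-like, *Anomalocaris*-type, *Hurdia*-type, mixed
paired-spine, short-great-appendage/chelicera, antennulate) differ most
strongly between the two raptorial types; taxa are noisy archetype copies
(15% state resampling, 8% MCAR missingness).  A body-plan overlay mirrors
how systematic groups cut across morphotype clusters: the dinocaridid
group unites the two most distinct clusters, the stem-bivalved group
scatters across several, and one "problematica" taxon rides with a cluster
but is EXCLUDED from variance computations.  By construction this makes
the dinocaridid group the most disparate and the bivalved group second —
the qualitative pattern the dataset exists to emulate — and gives the
cascade a clean CH optimum at six groups.  The instance is identified by
its generation seed (default 0); analyses treat it as a fixed input, with
run seeds driving only the clustering restarts.

## Determinism and numerics

Every stochastic component (k-means restarts, cascade sub-seeds, synthetic
draws) flows from explicit integer seeds; identical config + seed yields
byte-identical report files (JSON with sorted keys, full-precision floats,
infinities encoded as "+INF").  Axis signs from the eigendecomposition are
arbitrary; all downstream statistics are reflection-invariant and the
tests assert it.  Chi-square p-values come from the scipy chi-square
survival function; CH uses exact sums of squares, not the k-means inertia
shortcut, so the score is well-defined for arbitrary partitions.

## Problem sizes used in verification

The shipped checks run the full pipeline on the 36×12 reference instance
(20 clustering seeds for the group-count stability rate) and a recovery
benchmark of twenty 60-taxon, 12-character, 3-group datasets at separation
5 with 10% missingness, cascade k = 2..7 at 100 restarts.  These sizes
mirror the intended application scale — phenetic matrices of this kind are
small — and complete in seconds.

## Known limitations

- Ordinal characters assume equally spaced ranks; a gamma-style ordered
  association statistic is not implemented.
- No correction for non-Euclidean distortion in PCoA; strongly negative
  eigenvalues shrink the variance-explained denominator silently (the
  eigenvalue table reports them).
- The scree-drop retention rule is fragile when consecutive variance
  shares are nearly equal; prefer a fixed axis count chosen by inspection.
- Disparity is not rarefied; groups of very different size are compared on
  raw variances.
- The association stage requires discrete character states; genuinely
  continuous characters would need a separate binning decision that the
  package deliberately does not make for you.
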