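# Methods

## The classification model

A cohort of reconstructed neurons from one source region is summarized by a
count matrix M (neurons × target columns), where M[i, j] is the number of
axonal tracing points of neuron i inside column j. Columns are
(parcel, hemisphere) pairs by default: contralaterally-projecting classes
exist, and a point's hemisphere is decided by which side of a configurable
midline coordinate it falls on relative to the soma. Source-region
collaterals are excluded from the classification matrix by default (classes
are defined by where axons go, not by local collaterals); a flag includes
them.

Tracing-point counts — not cable length — are the extent metric. Light
microscopy does not resolve boutons, and the longest unbranched stretches
of projection axons are typically fibers of passage; tracers place points
more densely where arbors meander through synaptic neuropil. The
`axonal_metric` module quantifies this on any cohort: branches are ordered
centripetally (Strahler: terminals are order 1; a parent takes the maximum
child order, +1 when at least two children attain it), and the point
spacing of orders 1–3 is compared with orders ≥ 4 by a one-tailed Welch
t-test on per-neuron band means. Per-neuron means are used as the test unit
because branches within one neuron are not independent; with SDs taken over
neurons the df land in the tens rather than the thousands.

### Null model

The single-class hypothesis is that neurons differ only through random
variation within the constraints of regional connectivity: neuron i keeps
its total axonal extent Σ_j M[i, j] and region j keeps its total
innervation Σ_i M[i, j], but the joint allocation is otherwise
unconstrained. The null is sampled by a swap chain: draw neurons i ≠ j and
columns a ≠ b uniformly, draw δ uniformly from {1..min(M[i,a], M[j,b])},
and move δ points across the 2×2 diagonal. Infeasible proposals
(min = 0) are rejected and do not count toward the budget of successful
swaps, which defaults to 20× the number of nonzero cells. With δ fixed at 1
the chain's stationary law is uniform on the set of non-negative integer
matrices with the given marginals (proposals are symmetric); the uniform-δ
rule mixes faster and is the default, with `delta_rule="max"` available for
sensitivity analysis. Matrices whose nonzero cells all sit in one row or
one column admit no swap; their fiber is the singleton {M} and they are
returned unchanged.

### Distance and gate

Pairwise dissimilarity is the angle between count vectors, in degrees
(variances in deg² are then on an interpretable 0–8100 scale). The angle is
computed as 2·atan2(‖û − v̂‖, ‖û + v̂‖) on the normalized vectors, which is
accurate near 0° where the arccos-of-clipped-cosine form loses half the
significant digits. Zero-count neurons have no defined angle; they are kept
in the matrix but excluded from distances and classification, and reported.

The split gate is Levene's test with the absolute-deviation center: a
one-way ANOVA of |x − group mean| across the experimental and randomized
distance samples. The gate is one-tailed: when var(exp) > var(rnd) the
reported p is half the ANOVA p; otherwise p is "not applicable" and the
node never splits, whatever the F value. α defaults to 0.05.

### Recursion

The dendrogram is built once, by average-linkage agglomeration over the
pairwise angles of all usable neurons. The root set is tested against a
fresh randomization of the full matrix; on a split the root's two dendrogram
children are each re-tested on their own submatrix (their rows, all
columns) against a fresh, independently seeded randomization — each test
conditions on its own subtree's marginals, and each failure point is
independent of the others. Subtrees below `min_subtree = 3` neurons become
classes without testing: two neurons yield a single pairwise distance, so
a variance test is impossible. Terminal classes are labeled A, B, … in
dendrogram left-to-right order with the class size appended. Recursion
depth is bounded by n − 1 and every usable neuron lands in exactly one
class.

## Population fractions (NNLS)

Bulk anterograde tracing gives each region r a weight
b_r = mean(projection volume) × mean(projection density) over the
available experiments, normalized to Σb = 1. Each class's signature is its
summed axonal counts per region, assembled into A (regions × classes) and
bi-normalized: rows to sum 1 (removes per-region scale), grand total
rescaled to k, columns to sum 1 (removes per-class extent). Note the
column normalization makes the grand-total step a mathematical no-op; it is
kept because the pipeline is specified sequentially and the intermediate
matrix is reported. Solving min ‖Ax − b‖, x ≥ 0 with active-set NNLS gives
the class mixing fractions; the squared residual is reported both raw and
as a percentage of ‖b‖². A target's afferent composition weights each
class's fraction by its mean per-neuron counts in the target (the mean, not
the class sum, since class size already enters through the fraction).

## Soma topography

Each class's soma cloud is summarized by its 3-D convex hull after one
leave-one-out pruning pass: with n points and all-points hull volume V, a
point is an outlier if dropping it changes the hull volume by more than
V/n. All flagged points are removed simultaneously (so the outcome does not
depend on input order); if fewer than four somata would survive — four
being the minimum for a 3-D hull — all points are kept instead. A single
pass against the all-points hull is used rather than iterating to a fixed
point: iterated sweeps cascade (each removal promotes interior points to
hull vertices) and collapse Gaussian soma clouds to a few percent of their
volume. Note that a distant outlier enlarges the leave-one-out deltas of
the points on its silhouette, so those can be flagged along with it; with
reasonably dense clouds the fallback keeps this benign.

Between-class segregation is the intersection/union volume ratio. The
intersection of two convex hulls is itself a convex polytope: when the
combined halfspace system has an interior point (found as the Chebyshev
center by linear programming) the intersection is computed exactly by
halfspace intersection and the union follows by inclusion–exclusion; with
no interior point the overlap is exactly 0 (flagged as degenerate, covering
the "too few overlapping somata" case). A seeded Monte-Carlo estimator over
the joint bounding box, with reported standard error, serves as fallback
when the exact route fails numerically.

## Path distances

The path distance from the soma to an axonal point is the summed Euclidean
gaps along the unique tree path — never less than the straight-line
distance. Divergence (one class, several targets) and convergence (several
classes, one target) are tested pairwise with the two-sample Mann–Whitney
rank test on pooled per-point distances, ipsi- and contralateral targets
separately, with Benjamini–Hochberg FDR across the pairs of each analysis.
Pooled per-point samples are the default because the reported sample sizes
in this literature are per-point; a per-neuron-median variant
(`use_medians=True`) is provided since pooled points from one arbor are
not independent and the pooled p-values are therefore optimistic. The
rank-sum test is used even where the field's reports name the signed-rank
test: the samples are unpaired with unequal sizes, for which the signed-rank
test is undefined.

## Synthetic data

`synthetic_fixtures` generates every input the package consumes:

- **Cohorts** — neuron i of class c draws a total point count from a
  log-normal (default median 1500 points, σ = 0.4, matching the order of
  magnitude of whole-brain axonal tracings) and spreads it multinomially
  over columns with class c's region-probability profile. Two convenience
  specs encode the study systems: a motor-cortex-like cohort (21
  cortically-targeting + 31 thalamically-targeting neurons) and a
  presubiculum-like cohort (93 neurons; classes of 38/27/3/19/6 with the
  hallmark mixes: 82% LEC for A, 92.5% dorsal MEC for B, contralateral
  targeting for C, the subiculum/DG/subcortical mix for D, thalamic nuclei
  for E; planted population fractions 30.6/16.3/1.3/38.1/13.7%). The
  A-class dentate-gyrus weight (0.054) is derived so the planted fractions
  and profiles jointly imply the ~21/79 dentate afferent split.
- **Trees** — an abstract binary branch topology is realized with
  per-branch lengths and point spacings drawn by Strahler band, emulating
  dense terminal sampling (default 20 µm) vs sparse passage sampling
  (40 µm); a log-normal option provides the heavy-tailed branch lengths of
  real arbors.
- **Soma clouds** — isotropic Gaussian blobs with controlled separation.

The multinomial model is the minimal model under which per-region point
counts fully describe a projection pattern: it has no spatial
autocorrelation within regions, no tracing artifacts, and no correlation
between a neuron's total extent and its targets. Passing tests on these
cohorts therefore demonstrate the statistical machinery (recovery of
planted structure, conservation laws, oracle equality), not robustness to
the idiosyncrasies of real tracing data.

## Calibration caveat

The split gate's type-I behavior depends on what "a single class" means.
For multinomial single-class cohorts the gate is strictly conservative: the
uniform-fiber null is far more dispersed than multinomial sampling noise
(variance ratios near 0.01), so homogeneous cohorts essentially never split
(0/500 seeded runs at α = 0.05 under the default conditions). Conversely,
when the experimental cohort is itself a draw from the swap continuum (so
experimental and randomized samples are exchangeable), the observed split
rate at 40 neurons is ~0.17 rather than α, because the C(n,2) pairwise
distances violate the independence assumption of the Levene ANOVA; the
rate approaches α only for small cohorts (~10 neurons). In practice the
gate is used as a conservative detector of structure far exceeding
marginal-preserving randomness, which the planted-recovery results bear
out.

## Numerical choices

- Swap chain state is kept in integer arithmetic throughout; conservation
  is exact, not approximate.
- Linkage ties are resolved by scipy's deterministic nearest-neighbor
  chain; merge heights are compared to 1e-12 where relevant.
- NNLS uses the active-set algorithm; coefficients forced negative by the
  data come back exactly 0.
- Hull volumes below the degenerate (coplanar) threshold raise rather than
  return 0, so zero-volume hulls cannot silently enter overlap ratios.
- All generators and the classification recursion are pure functions of
  their seeds (child seeds are spawned from a `SeedSequence`), so a fixed
  seed reproduces a `ClassTree` bit-exactly.

## Problem sizes

The test suite and the acceptance script run on scaled-down but
structurally faithful instances: cohorts of 40–145 neurons over 6–18
columns, 40 trees of 60 bifurcations (~4800 branches) for the spacing
statistics, and 10⁵-swap chains for conservation checks. These sizes keep
the full suite under a minute while leaving every statistical effect of
interest (planted separations, band contrasts, fiber coverage) several
standard errors wide.

## Known limitations

- The swap chain's stationary law under the uniform-δ rule is not exactly
  uniform on the fiber; the chain, not a particular stationary law, is the
  specified null.
- Exact hull intersection can be ill-conditioned for near-tangent hulls;
  the Monte-Carlo fallback reports its standard error.
- Pooled per-point path-distance tests inherit within-neuron dependence;
  see the per-neuron-median variant.
- Parcel grouping (e.g. "CA3+CA1") is configuration, shipped as an
  editable table (`axoclass/data/parcel_groups.csv`), not inferred.
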