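# Methods notes

This note records the models, numerical choices, and known limitations of
`morphlands`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Size correction

Specimen size is the geometric mean of all linear traits; linear traits
become log-shape ratios ln(trait/size) and angular traits pass through
untouched (angles are dimensionless in size, and including them in the
geometric mean would mix units). Two consequences are used as invariants:
the log-shape ratios of the geometric-mean traits sum to zero per specimen
(tested at 1e-10), and multiplying a specimen's linear traits by any
positive scalar leaves its corrected values unchanged. A configuration flag
disables the correction (the no-size-correction sensitivity variant), in
which case linear traits enter the PCA as plain logs and size is recorded
as 1. Specimens with missing trait values are rejected with a named error
rather than imputed. Whether angular traits enter the PCA raw is
config-exposed (`angular_in_pca`, default on); the default keeps them raw
because no transformation is obviously privileged for joint angles.

## Morphospace

PCA uses the sample covariance matrix (n−1 denominator), computed by SVD of
the centered matrix rather than by forming the p×p covariance, for
numerical stability at p=136 > n=109. Component signs are fixed by
orienting each loading column so its largest-magnitude entry is positive —
PCA signs are otherwise arbitrary and determinism is required for
reproducible artifacts. Trace conservation (eigenvalue sum = total
variance) and full-rank round-trip reconstruction are tested at 1e-8.

Theoretical morphologies are reconstructed on an evenly spaced lattice
(default 9×7 = 63 nodes) spanning the observed PC1/PC2 range exactly, with
all components beyond the first two at zero. The reconstruction convention
is this package's documented assumption; nothing in the underlying method
fixes how higher components should be treated, and zero is the maximum-
likelihood choice under the PCA model. Reconstructed values are log-shape
ratios; `grid_shape_table` exponentiates the linear traits so the proxy
registry sees positive size-relative magnitudes.

## Functional proxies

The registry ships conventional ecomorphology formulas (mechanical
advantage = in-lever/out-lever; robustness = midshaft diameter/length;
epicondylar indices = epicondylar breadth/length; crural/brachial indices =
distal/proximal lengths; manus/pes indices = metapodial length over the sum
of the proximal elements; vertebral stiffness via the elliptical-beam
second moment (π/64)·a·b³; joint torsion and verticality as raw angles).
Each of the four vertebral proxies is instantiated at three joint regions
(third cervical, diaphragmatic thoracic, middle lumbar), giving
2 + 7 + 6 + 4×3 = 27 proxies. Every formula is overridable in YAML, because
published index definitions vary between labs and the pipeline should not
be welded to one algebra. Ratio-type proxies are computed from raw (not
size-corrected) traits; their scale invariance is asserted by property
test, not assumed. The four proxies dropped by default (masMA, SI, GI, TRI)
are user configuration: the removal criterion in empirical work is visual
inspection of surface topology, which this package deliberately does not
automate.

## Ordinary kriging

The semivariogram γ(h) is estimated in equal-width distance bins spanning
(0, max pairwise distance]; model fitting uses only lags up to half the
maximum (far bins hold few pairs and are dominated by boundary geometry —
the standard working rule). Candidate families are spherical (default),
exponential, and gaussian with the practical-range convention; parameters
(nugget ≥ 0, partial sill > 0, range > 0) are fitted by bounded nonlinear
least squares weighted by sqrt(pair count), with two range starts per
family, and the family with the lowest weighted SSE wins. When a
pure-nugget model explains the binned semivariances as well as any
structured model, the fit collapses to it deterministically; kriging under
a pure-nugget model predicts the global mean everywhere, and the resulting
constant surface is treated as degenerate (dropped with a logged warning)
— the honest outcome for a proxy with no spatial signal in the
morphospace.

The kriging system is the standard augmented form with a Lagrange
multiplier enforcing unit weight sum; it is LU-factorized once per surface
and back-solved for all grid nodes simultaneously. The system diagonal is
zero (a point has zero semivariance with itself), so a zero-nugget model
interpolates the samples exactly (tested at 1e-8 against both the sample
values and an independently coded dense per-node solve). Duplicate sample
coordinates are averaged before solving to avoid singularity. Prediction
grids default to 50×50 over the observed score range expanded 5% per side.

One realization of a random field does not identify the variogram family
well — the three families differ mainly near the origin, where binned
estimates are noisiest. The generative-recovery test therefore averages
binned semivariances over several independent realizations before fitting;
single-realization fits should be read as smoothing choices, not inference
about the true family.

Surfaces are min–max normalized to [0, 1]. The alternative reading of
"equal variance across surfaces" — z-standardization — is available in
principle by normalizing raw values upstream, but the shared [0, 1] range
is what makes weighted sums interpretable as relative fitness and is the
default. Strictly positive proxies whose values span more than two orders
of magnitude (the second-moment indices, which cube a linear trait) are
interpolated on the log scale before normalization; this is the usual
variance-stabilizing practice and prevents a handful of extreme values from
flattening the empirical variogram into a spurious pure nugget.

## Weight search and W′

Weights live on a simplex lattice (multiples of the increment, default
0.25) and are stored as integer unit counts so every vector sums to 1
exactly; counts follow stars-and-bars, C(n+m−1, m) for n surfaces and m
units. The full enumeration at 0.25 increments is exhaustive by
construction; finer increments (config-exposed down to 0.05) grow
combinatorially and the search should then be read as a ranked
approximation rather than exhaustive.

Group fitness defaults to the landscape height at the group's mean
position (`at_group_mean`), with `mean_over_members` as the averaged
alternative; both are linear functionals of the weights, so each
candidate's fitness is a dot product and the exhaustive search over 27,405
candidates is a single matrix product. This linearity has a geometric
consequence worth stating plainly: the top-ranked candidate is always a
vertex of the simplex (all weight on one surface), except under exact
ties. The package therefore reports two optima: `w_prime`, the top-ranked
candidate under a deterministic lexicographic tie-break, and the mean of
the tie-inclusive top-percentile set (`average_top_weights`), which is the
quantity that takes interior values and is the appropriate summary of a
group's optimal weighting. Recovery behavior follows the same geometry:
vertex ground truths are recovered exactly as `w_prime`; interior ground
truths are recoverable through the top-set mean when the construction
produces plateaus/ties (e.g., surfaces rising to a shared optimum), and
only approximately otherwise.

## Group comparison

The sharing test draws the null from a hypergeometric: |top_b| draws from a
pool of N candidates of which |top_a| are marked, one-sided toward fewer
shared landscapes (small p = the groups' preferred landscapes differ; a
group compared with itself gives p = 1). A seeded permutation null is
available and is checked against the closed form within Monte-Carlo error.
The top set is the ⌈percentile/100 · N⌉ best candidates with cutoff ties
included (deterministic inflation). The top percentile is a configuration
value, default 5%; p-values are reported raw (optional Holm adjustment is a
config concern, not a default).

The permutational MANOVA computes R² = SS_between/SS_total and the one-way
pseudo-F on the multivariate scores with p = (1 + #{F_perm ≥ F_obs})/(1 +
n_permutations); an independent identity — the same sums of squares
recovered from pairwise Euclidean distances — is used as a test oracle.
Type-I error is calibrated over 1,000 null replicates (accepted band
3–7% at α = 0.05).

## Synthetic data

The generator emulates the statistical shape of the target data: 109
species × 136 traits (118 linear, 18 angular) by default, 7 locomotor and
7 dietary regimes, and 12 family labels. Latent ecological positions are
2-D: locomotor group means sit on a circle of radius `group_effect_size`
(in within-group SD units, default 2.0), dietary means on a half-radius
circle rotated against it, plus unit isotropic noise. Log linear traits are
affine in the latent position (loading SD 0.15 log-units per latent unit)
plus N(0, 0.05) noise, then multiplied by a lognormal per-specimen size
factor (log-SD 0.3); angular traits are affine in degrees (loading SD 8°,
noise SD 2°). Independent RNG streams drive latent positions, trait noise,
and size factors, so toggling the size confound changes nothing else —
size correction then cancels it analytically (tested at 1e-12; exp/log
round trips preclude literal bit equality).

What the generator does **not** emulate: phylogenetic covariance among
species, realistic trait–trait covariance blocks (residuals are isotropic),
uneven group sizes, and measurement outliers. Passing tests therefore
demonstrate correctness of the machinery — recovery of planted latent
structure, calibration of the tests under exchangeable nulls — not that
empirical carnivoran results would reproduce. Because the planted latent
plane dominates trait variance, PC1–PC2 capture far more variance on
synthetic data (~99%) than is typical of real morphometric tables (~50%).

Known-truth landscape scenarios use isotropic Gaussian bumps with distinct
peaks on a circle (width 0.35 of the grid span) and place the group, with
tiny centered jitter, at the argmax of the true weighted combination.
Smooth unimodal fields guarantee kriging fidelity and an unambiguous
argmax.

## Problem sizes and defaults

Defaults were chosen once to mirror the emulated study design: 109×136
input, 27 proxies (23 after the drop list), 50×50 surfaces, 0.25 weight
increments, 5% top sets, 999 MANOVA permutations. Test-suite runs use
smaller sizes (e.g., 42 species, 25×25 grids, 99–199 permutations) where
the property under test does not depend on scale; the acceptance script
runs the pipeline at the full default sizes.

## Known limitations

- No phylogenetic comparative machinery (no phylogenetic PCA, no PGLS):
  deliberate scope, matching the package's focus on the ordination-and-
  landscape pipeline itself.
- Isotropic variograms only; no universal/co-kriging or anisotropy.
- The likelihood interpretation of landscape optimization is not
  implemented; ranking is by fitness over the enumerated lattice, and the
  search at coarse increments is a ranked approximation, not a continuous
  optimization.
- The sharing test conditions on fixed top-set sizes; it does not model
  selection of the percentile itself.
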