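# Methods

## Model and scope

`scnet` analyses cross-sectional morphometry cohorts as *structural
correlation networks*: nodes are cortical regions, and the edge between
regions i and j is the Pearson correlation of their cortical thickness across
participants. Raw values are used, without covariate adjustment. Age
resolution comes from a sliding-window design in participant counts: the
cohort is sorted by age and networks are estimated on overlapping windows, so
each window contributes one point, at its median age, to every metric's
developmental trajectory.

Everything downstream assumes the cross-sectional design: each participant is
one draw from the population at their own age, and age enters only through
(a) the windowing and (b) the generative model of the synthetic cohorts.
Longitudinal repeated measures, scanner/site effects, and motion artefacts
are out of scope.

## Windowing

Two modes are provided. *Index* mode slides a window of `width` participants
by `step` over the age-sorted cohort; `anchor_final` appends a last window
flush with the oldest participants when the grid does not reach them.
*Stratum-interpolated* mode (the default) splits the cohort into `n_strata`
contiguous strata of near-equal size and forms `2·n_strata − 1` windows: the
strata plus, for each adjacent pair, the older half of the first joined to
the younger half of the second. With 5 strata of 60 this yields the canonical
9 half-overlapping windows of 60. Ties in age are broken by stable input
order; an odd stratum puts its extra participant in the younger half (an
arbitrary but fixed convention). Median ages use the standard even/odd
median.

## Bootstrap thresholding

Windowed correlation matrices at n ≈ 60 are noisy, so edges are retained only
with evidence of a sign-consistent nonzero correlation across bootstrap
resamples. One resample redraws the window's participants with replacement
and re-estimates the *whole* matrix (edges are never resampled
independently). The two-tailed sign-crossing p-value is

    p = 2 · min(#{r*_b ≤ 0}, #{r*_b ≥ 0}) / B,   capped at 1,

which is exactly 0 when the edge is consistently positive or consistently
negative across all B resamples. We deliberately use no add-one smoothing:
with smoothing, the minimum attainable p is 2/(B+1), and under
Benjamini–Hochberg at α = 0.01 the adjusted p of the edges tied at that
minimum is (2/(B+1))·m/#tied — at B ≤ a few hundred this exceeds α unless
essentially *all* edges are tied there, so thresholded networks would be
empty at any realistic test size. With the unsmoothed statistic, "retained"
coincides with "sign-consistent across all resamples", FDR control on null
data holds empirically (mean retained fraction ≈ 1.5% at the achievable
resolution of B = 200, α = 0.01; the acceptance suite checks < 2%), and p = 0
edges are handled exactly by BH. A resample in which some region has zero
variance contributes a neutral r* = 0 to both tails for the affected edges
(logged), rather than aborting a long run.

BH (not BY) is used for the FDR adjustment, as the field default without a
dependence correction. Retained edges keep the observed full-subset
correlation, not the bootstrap mean.

## Graph metrics

Deliberately elementary, because bootstrap-thresholded networks vary in edge
density and density-dependent higher-order metrics would confound age effects:
node degree and weighted degree of retained edges; nodal strength as the mean
unthresholded correlation of a node's row (diagonal excluded); global mean
correlation over the upper triangle; edge density as % of possible edges;
connection distance as the Euclidean distance between anatomical centroids,
averaged over retained edges (global) or over a node's retained edges (nodal;
undefined for isolated nodes). Community edge density D divides retained by
possible edges within each community (m(m−1)/2) and between each pair
(m_a·m_b); global density equals the possible-edge-weighted mean of D.
Whether global distance should average over edges or over nodes is genuinely
ambiguous; edge-averaging is implemented.

## Communities

Louvain modularity (Newman–Girvan with resolution γ scaling the null term)
runs on positive weights only; negative retained edges are excluded because
the partition seeks communities with higher *positive* correlation within
than between, and no signed null model is defined. Versatility
operationalizes the uncertainty of module affiliation: with p_ij the
co-assignment proportion of a node pair across runs, V_i = mean_{j≠i}
4·p_ij·(1−p_ij), zero for run-invariant partitions and maximal for a 50:50
split; the mean curve over a γ grid is smoothed (3-point window) and its
local minima are candidate resolutions. A single-module solution is
*trivially* consistent, so recommendations are restricted to resolutions
whose modal partition is nontrivial. The final partition is a
Lancichinetti–Fortunato consensus: threshold the co-assignment matrix at
τ = 0.5, re-cluster it with the same number of runs, and iterate (max 20)
until all runs agree. NMI between partitions is 2·I/(H₁+H₂) from the label
contingency table; two single-module partitions have NMI 1 by convention
(0/0 → 1, identical partitions).

## Trajectories

Each windowed series is fitted with a line and with a penalized spline: 6
cubic B-splines on the age range with interior knots at the terciles of the
window ages, a second-derivative penalty integrated exactly (2-point
Gauss–Legendre per inter-knot interval), and λ chosen by Gaussian REML. The
REML profile in log λ is routinely multimodal on near-linear series, with the
correct optimum at the smooth boundary; a global grid search (81 points over
log λ ∈ [−15, 25]) precedes local refinement, which matters in practice — a
purely local optimizer lands in the spurious undersmoothing minimum on a
substantial fraction of null series. The effective degrees of freedom,
tr[(BᵀB+λS)⁻¹BᵀB], are capped at 3.5 by *inflating* λ (never by dropping
basis functions): over a ~10-year span the trajectory is allowed at most
quadratic-like complexity. Model choice is by Gaussian AIC with k = edf + 1
(error variance included); ties go to the line. AICc and BIC are recorded as
consistency diagnostics. The p-value for nonzero change is an F-type test of
the chosen model against the intercept-only model with edf-based degrees of
freedom; nodal p-values are BH-adjusted across regions.

Change parameters are read off a dense fitted grid (step 0.01 y, so argmin
error is bounded by the grid): Δmax = |max − min| of the curve; age_min = age
at the minimum, flagged when it falls on an endpoint; direction is
"decreasing" when the maximum precedes the minimum in age; shape is the
chosen model class. Confidence intervals for age_min are percentile intervals
over bootstrap replicates: replicate b of every window (one shared resample
index per window per replicate) forms one replicate series, the chosen model
is refitted to each, and the 2.5/97.5 percentiles of the argmin distribution
are reported. Fewer than 100 replicates triggers a warning.

## Spin test

Regional map–map associations use Spearman's ρ with two p-values: the
parametric one and a spherical permutation p. One uniformly random rotation
(QR of a Gaussian matrix with Haar sign correction, determinant fixed to +1)
is applied to the left hemisphere's spherical projection and its
sagittal-mirror conjugate to the right hemisphere, preserving hemispheric
symmetry; each region then takes the value of the nearest original region
(great-circle distance) on its own hemisphere, a mapping that may be
non-injective. The two-sided p compares |ρ| against the null distribution
with the add-one rule, so p is never exactly 0. The rotated map is by
convention the second argument. On spatially smooth null maps the parametric
test is badly anticonservative while the spin p stays near nominal; both are
asserted in the test suite.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: N = 297
participants (ages 14–24, five equal-width strata with near-equal counts,
uniform within strata), 308 regions — 154 per hemisphere on a Fibonacci
lattice over each hemisphere's projection sphere, mirror-symmetric across the
sagittal plane, with anatomical centroids at a nominal 70 mm brain radius and
a ±35 mm hemispheric offset so homologous regions do not coincide — and 7
bilateral, spatially contiguous planted modules (spherical Voronoi patches
around random seed regions, mirrored to the other hemisphere).

Each participant's regional vector is multivariate normal with the
correlation matrix of a block model evaluated *at that participant's own
age* (so any windowing can be applied afterwards), mean = regional baseline +
slope·(age − 14), and marginal SD 0.10 mm. Defaults: CT baselines
N(2.7, 0.15) mm, thinning slopes N(−0.02, 0.01) mm/y; MT maps at 12 depths
(10 fractional + 2 white-matter) with slopes N(0.006, 0.003) PU/y, optionally
coupled at one depth to a supplied regional map to plant a recoverable
depth-specific association. The correlation model is convex in age:
between-module r(a) = 0.18 + 0.0045·(a − 19.5)², within = between + 0.15,
minimum at a* = 19.5 y. These values were chosen once so that (a) windowed
mean correlations run from ≈ 0.34 at age 14 to ≈ 0.20 at the minimum — the
scale and shape typical of adolescent CT covariance — and (b) edge retention
at n = 60 traverses its transition zone across the age range, so thresholded
density trajectories have a recoverable interior minimum rather than
saturating. Positive semi-definiteness is checked at every age and repaired
by eigenvalue clipping at 0 with re-normalization to unit diagonal; matrices
far from PSD are rejected.

`smooth_cortical_map` generates bilaterally symmetric, spatially
autocorrelated null maps for spin-test calibration: a Gaussian random field
with rotation-invariant covariance (independent equal-variance coefficients
within spherical-harmonic degrees 1–3, weights 1/0.7/0.5) evaluated on the
canonical hemisphere sphere, copied to mirrored twins, plus 25% regional
white noise. Rotation invariance and exact bilateral symmetry are what make
these maps a *valid* null for the mirrored-rotation spin test; maps without
those properties are miscalibrated by construction, not by implementation.

### What the generator does not emulate

Block-constant correlation means all between-module edges load on a handful
of module-level factors, so window-level summaries co-fluctuate more than in
real cortex, where correlation structure is far more distributed; this is why
recovery simulations are run at the full 308-region / 7-module scale (21
factor pairs) rather than in very small block designs, and why per-seed
argmin estimators of the correlation minimum are heavy-tailed in small
configurations. There are no site, motion, or reliability artefacts, no
age-by-sex structure (sex is assigned at random), and morphometric trends are
exactly linear. Passing tests therefore demonstrate that the pipeline
recovers what it is designed to recover under its own assumptions — not that
those assumptions hold in any empirical cohort.

One realistic side effect is worth noting: because regions share thinning
trends, cross-sectional age trends *induce* structural covariance between
otherwise independent regions (the same mechanism thought to generate
empirical structural covariance). Tests that need exactly-null between-block
edges disable the trends.

## Problem sizes and numerical choices

Simulation-based checks use sizes at which their statistics are informative:
full study scale (308 regions, N = 297, B = 200) for trajectory-minimum
recovery; 60–100 regions for FDR, retention, consensus, and spin calibration
checks; B = 200 bootstraps and 1000 spin permutations where the full-profile
values (1000 / 10 000) would add nothing but runtime. The acceptance script
uses the same reduced profile; the `analysis/` drivers run the full profile.
Tolerances: PSD repair threshold 1e−8 on the smallest eigenvalue; symmetry
checks at 1e−12; spline edf cap enforced to 1e−6; dense-grid argmin accurate
to the 0.01 y grid step. Degenerate inputs (constant maps, zero-variance
regions, single-module partitions, empty networks) are either rejected with a
named cause or handled by documented conventions, as listed per module above.

## Known limitations

The bootstrap p-value construction and the regional spin reassignment rule
(nearest centroid, non-injective) are each one defensible operationalization
among several; both are flagged in their docstrings. The consensus procedure
inherits Louvain's resolution limit at small γ. The edf cap can leave
systematic lack-of-fit on steeply asymmetric trajectories, biasing AIC toward
the spline less than an uncapped smoother would; this is intentional
(complexity control) but means Δmax is conservative for very sharp curves.
CIs for age_min ignore between-window dependence introduced by overlapping
windows (replicate b is drawn independently per window), which in practice
widens rather than narrows them.
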