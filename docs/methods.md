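# Methods

## Quantities and their definitions

**Normalized granule density.** Each ROI is an axis-aligned cuboid (2–4 µm
per side, nm coordinates) around one axon-spine synapse; its astrocytic
compartment has volume `astro_volume` (µm³). Density is
`granule_count / astro_volume` (granules per µm³ of astrocyte), computed over
*all* granules annotated in the ROI — the distance window applies only to
distance statistics.

**Glucose residues (GR).** Glycogen granules grow in concentric tiers of
thickness L ≈ 1.9 nm; each tier doubles the number of glucose chains
(branching degree b = 2) and a chain carries c = 13 residues on average. A
granule of diameter d spans `d / 2L` tiers along its radius, giving

    GR(d) = c (b^{d / 2L} − 1).

GR(0) = 0, GR(2L) = c exactly, and GR satisfies the tier recurrence
`GR(d + 2L) = b·GR(d) + c(b − 1)`. GR is kept real-valued (not rounded):
population means of GR feed the condition comparisons, and rounding would
bias small granules. All three constants are parameters (`GrParams`) with
the defaults above; L is frozen at exactly 1.9 nm.

Because GR is convex in d, pooled GR means depend on the whole diameter
distribution, not just its mean (Jensen gap). With the moment-matched normal
diameter marginal the simulated pooled GR mean for the sleep condition lands
within ~6% of the reported value; the *ordering* of pooled GR means across
conditions is not recoverable from printed means/SEMs alone, because the
conditions' diameter variances differ enough to flip it. The package
therefore treats pooled GR summaries as descriptive output, not calibration
targets.

**Granule-to-ASI distance.** The distance is from the ball annotation to the
*nearest vertex of the ASI mesh's unique-vertex set* — deliberately not the
closest point on a triangle face, matching how the annotations were
measured; a face-projection mode is intentionally absent. Duplicate vertices
are merged by exact coordinate match at load time, before any distance
computation. Two modes: `center` (default; ball centre to vertex) and
`surface` (centre distance minus radius, floored at 0) — the annotation
tool's ball anchor makes centre mode the natural reading, and surface mode
is provided for sensitivity analysis. Only granules within the window
(default 500 nm, boundary *inclusive*) enter distance statistics; distances
are averaged within each ROI, and ROIs with no within-window granule yield
an explicit undefined marker (NaN) and are dropped from distance analyses
rather than imputed.

**Coverage.** The ASI perimeter is a closed polyline of mesh-vertex indices
with one boolean PAP-contact label per segment; coverage is the contacted
fraction of total perimeter length. Labels are inputs (produced upstream by
segmentation), never inferred from geometry.

## Statistics

All tests operate on mid-ranks. Kruskal–Wallis uses the tie-corrected
statistic with a chi-square upper tail on k−1 degrees of freedom (the exact
small-sample distribution is not implemented; at hundreds of observations
per group the approximation error is far below Monte-Carlo resolution — the
test suite quantifies it against a sampled permutation null, and the
empirical type-I error over 10,000 null replicates of 4×80 observations
sits within 3 MC SE of 0.05). Dunn's pairwise z uses the tie-corrected rank
variance; in the two-group case z² equals the tie-corrected H exactly, which
is how the within-condition SER/mitochondrion comparisons are run (staying
inside the rank-based toolkit). The p-value adjustment is Bonferroni by
default with Šidák and none selectable — reported in every output row, since
published analyses rarely state which their software used. All tests are
two-sided. Spearman's rho is the Pearson correlation of mid-ranks with the
two-sided t approximation on n−2 df; |rho| = 1 reports p = 0; constant
inputs are an error at the API level and a NaN row at the pipeline level
(degenerate datasets should not abort the other panels). No mouse-level
clustering adjustment is applied: ROIs/granules pool across the 3 mice per
condition, matching the analysis design the pipeline mirrors.

The density-vs-ASI correlation uses log2(density) with zero-density ROIs
excluded (log undefined) and their count reported; since Spearman is
invariant under monotone transforms, the log only matters for plotting and
for the exclusion rule. Diameter-vs-distance correlations are granule-grain
on within-window granules; coverage-vs-distance is ROI-grain. Each
correlation row records grain and n.

## Synthetic-study generator

The generator emulates the annotation structure, calibrated to published
per-condition summaries: ROI counts (308/268/339/339 for S/W/SD/CSR),
density 103.6/116.3/125.7/123.1 ± SEM, diameter 27.2/27.1/26.9/26.3 ±
0.1 nm at the reported granule counts, within-window per-ROI distance means
357.2/368.7/366.5/334.9 ± SEM, SER prevalence 57.5/35.9/47.2/48.6%,
mitochondrion prevalence 69.5/66.1/67.7/59.9%. Population SDs derive from
SEMs as SD = SEM·√n at the reported n (ROI counts for ROI-grain variables,
granule counts for diameter).

Distributional choices, where only mean/SEM are published:

* **Density**: gamma, moment-matched. A truncated normal at these
  coefficients of variation (~0.9) shifts the mean by >20%, which would
  wreck recovery; gamma has positive support, exact moments, and is the
  mixing law that makes Poisson counts negative-binomial. Granule counts are
  `round(density × astro_volume)`, so a zero-SD configuration degenerates to
  the exact mean up to integer rounding.
* **Diameter**: truncated-at-zero normal (truncation ~4.8 SD out,
  negligible); a lognormal alternative is a settings option.
* **Distance**: a per-ROI mean target t_i follows a Beta on [0, 500] nm
  moment-matched to the configured mean/SD; within-window granule distances
  follow a Beta on [0, 500] with mean t_i (concentration 8); a far fraction
  (default 20%) is uniform in (500, 900] nm so the window actually filters.
  All Beta constructions have exact means, keeping recovery unbiased.
* **ASI area**: lognormal (median 0.15 µm², σ = 0.6, capped at 0.6 µm²) —
  typical cortical ASI scale; **coverage**: Beta(4, 6) (mean 0.4);
  **astrocytic volume fraction**: uniform in [0.05, 0.15] of the ROI volume.
  None of these three has a published summary to match.

**Rank correlations** (density↔ASI area per condition; diameter↔distance and
coverage↔distance where reported, with near-zero values elsewhere) are
induced by Gaussian-copula reordering (Iman–Conover): both samples map to
van der Waerden scores, the second is remixed at latent Pearson
r = 2 sin(πρ/6), and the second sample's *values* are permuted to follow the
mixed ranks. Margins are preserved exactly and the population Spearman of
the pair equals the target; realized sample values fluctuate at O(1/√n), so
the recovery contract is on the seed-averaged realized rho (within 3/√n of
each target). One reported r/p pair (CSR density–ASI) is internally
inconsistent at its n and is replaced by 0.

**Geometry realization.** Each ROI's ASI is a regular-polygon disc (32
segments, fan-triangulated, exact polygon area equal to the drawn ASI area)
in the z-plane through the ROI centre. A granule with target distance d is
placed at a uniformly chosen mesh vertex offset by ±d along the disc normal;
since all vertices are coplanar, every other vertex is at √(d² + r²) ≥ d, so
the nearest-unique-vertex distance equals the drawn value exactly and the
geometry stage recovers the generator's distances bit for bit. Coverage
labels mark a contiguous run of round(c·32) equal-length segments. Mice have
no variance component (ROIs are assigned round-robin to 3 mice), matching a
pooled analysis; this means the generator cannot exhibit mouse-level
clustering effects.

**What passing tests do and do not show.** Synthetic data demonstrate that
the pipeline recovers known ground truth and reproduces the calibrated
group-level orderings; they do not validate the metrics against real EM
noise sources — segmentation error, anisotropic voxels, non-spherical
granules, within-mouse correlation, or ASI meshes more complex than a disc.

## Problem sizes and runtime

Default-calibration studies carry ~1,250 ROIs and ~350k granules and take a
few seconds each to generate and analyse. The calibration suites use 20
seeds for recovery/qualitative checks and 10,000 replicates for the type-I
error estimate; unit tests run on 40-ROI-per-condition studies. The whole
test suite completes in a couple of minutes on one CPU.

## Known limitations

* Distance is vertex-based by design; against a coarsely meshed ASI it
  overestimates the true surface distance by up to the edge length.
* The chi-square and normal approximations are asymptotic; the package does
  not provide exact permutation p-values (the test suite uses permutation
  nulls only as oracles).
* Pooled GR means are distribution-dependent (see above) and should not be
  compared against published pooled values without knowing the full diameter
  distribution.
* ROI volumes implied by 2–4 µm edges (~8–64 µm³) are an order of magnitude
  above the published per-ROI volume summary (~1.7 µm³); the generator
  follows the stated edge lengths, and no recovery target depends on the
  absolute ROI volume. Granule counts per ROI scale accordingly.
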