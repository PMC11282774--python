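# Methods

`mechanoquant` implements the quantitative analyses used to characterize
contactless microfluidic cell mechanoporation: the geometry of the
compressed cell, the membrane-tension readout, the localization of
tension hot-spots, cortex morphometry, volumetric nanoparticle counting,
transport classification of delivered cargo, and a diffusion model of
pore-mediated uptake.  Every stage is paired with a seeded synthetic-data
generator so the whole pipeline can be validated closed-loop against
known ground truth.  This note records the models, the defaults and why,
the numerical choices, and the known limitations — including what
passing the synthetic tests does and does not establish about real
microscope data.

## Cell geometry and curvature

A cell compressed uniaxially in flow deforms from a sphere into an
oblate spheroid with equatorial semi-axes a = b and polar semi-axis
c < a, measured in-flow as the diameters 2a and 2c.  With the squared
first eccentricity e² = (a² − c²)/a², the principal radii of curvature
at reduced latitude φ (0° equator, 90° pole) are the classical surface-
of-revolution forms

    ρ₁(φ) = a (1 − e²) / (1 − e² sin²φ)^{3/2}      (meridional)
    ρ₂(φ) = a / (1 − e² sin²φ)^{1/2}               (prime vertical)

with curvatures C₁ = 1/ρ₁, C₂ = 1/ρ₂ and total curvature J = C₁ + C₂.
These satisfy the limits ρ₁(0) = c²/a, ρ₂(0) = a, ρ₁(90°) = ρ₂(90°) =
a²/c, and ρ₁ = ρ₂ = a for a sphere, and they are verified in the test
suite against finite-difference differential geometry of the meridian
ellipse to a relative error below 10⁻⁶.  J is maximal at the equator,
which is where pores form.  Some sources print the exponent 3/2 in both
denominators and call (a² − c²)/a² the eccentricity itself; that variant
violates the sphere and equator limits, so it is not the default, but it
is available as `variant="literal"` for auditing.  For the control
sphere both J (= 2/a) and the single curvature 1/a are reported, since
conventions differ on which is quoted.

The viscoelastic compression force scales as F ∝ β³ η λ U²max with β the
confinement ratio (cell diameter / channel height), η the fluid
viscosity, λ its relaxation time, and U_max the maximum cross-section
velocity.  The proportionality constant is not identifiable from the
scaling law, so the output is in relative units with the constant fixed
at 1.

## Lifetime fitting (tension readout)

Membrane tension is read out as the dominant fluorescence lifetime of a
planarizable push–pull probe.  Binned photon decays are fitted with
I₁ e^{−t/τ₁} + I₂ e^{−t/τ₂} (optional constant background) by bounded
nonlinear least squares, multi-started from log-spaced lifetime pairs.
Weights are √(counts + mean counts): Poisson-motivated, with a variance
floor that scales with the data so the fit is exactly scale-equivariant
(multiplying all counts by k scales I₁, I₂ by k and leaves the
lifetimes unchanged).  Components are ordered by signal share I·τ, so
τ₁ is always the majority component regardless of optimizer labeling;
when the two fitted lifetimes agree within 5% the decay is effectively
monoexponential and the amplitude split is unidentifiable, so the
components are merged.  Median recovery error of τ₁ is below 1% at 10⁵
photons on the synthetic conditions (256 bins over 50 ns, amplitude
ratios 4:1–19:1).  No instrument-response deconvolution is performed;
the generator produces no IRF, so real FLIM data with a non-negligible
IRF would need deconvolution upstream.

## Tension-point mapping and angular statistics

High-tension points appear as red spots (lifetime colormap) on the cell
rim.  The cell silhouette is Otsu-thresholded, the largest connected
region's contour is fitted with a least-squares (Kåsa) circle, and
pixels whose red-channel value lies in the inclusive window [120, 180]
are detected, with connected clusters collapsed to centroids so one
physical spot counts once.  Each point is expressed as a normalized
radius (distance to centroid over cell radius; values up to 1.1 are
tolerated as boundary pixels and flagged beyond that) and an angle
measured counter-clockwise from +x with the image y-axis flipped
(mathematical convention; the convention is arbitrary but fixed).
Angular concentration uses eight fixed bins of 45° starting at 0°; the
maximal bin count as a percentage of all points is compared against the
12.5% uniform baseline.  A phase-scan variant maximizing over bin
offsets exists but is not the default, since fixed bins are assumed by
the baseline.  With fixed bins, a 45°-wide cluster of points straddles
at most two bins, so its max-bin fraction is at least 50% and exactly
100% when aligned with a bin.

Cortex morphometry takes the annular actin ROI radii and reports the
thickness (r_major − r_minor)/2 and the ring intensity normalized by the
ring area π(r_major² − r_minor²).

## Volumetric nanoparticle counting

Beads of 44/200/500/1000 nm inside cells are quantified from confocal
z-stacks (0.35 μm slice spacing; 0.15 μm for 44 nm beads).  The
analysis excludes an axial depth of 10% of the cell's major radius from
the top and bottom of the stack (converted to slices by ceiling —
conservative), thresholds the remaining slab, and converts the
above-threshold voxel volume into a real-valued bead count by dividing
by the single-bead volume (4/3)π(d/2)³.  Aggregates therefore contribute
their volume without declumping.  For 44 nm beads — an order of
magnitude below the diffraction limit — only the voxel count is
reported.

Three threshold choices are provided, in increasing order of rigor:

1. mean of the four brightest pixels of a user-marked reference bead
   (`threshold_mean_top4`) — simple, but biased when the PSF smears a
   bead over many partially filled voxels;
2. reference-ensemble calibration (`calibrate_threshold`): the threshold
   at which the mean above-threshold volume over isolated-bead stacks
   spanning random sub-voxel alignments (and the acquisition's noise)
   equals one bead volume;
3. spike-in calibration (`calibrate_threshold_spike`): standards of
   known planted count imaged like the samples; the threshold zeroes
   the mean relative count error, which also absorbs density effects
   (overlap of blurred bead skirts at working concentrations).

A Gaussian detection filter of (0.8 slice, 1 px, 1 px) is applied before
thresholding (and identically during calibration); it approximately
matches the blurred single-bead profile and suppresses noise-driven
threshold crossings.

Accuracy is limited by axial sampling.  A 200 nm bead occupies ~60% of
one 0.35 μm slice, so its apparent brightness varies about two-fold with
its sub-slice alignment; calibration removes the resulting bias but not
the per-bead variance.  On the synthetic study conditions (about 30
beads per cell, SNR 10, lateral PSF σ = 1 px) the per-stack count error
has σ ≈ 7% for 200 nm beads and ≈ 2% for 500 nm beads; roughly 85–95%
(200 nm) and ~100% (500 nm) of stacks recover the planted count within
±10%.  These numbers characterize the estimator itself; real stacks add
optical backgrounds and aggregation not present in the generator.

## Transport classification

Delivered beads are tracked at 0.5 s sampling over 20 s (40 frames).
Per track, the time-averaged MSD is computed for lags up to half the
track length (a standard variance/bias compromise; configurable), and
log MSD is regressed on log lag with weights (n − k)/k — the inverse of
the leading-order variance of a time-averaged MSD point at lag index k.
Fits with R² ≤ 0.75 are rejected; accepted tracks with α ≤ 1 are
diffusive and 1 < α < 2 actively transported; α ≥ 2 (at or beyond the
ballistic limit) is labeled transported with a warning rather than
given a class of its own.  For accepted diffusive fits the 2-D relation
MSD = 4Dτ yields the diffusion coefficient.

A known statistical limitation: a *pure* Brownian track has true α = 1,
exactly on the decision boundary, so any (approximately) unbiased per-track
estimate classifies roughly half of such tracks as transported no
matter how good the estimator.  On synthetic mixtures of pure Brownian
and strongly directed tracks the directed class is recovered essentially
perfectly, but the diffusive share reads ~25 percentage points low.
Real intracellular cargo is typically *sub*-diffusive (α ≈ 0.7–0.9 from
crowding), which sits clear of the boundary; the synthetic mixture is
thus a worst case for this rule, and population fractions from it should
be read with that in mind.

## Pore-diffusion simulation

Uptake of beads through a membrane pore is modeled as Fick's second law
with spatially varying diffusivity in an axisymmetric (r, z) cylindrical
domain: a spherical cell (default radius 7.5 μm) centered in a bath of
unit bead concentration, a membrane shell of zero diffusivity, and a
pore — a patch of the shell on the symmetry axis restored to bulk
diffusivity — of 1.5 μm (fresh) or 0.5 μm (partially resealed).
Diffusivities come from Stokes–Einstein D = kT/(3πμd) with T = 310 K,
bulk viscosity 0.7 mPa·s (water at 37 °C) and a cytoplasm three times
more viscous; for 200 nm beads D_bulk ≈ 3.2 μm²/s.  All of these are
overridable.

The discretization is a conservative finite-volume scheme on annular
cells with harmonic-mean face diffusivities (so a zero-diffusivity
membrane blocks flux exactly), stepped with Crank–Nicolson via a sparse
LU factorization; no-flux outer boundaries make total mass conserved to
solver round-off, monitored at every output step with a 10⁻⁶ abort
tolerance.  The membrane shell thickness defaults to 0.25 μm — the
smallest grid-resolvable shell at the default 0.25 μm spacing — rather
than the physical ~5–50 nm; with zero diffusivity the shell thickness
does not affect the blocking behavior, only the (excluded) membrane
volume.  Validation: the uniform-diffusivity solver matches the analytic
Gaussian heat kernel to < 0.2% RMS; halving the grid changes uptake by
< 2%; uptake is non-decreasing in time, pore diameter, and membrane
diffusivity.  The default grid (0.25 μm over a 15 × 30 μm domain) runs a
20-minute simulation in a few seconds on one CPU.  The model contains no
advection, electrostatics, or particle–membrane interactions, and does
not attempt to reproduce any particular finite-element solver's numbers.

## Synthetic data — what it emulates and what it does not

All generators are pure functions of (parameters, seed).  Defaults
follow the study conditions: biexponential decays with dominant
lifetimes 4.7–6.5 ns; tension maps with in-window (red 120–180) spots at
norm_r = 1; z-stacks at 0.35/0.15 μm slice spacing with lateral PSF
σ = 1 px, axial PSF σ = 0.27 μm (the elongated axial response of a
high-NA confocal), additive Gaussian camera noise at SNR 10, and an
MCF-7-sized cell of semi-axes (7, 5) μm; trajectories of 40 frames at
0.5 s with Brownian steps of variance 2DΔt per axis and directed tracks
adding a constant v·Δt drift.  Not emulated: instrument response
functions, spectral bleed-through, autofluorescence backgrounds,
detector afterpulsing, bead aggregation, localization error in tracking,
and subdiffusive cytoplasmic motion.  Closed-loop tests passing on this
data therefore validate the estimators and their calibration logic, not
the full error budget of real acquisitions.

## Statistics and reporting

Condition comparisons use the Kruskal–Wallis rank test with the
conventional star annotation (* p < 0.05, ** p < 0.01, *** p < 0.001).
The pipeline runner executes stages in a fixed order, derives each
stage's random stream from the manifest seed, stamps every output row
with cell id, condition and stage, and reproduces outputs byte for byte
on rerun.  Osmolarity bookkeeping (e.g. a 0.5× dilution of ~274 mOsmol
PBS giving ~137 mOsmol, the hypo-osmotic calibration condition) is plain
dilution arithmetic provided for completeness.

## Problem sizes used in tests

The shipped test and acceptance runs use deliberately desk-scale sizes:
100 decay traces of 10⁵ photons; 20 z-stacks (10 each of 200 and
500 nm) with Poisson-mean-30 planted counts plus 6 spike-in standards
per size; 10 trajectory mixtures of 100 tracks; pore runs of 5 and 20
simulated minutes at 0.25 μm grid spacing; and a two-condition,
two-cell-per-condition end-to-end pipeline run.  These sizes were chosen
as the smallest that make the statistical tolerances meaningful.
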