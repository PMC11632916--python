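# Methods

`photogel` quantifies four assays used to characterize photo-crosslinkable
methacrylated collagen hydrogels and the lymphatic endothelial monolayers
cultured on them: oscillatory-shear stiffening profiles, transwell dextran
permeability, fibril microstructure, and cell/junction morphometry.  Every
assay has a seeded synthetic generator so the complete analysis chain can be
validated against known ground truth without any experimental data.

## Stiffening-profile analysis

A photo-rheology time sweep records the shear storage modulus G′(t) (and loss
modulus G″) of a gel that self-assembles for 10 min at 37 °C and is then
exposed to light, triggering radical crosslinking and a rise from a baseline
plateau G′_pre to a stiffened plateau G′_max.

The analysis follows the standard reduction: G′ is smoothed by locally
weighted regression (LOWESS, local linear, one robustifying iteration,
default span 0.05 of the series), the first derivative of the fit gives the
stiffening rate, and a threshold of 3 Pa/s splits the sweep into *plateau*
and *stiffening* regions.  Threshold runs shorter than 10 s (configurable)
are absorbed into their neighbors to suppress noise flicker.  Per replicate:

* pre-stiffening mean — raw G′ averaged over plateau samples before light
  onset (raw, not the fit: unbiased under symmetric noise);
* post-stiffening mean ("maximum stiffness") — raw G′ over the final
  plateau run;
* fold change — post/pre of the *same* replicate;
* time to plateau — total seconds the rate exceeds the threshold.

Group summaries are means and sample SDs across replicates (n = 1 reports
SD 0 and is flagged).  The span default is small deliberately: the light-
onset transition is sharp, and wider windows both smear the transition and
inflate the above-threshold duration.  The threshold comparison is one-sided
(rate > 3 Pa/s): these gels only stiffen.

### Synthetic time sweeps

The generator produces G′(t) as a **constant-rate linear ramp smoothed by a
Gaussian kernel** (edge sd σ), sampled at 1 Hz.  A logistic rise was
considered and rejected: for the LAP-like preset (amplitude 1.46 kPa) no
logistic rate constant can keep dG′/dt above 3 Pa/s for the required 360 s
(the maximum over rate constants is ≈ 218 s), whereas a near-linear ramp
sustains ~4 Pa/s comfortably.  The smoothed ramp is C∞, monotone, and admits
a closed form via ψ(x) = xΦ(x) + φ(x):

    G′(t) = G′_pre + r₀ σ [ψ((t−t₁)/σ) − ψ((t−t₁−R)/σ)],   r₀ = ΔG′/R.

The internal ramp duration R is calibrated numerically (bracketed root
solve on the exact rate profile) so that the noiseless rate exceeds 3 Pa/s
for exactly the preset `rise_time`, and the above-threshold interval starts
at light onset.  Presets: Ru/SPS 0.5 → 5.93 kPa, rise 180 s, σ = 30 s;
LAP 0.5 → 1.96 kPa, rise 360 s, σ = 10 s; Irgacure 0.5 → 1.38 kPa, rise
180 s, σ = 30 s.  LAP's σ must be small because its mean rise rate
(4.06 Pa/s) sits barely above the threshold; an infeasible
amplitude/rise-time combination raises an error rather than miscalibrating.
Replicate noise is additive Gaussian, default sd 100 Pa (a free choice —
replicate-level raw traces are not published; 100 Pa is a few percent of the
stiffened plateau, typical of parallel-plate time sweeps).  G″ is modeled as
a fixed fraction (0.1) of G′, consistent with G″ ≪ G′ for elastic gels.

What the generator does *not* emulate: secondary slow creep of the plateaus,
temperature equilibration transients, inertia/gap artifacts, or
heteroscedastic noise.  Passing recovery tests therefore shows the pipeline
is correct for monotone single-transition profiles, not that it handles
pathological rheometer output.

## Transwell permeability

A gel on a permeable insert separates a donor compartment (FITC-dextran at
C_d0 = 2 mg/mL) from an acceptor compartment sampled hourly; each aliquot is
diluted 1:25 and read on a plate reader.  A linear standard curve
(0–0.0125 mg/mL) converts fluorescence to concentration,
C_a = dilution·(RFU − intercept)/slope.  The estimator finds the contiguous
window (≥ 3 points) maximizing the R² of a straight-line fit — ties broken
toward longer, then earlier, windows — and applies the pseudo-steady
reduction of Fick's law:

    P = (dC_a/dt) · V_a / (A · C_d0)     [m/s]

with dC_a/dt the window slope.  C_d is approximated by its initial value
inside the linear region.  Replicate coefficients are cleaned with a
single-pass Grubbs test (α = 0.05) before group aggregation.

### Synthetic assays

The simulator integrates the full two-compartment system with donor
depletion — the concentration difference decays as exp(−λt) with
λ = P·A·(1/V_a + 1/V_d) — exactly (piecewise-exponential propagation between
sampling events), conserving mass to machine precision; each read removes a
20 µL aliquot from the acceptor (volume loss at unchanged concentration).
This deliberate nonlinearity is what the linear-window selector is tested
against, and extending sampling into the saturating regime demonstrably
biases the chord estimator low.

Packaged presets carry the six group permeabilities (uncrosslinked / 30 s /
90 s crosslinking × 40 kDa / 60–76 kDa dextran: 2.58e-6, 7.96e-7, 5.59e-7,
1.11e-6, 6.38e-7, 7.40e-7 m/s).  Preset geometry is an **idealized
diffusion cell** (A = 0.1 cm², V_a = V_d = 10 mL): with a typical 24-well
insert geometry (0.3 cm², 0.9 mL) the fastest group gives λ·1 h ≈ 0.3–1.7,
i.e. the acceptor saturates within the first sampling interval and *no*
chord-slope estimator can recover P from hourly samples.  The idealized
geometry keeps λ·3 h ≤ 0.06 for every preset, the quasi-linear regime the
analysis assumes.  For measured data the geometry is always user-supplied
configuration (a plausible 24-well default of 0.3 cm²/0.9 mL is used by the
CLI config template); reported P values scale directly with V_a/A, so they
are only as good as the geometry provided.  Plate-reader gain 8×10⁴
RFU/(mg/mL) and read noise sd 1 RFU place the diluted samples inside the
standard-curve range with ~1–10% per-point noise.

## Fibril microstructure

Reflectance-style fibril images are enhanced with a multi-orientation linear
white top-hat (default 8 orientations, 9 px lines): the maximum over
orientations retains curvilinear bright features and suppresses flat or
blob-like background.  The enhanced image is thresholded (Otsu by default)
and summarized as the **fibril area fraction** — foreground pixels / total
pixels.  The generator paints random straight segments (dilated to a set
width), returns the exact pre-blur mask as ground truth, then blurs and adds
noise.  Real collagen networks are curved, branched and three-dimensional;
the generator only establishes that denser networks yield larger measured
fractions (monotone recovery), not absolute accuracy on real reflectance
stacks.

## Monolayer morphometry

Nuclei (primary objects): Otsu threshold → hole filling →
distance-transform watershed declumping (peak seeds at least one minimum
nucleus radius apart) → area filter.  Cells (secondary objects): seeded
watershed from the nucleus labels on the smoothed junction-stain intensity,
restricted to a foreground mask (whole frame for confluent monolayers); each
cell contains exactly one nucleus and cells partition the foreground.

Per-object shape metrics: area (pixel count × pixel_size², holes filled),
perimeter, eccentricity of the moment-matched ellipse √(1 − (b/a)²), and
form factor 4πA/P².  **Perimeter estimator**: marching-squares boundary
polygon smoothed with a 5-point circular moving average.  Plain chain-code
perimeters overestimate smooth boundaries by ~4–5% (staircase bias), which
drives a rasterized disc's form factor to ~0.92; Crofton perimeters
underestimate straight edges.  The smoothed polygon is near-exact for both
(disc form factor 0.994, 50 px square 0.816 vs π/4 ≈ 0.785 analytic —
within the discretization tolerance used throughout).

Junction thickness: the junction-stain image is thresholded, nucleus
regions (dilated 2 px) are removed, and connected components that are both
compact (form factor > 0.8) and small (< 400 µm²) are discarded — these are
the rounded, brightly stained dead-cell artifacts.  The surviving network
is skeletonized; thickness at each skeleton pixel is **2 × the Euclidean
distance transform** (vessel-diameter convention, +≤1 px quantization for
odd widths).  Four square ROIs (default 256 px) are drawn uniformly at
random (seeded; redrawn if they contain no skeleton; overlap allowed) and
the result is the unweighted mean of per-ROI mean thicknesses, in µm.

### Synthetic monolayers

Cells are a Voronoi tessellation of seed points (two Lloyd relaxation passes
for even sizes), so mean cell area is exactly frame area / n_cells.  Nuclei
are rotated ellipses at the seeds; the junction channel is a band of the
preset width along cell boundaries plus bright discs (diameter below the
mean nucleus diameter, intensity above the junction's 95th percentile)
emulating dead-cell artifacts.  The soft preset has 90 cells and a 4 px
junction band, the stiff preset 40 cells and 8 px — encoding the observed
substrate-stiffness contrast (larger, more irregular cells and thicker
junctions on stiff gels).  Junction widths are even numbers of pixels, where
the 2×EDT thickness convention is quantization-exact.  The generator omits
intensity gradients, uneven illumination, out-of-focus blur and partial
confluence; segmentation scores on it (mean IoU ≈ 0.99) are an upper bound,
not an estimate of real-image performance.

## Statistics

Grubbs' two-sided single-outlier test is implemented from first principles:
G = max|x_i − x̄|/s with s the sample SD, critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t quantile on
n−2 df.  Removal is single-pass (at most one point) by default; an
iterative mode repeats until no outlier remains.  Zero-variance input
returns statistic 0, no outlier.

`compare_groups` gates on per-group Shapiro–Wilk normality (α = 0.05): all
normal → one-way ANOVA (Tukey HSD post-hoc for > 2 groups; for 2 groups the
ANOVA is the equivalent two-sample comparison); otherwise Mann–Whitney U
(2 groups) or Kruskal–Wallis (> 2, an extension beyond the original
two-group nonparametric path).  Under the null the gated procedure's
empirical type-I error at n = 10/group is close to nominal (checked by Monte
Carlo in the test suite).

## Numerical choices and degenerate inputs

* Sweeps: 1 sample/s; durations from interval spans; strictly increasing
  time required; fewer than 10 samples rejected by the smoother.
* Segmentation tie-break: run-merging flips the shortest sub-minimum run
  first, deterministic.
* Linear-window ties: R² compared at 1e-12 resolution, then longer, then
  earlier.
* Negative back-calculated concentrations are clipped to 0 with a warning.
* Watershed/labels: 8-connected, 0-based row-major coordinates.
* All generators consume a `numpy.random.default_rng(seed)` stream only, so
  outputs are bitwise reproducible per seed.

## Problem sizes used in validation

Recovery checks run at the study scale: 4 replicates per rheology group
(1801 samples each), 4 inserts per permeability group (4 time points each),
512×512 monolayer images with 3 seeds per condition, 100-series brute-force
window enumeration, 2000-draw Monte Carlo for the type-I error.

## Known limitations

* The permeability number is geometry-bound; without the true insert area
  and volumes it is an effective, not absolute, coefficient.
* The rheology segmentation assumes a single monotone stiffening
  transition; multi-pulse (burst) schedules segment correctly only if
  pulses are separated by resolvable plateaus.
* Junction thickness inherits skeleton sensitivity to mask roughness at
  widths near 2–3 px.
* Shape metrics assume 2D projections; no 3D morphometry.
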