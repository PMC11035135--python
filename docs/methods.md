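# Methods

This note records the models implemented in `reporterdiff`, the
parameter choices that matter, and what the synthetic validation does
and does not demonstrate.

## Diffusion-weighted MRI and the reporter contrast

The signal model is mono-exponential decay with diffusion weighting,
`S(b) = S0·exp(−b·D)`, with `b` in ms/µm² and the apparent diffusion
coefficient `D` in µm²/ms so that `b·D` is dimensionless
(1 µm²/ms = 10⁻³ mm²/s exactly). `effective_bvalue` evaluates the
standard Stejskal–Tanner expression `b = γ²G²δ²(Δ − δ/3)` for
rectangular gradient lobes; for the stimulated-echo timing emulated
here (δ = 5 ms, Δ = 300 ms) a gradient of ~43 mT/m gives b ≈ 1 ms/µm².

ADC is estimated as the negated OLS slope of `ln S` on `b`
(`fit_adc`), exactly recovering `D` on clean data for any ≥2 distinct
b-values. A nonlinear least-squares mode on `S0·exp(−bD)` is available
and agrees with the log fit on clean data; log-OLS is the default
because it is the direct transcription of "slope of the logarithmic
decay" and has no iteration/initialization concerns. Voxel-wise maps
(`fit_adc_map`) apply the same fit per voxel; voxels with any
nonpositive intensity are marked invalid rather than raising, whereas
the scalar fit raises and names the offending b-value — maps must be
robust, scalar fits explicit.

**Rician noise floor.** Magnitude MRI data are Rician distributed: the
expected magnitude decays not to zero but to σ√(π/2), flattening the
decay tail and biasing log-linear ADC fits low. At the acquisition
regime used for validation (S0/σ = 50, b up to 3 ms/µm²,
D up to 1.2 µm²/ms) this bias reaches ~10% and dominates every other
error source. When σ is known (from the phantom spec or a background
ROI), `correct_rician_floor` inverts the exact Rician mean function
E[M] = σ√(π/2)·L₁∕₂(−ν²/2σ²) (tabulated inverse, asymptotic form
ν ≈ m − σ²/2m beyond ν/σ = 60); both ROI means and N-average voxel
values share this expectation, so one inversion serves both paths.
With the correction, ROI fits recover D to <0.5% and voxel medians to
<2% under the validation conditions. Signals at or below the noise
floor are unidentifiable and are treated as unfittable points.

**Rendering.** Diffusion maps are smoothed with a median filter
(default kernel 3, reflect boundaries; invalid voxels are excluded
from each neighbourhood rather than contaminating it) and linearly
mapped to 8 bits between a lower and upper diffusivity, clamped. The
rendering is invariant to joint affine rescaling of (D, lower, upper).

**Contrast statistic.** `ΔD/D₀ = 100·(D − D₀)/D₀` compares
reporter-expressing to control cells; replicate aggregation reports
mean ± s.e.m. with the sample (n−1) standard deviation.

**Phantom conditions.** The pellet phantom defaults emulate the
hippocampal-line condition: control diffusivity 0.67 µm²/ms and a
79% reporter increase to 1.2 µm²/ms, on a 128×128 grid with four
b-values spanning 1–3 ms/µm² (the in-range schedule
{1, 1.67, 2.33, 3} is a configurable stand-in), 5 averages, S0/σ = 50,
two 18-voxel-radius compartments (~1000 voxels each). Per-channel
noise σ is S0/SNR referenced to the largest compartment S0 (scanner
noise is signal-independent); averages are combined as the arithmetic
mean of magnitude images, matching multi-average magnitude
acquisition. The high-contrast condition reported for the
breast-cancer line (~160% increase, D ≈ 1.8 µm²/ms) is *not* used for
noisy validation: at S0/σ = 50 the signal at b = 3 lies far below the
noise floor (ν/σ ≈ 0.2), where D is unidentifiable by any estimator;
recovery there would require higher SNR or a lower-b schedule.

## QPI morphometry

Optical path length is the discrete integral of index contrast along
the optical axis, `OPL(x,y) = Σ_z (n − n_surr)·dz` restricted to the
segmented cell; dry mass is `m = (Σ OPL · pixel area)/α` with
α = 0.18 µm³/pg, the accepted specific-refractive-increment constant
for eukaryotic cells. Mass is therefore exactly linear in index
contrast and thickness. Default voxels are 0.202 × 0.202 µm lateral,
0.363 µm axial; anisotropy is honoured everywhere.

Volume is voxel count × voxel volume. Surface area is measured on a
marching-cubes triangulation of the binary label (voxel spacing
applied), after Gaussian pre-smoothing of σ = 1 voxel: meshing a raw
binary grid yields a staircase surface that overestimates smooth areas
by ~9% and would bias sphericity `Ψ = π^(1/3)(6V)^(2/3)/S` low; with
the smoothing, a digitized radius-20-voxel ball gives S within 0.5% of
4πr² and Ψ within 0.4% of 1. Voxel-face counting was rejected for the
same reason (constant-factor overestimation). Sphericity may slightly
exceed 1 on digitized spheres; this is discretization, not error.

Segmentation of synthetic scenes thresholds index contrast at half the
nominal contrast and labels 26-connected components; components
touching the lateral image boundary are flagged excluded (measuring
them requires an explicit override), and components under 27 voxels
are dropped as noise. Real-data segmentation is expected to arrive as
a user-supplied label mask. Ground truth for ellipsoidal cells uses
the analytic volume (4/3)πabc and the Knud Thomsen surface
approximation (p = 1.6075, worst-case error ≈ 1.06%), which only
backs tolerance-based tests. Group comparisons report
mean(case)/mean(control) per metric with the s.e.m. propagated in
quadrature from the two group means.

## qPCR relative expression

Technical replicate Ct values within a sample are averaged first;
per-sample ΔCt = Ct(target) − Ct(housekeeping); ΔΔCt is the difference
of group-mean ΔCt; fold = 2^(−ΔΔCt). ΔCt is invariant to adding a
constant to one sample's target and housekeeping Ct (template-amount
cancellation), and swapping case and control inverts the fold exactly.
Dispersion and significance are assessed across biological samples
only: a two-sample t-test on per-sample ΔCt (equal-variance Student by
default, Welch by flag; one-sided available for comparisons whose
direction is known a priori, e.g. ER-stress induction). No
multiple-testing correction is applied across gene panels — results
are per-gene, which is a caveat for wide panels. Error bars are
emitted both as s.e.m. of ΔΔCt and as s.e.m. of per-sample folds,
labeled, since the two conventions differ.

Primer efficiency comes from the OLS slope of Ct versus log10 dilution
(dilution 1 = undiluted): E = (10^(−1/slope) − 1)·100, so a
perfect-doubling slope of −1/log10(2) ≈ −3.3219 cycles/decade gives
exactly 100% regardless of intercept. Nonnegative slopes return a
result flagged invalid with a diagnostic instead of a silent number.

The Ct generator plants fold F by shifting the case group's target Ct
by −log2(F) (100% efficiency), with Gaussian noise per technical
replicate; the expected ΔΔCt is −log2(F) exactly, making noiseless
round trips exact. Defaults: 3 biological samples and 3 technical
replicates per group, replicate σ = 0.15 Ct.

## Assay formulas

- Stimulation% = 100·CD3⁺CD25⁺/(CD3⁺CD25⁺ + CD3⁺CD25⁻); CD3⁻
  quadrants never enter, so the statistic is invariant to scaling all
  counts.
- Phagocytic index: background-subtracted integrated bead-channel
  fluorescence over cell regions divided by cell count. Background
  defaults to the median of non-cell pixels (robust to bright beads;
  configurable), and negative post-subtraction pixels clip to zero.
- Invasion area = escaped-pixel fraction × total imaged area
  (113.5 mm² default, the 10×10 tile mosaic); additive over disjoint
  regions and bounded by the total area.
- Viability-normalized caspase fold: per-well caspase/viability ratio,
  then mean(case)/mean(control); the ratio makes the fold invariant to
  proportional changes in cell number and to the plate reader's units.
- ELISA inversion: least-squares quadratic of signal on concentration,
  required to be strictly monotone over its dynamic range
  (0.1–12.8 ng/mL default); inversion selects the in-range root,
  refuses signals outside the calibrated signal range (no
  extrapolation), and treats two in-range roots as an error since a
  monotone curve cannot produce them. Concentrations divide by total
  protein for normalized secretion.

Fold changes everywhere are case mean over control mean.

## Orchestration and determinism

Every generator draws from a single `numpy.random.Generator` seeded
per call; no global state. The pipeline derives one seed per stage
from the run seed, logs parameters to stderr, and writes tables as CSV
with fixed float formatting plus a provenance record (config SHA-256,
seeds, package version) — a fully seeded run is byte-reproducible,
which the test suite asserts. Problem sizes for the bundled validation
runs (128×128 phantoms, ~1000 voxels per compartment, 50³–96³
tomograms, 2000-replicate t-test null) were chosen so the whole suite
runs in well under a minute while keeping Monte-Carlo errors small
relative to the tolerances being checked.

## What passing tests show — and what they do not

The generators emulate the *statistical* structure of the
acquisitions: mono-exponential decay with Rician magnitude noise and
averaging; piecewise-constant refractive index; Gaussian Ct replicate
noise at perfect amplification efficiency. They deliberately omit
k-space artifacts, eddy currents, partial-volume voxels, optical
diffraction, inter-run efficiency drift, and segmentation ambiguity.
Parameter recovery on these phantoms therefore validates the
estimators' correctness and noise behaviour, not the pipeline's
robustness to real-acquisition systematics; real data enter through
the same file interfaces with user-supplied masks.
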