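# Methods

## Scan-protocol model

A DOCT volume is acquired as `n_blocks` sequential sub-fields (blocks); each
block interleaves `locations_per_block` B-scan locations in a repeated
raster, so one location is revisited every `inter_frame_interval` (204.8 ms
by default) and accumulates `n_repeats` (32) frames. The per-frame slot is
therefore `inter_frame_interval / locations_per_block` (12.8 ms at the
defaults) — this value is implied by the protocol rather than stated
anywhere, and is derived, not configurable. Defaults: 8 blocks × 16
locations × 32 repeats → 4096 frames, 6.5536 s per block, 52.4288 s per
volume. Schedule timestamps are stored as exact rationals
(`fractions.Fraction`) so schedule invariants (equal revisit spacing,
conservation of total span) hold without float drift; floats appear only at
array/export boundaries. A-line-level timing is out of scope; the A-line
rate is carried as metadata.

Longitudinal grids are inclusive: 100 h at 4 h intervals gives 26
timepoints; at 30 min, 201.

## Dynamic-speckle generator

Per voxel the complex field is

    E(t) = √B · [ √(1−f) · E_static + √f · E_dyn(t) ],

with `f` the dynamic fraction (share of backscattered power from moving
scatterers), `B` the mean backscatter, `E_static` a fixed random-phase
unit phasor, and `E_dyn` a sum of `n_phasors` (default 16, minimum 8) unit
phasors whose phases perform independent Gaussian random walks with step
variance `2·Δt/τc`, giving the ensemble field autocorrelation

    g₁(τ) = (1−f) + f·exp(−τ/τc).

Detected intensity is |E|² plus exponential noise of mean `noise_floor`
(0.01 by default, in the same linear units as B), preserving speckle-like
statistics in the background; intensities are dB-scaled with a linear floor
of 10⁻³ (−30 dB). Voxels are statistically independent — LIV and OCDS_l
are per-voxel statistics, so lateral speckle correlation is irrelevant to
their contracts — and no point-spread function, beam refraction or bulk
motion is modeled. Phase walks are only simulated where f > 0; static
voxels keep their fixed phasor. Internally the walk runs in float32
(ensemble moments are far above float32 noise); a fixed seed gives
bit-identical output.

Consequences of the model worth knowing: fully developed dynamic speckle
(f = 1) has a dB-intensity variance of ≈ 31 dB² regardless of brightness,
so LIV saturates there; LIV rises monotonically with f at fixed τc.

### Tissue classes and phantoms

Absolute LIV/OCDS_l levels of viable versus dead tissue are not published,
so class parameters are calibrated only to straddle the LDV cut-offs
(3 dB², 2×10⁻⁴ ms⁻¹):

| class | f | τc (ms) | B | median LIV (dB²) | median OCDS_l (ms⁻¹) |
|---|---|---|---|---|---|
| viable shell | 0.8 | 1200 | 100 | ≈ 23 | ≈ 5×10⁻⁴ |
| low-dynamics (dead) | 0.02 | 100 | 100 | ≈ 0.7 | ≈ 7×10⁻⁵ |
| culture medium | 0 | — | 0.02 | ≈ 1.4 (noise) | ≈ 0 |
| well plate | 0 | — | 1000 | ≈ 0 | ≈ 0 |

Dead tissue is modeled as a small residual fraction of fast, weak jitter
(debris-scale Brownian motion): both its fluctuation amplitude (LIV) and
its late-window decay slope (OCDS_l) are low. Phantoms are spheres (default
90 µm radius on a 48³ grid of 5 µm voxels) with optional central core and
randomly placed spherical low-dynamics spots, an exterior medium, and a
static bright plate plane; ground-truth masks are retained for validation.

Longitudinal scenarios grow volume linearly in time (2 %/h by default) and
modify growth/dynamics from a 32 h onset: `control` (steady growth),
`dox_like` (growth arrest + core expanding at 1 µm/h), `tam_like` (growth
rate × 0.25, dynamics unchanged), `ptx_like` (growth arrest + 0.25
spots/h, 15 µm radius, persistent across timepoints).

What passing tests on these phantoms do **not** show: recovery of any
published biological magnitudes (raw study data are not deposited), realism
of absolute volumes, PSF-correlated speckle, spheroid drift, or
medium-opacity artifacts. The phantom validates the *pipeline*, not the
biology.

## Metric estimators

- **LIV**: population variance (divisor N) of the dB intensity over frames;
  "temporal variance" is ambiguous between N and N−1, so the convention is
  explicit and switchable (`liv_ddof`).
- **Autocorrelation**: biased, common-mean estimator
  ρ̂(k) = Σᵢ₌₁^{N−k}(Iᵢ−Ī)(Iᵢ₊ₖ−Ī) / Σᵢ(Iᵢ−Ī)², with Ī the full-sequence
  mean. Per-lag means and unbiased normalizations were rejected for their
  variance at N = 32; the estimator is pinned by brute-force oracle tests.
  Zero-variance voxels are flagged invalid (LIV = 0, OCDS_l undefined).
- **OCDS_l**: minus the OLS slope of ρ̂(τ) over grid delays inside the
  window (default 204.8–1228.8 ms, i.e. lags 1–6; lag 0 is never in the
  window). The sign convention makes faster decay a larger value, matching
  the use of a *lower* cut-off to mark low dynamics.

### OCDS_l is band-pass in τc

A late-window slope cannot be monotone in decorrelation time. If τc is
shorter than the first window lag the curve is already flat inside the
window (slope ≈ 0); as τc grows into the window the slope steepens; and
only on the slow side — once the remaining dynamic variance is diluted by
noise — does faster decorrelation again give a strictly higher OCDS_l.
Measured medians at f = 1 (no noise): ≈ 4×10⁻⁵ at τc = 200 ms, ≈ 3×10⁻⁴
at 600 ms, ≈ 5.5×10⁻⁴ at 1800 ms, peaking near τc ≈ 3–5 s. The estimator's
common-mean bias also tilts very-slow-τc curves downward at this N. The
monotonicity tests therefore check the rising edge (200 < 600 < 1800 ms)
and, at a noise-to-signal ratio of 0.5 where the slow side is expressed at
practical τc values, the strict decrease over {3.6, 10, 30} s. "Faster
decay → higher OCDS_l" is a within-band statement.

## Segmentation

Product image: LIV × max(⟨I_dB⟩ₜ − floor_dB, 0). The *time-averaged* dB
intensity is used (a single frame would add speckle noise for no benefit),
rebased to ≥ 0 so dim voxels cannot flip the product's sign. Then Gaussian
blur (σ = 2 voxels) → Otsu threshold (256 bins) → binary erosion (ball,
radius 1) → 26-connectivity labeling → hole filling → removal of
components < 100 voxels → component choice. Blur/erosion/size parameters
of the original procedure are not published; these defaults are exposed in
config, and only the step order is load-bearing. The spheroid is the
largest surviving component, ties broken by mean product; a manual label
override exists for late-timepoint floaters. The mask is invariant to
positive scaling of the product (Otsu acts on the relative histogram).
Degenerate (constant) inputs raise rather than guess.

## Quantification

Volume = voxel count × voxel volume (µm³ end-to-end). LDV counts
foreground voxels strictly below the cut-off (ties are not low;
switchable). OCDS-invalid voxels (static) count as low dynamics in
OCDS-LDV and are excluded from mean OCDS_l — a perfectly static voxel is
the semantic target of "low dynamics". LDV plus the ≥-cut-off volume
equals the mask volume exactly. The centroid (foreground center of mass)
recenters volumes for slice/montage export; no other registration is done.

## Statistics

Classical one-way ANOVA (F = MS_between/MS_within, p from the F
distribution) and Tukey HSD (studentized-range adjusted p, Tukey–Kramer
for unequal n) are implemented from the standard formulas — they are part
of the pipeline's reproduction surface — and cross-checked in tests
against `scipy.stats.f_oneway` / `scipy.stats.tukey_hsd` /
`scipy.stats.pearsonr`. Tukey tables are attached only when the ANOVA is
significant at α = 0.05. The many ANOVAs across metrics, timepoints and
drugs are deliberately *not* globally multiplicity-corrected (they address
independent questions); expect the nominal false-positive rate among
null tests. Significance symbols: '-' (p > 0.05), '*' (p < 0.05),
'**' (p < 0.01). A two-segment slope summary around a user-chosen
breakpoint is provided as a descriptive convenience only; no changepoint
detection is implemented because none is defined for the deflection-point
annotations it loosely mirrors.

## Problem sizes

The default grids are deliberately desk-scale: 48³ voxels (5 µm) for
phantom validation, 32³ with 8 phasors for the 100-run early-detection
experiment (two groups × four replicates through the full pipeline per
run), 10⁴–2×10⁴ voxels for ensemble calibration, and 10⁴ simulations for
ANOVA/Tukey error-rate checks. These sizes make the whole validation suite
run in a couple of minutes while keeping Monte-Carlo error well inside the
asserted tolerances; all are configurable.

## Known limitations

- No physical-optics speckle model (PSF, sub-wavelength displacement
  statistics); the generator matches the two stated sensitivities (f →
  LIV, τc → OCDS_l) and nothing finer.
- OCDS_l magnitudes depend on the estimator details at N = 32 (common-mean
  bias); they are internally consistent but not calibrated to any external
  reference.
- The early-detection experiment fixes the treated-shell dynamic fraction
  at 0.6 (vs 0.8 viable) as a moderate early effect; power is reported
  under that condition, not searched over effect sizes.
- Segmentation robustness degrades as the noise floor approaches the
  tissue backscatter; no opaque-medium or floater scenarios are generated
  by default.
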