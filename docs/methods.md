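# Methods

`carnotype` implements a non-invasive estimate of human muscle fiber-type
composition from the carnosine content of the gastrocnemius, measured by
single-voxel proton MRS. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the published
description left the design open.

## Physical model and quantification

A PRESS acquisition (TR = 2000 ms, TE = 30 ms, 128 excitations, 1024 complex
points over a 1200 Hz bandwidth at 3 T) yields an FID from a voxel of nominal
size 40 × 12 × 28 mm (13.44 ml). Carnosine's imidazole protons resonate at
≈7.0 ppm (C4-H) and ≈8.0 ppm (C2-H); quantification targets the C2-H line
because the 7.0 ppm resonance overlaps residual aromatic/amide signal in
vivo. The published analysis does not state which resonance it integrates;
this is a documented choice of the package.

Absolute concentration uses an external 20 mM carnosine phantom:

    C_m = C_r · (S_m/S_r) · (V_r/V_m) · (C_T1m · C_T2m)/(C_T1r · C_T2r) · (T_m/T_r)

with saturation correction `C_T1 = 1/(1 − exp(−TR/T1))`, decay correction
`C_T2 = exp(TE/T2)`, voxel volumes `V`, and absolute temperatures `T`. The
source describes this formula only through its symbol list; the arrangement
above is the standard external-reference form, with the temperature ratio
oriented so Curie-law polarization (∝ 1/T) penalizes the warmer muscle. The
arrangement is guarded by an identity test: when every muscle parameter
equals its phantom counterpart and S_m = S_r, the formula returns exactly
C_r = 20 mM.

None of the relaxation times or temperatures are published. They are
explicit config entries with literature-guided defaults (carnosine C2-H in
muscle: T1 = 1300 ms, T2 = 50 ms; aqueous room-temperature phantom:
T1 = 2200 ms, T2 = 250 ms; T_m = 310.15 K, T_r = 295.15 K), never buried
constants. Changing them changes the absolute scale of C_m but cancels out
of the synthetic round-trip, because the generator applies the same factors
it asks the quantifier to undo.

## Spectral processing

* **Transform.** The FID is apodized (optional exponential line broadening),
  zero-filled, and discrete-Fourier-transformed with dwell-time scaling so
  spectral areas carry signal × Hz units. The first FID point is halved by
  default (trapezoid-rule DFT) to remove the constant baseline offset a
  one-sided acquisition otherwise leaks into the spectrum; the plain DFT is
  available via `first_point_correction=False`.
* **Referencing.** The ppm axis is anchored by shifting the tallest peak in
  a 4.2–5.2 ppm search window to 4.70 ppm (water). Peak location uses
  parabolic sub-bin interpolation; a robust noise floor (median + 5 × 1.4826
  MAD of the whole magnitude spectrum) rejects noise-only windows.
* **Water linewidth.** FWHM by interpolated half-maximum crossings on the
  magnitude spectrum. The magnitude line is broader than the absorption
  line quoted by convention: exactly √3 × for a Lorentzian; for a Gaussian
  envelope the dispersion component is a Dawson function and the factor
  (≈1.785) is solved numerically. The estimator divides by the lineshape's
  factor so it reports the conventional absorption-mode FWHM.
* **Peak fitting.** Windowed nonlinear least squares (lmfit) of one analytic
  lineshape plus a polynomial baseline (default order 1) on the real part of
  the phased spectrum, magnitude fallback available. Default window
  7.6–8.4 ppm. Multi-start from linewidths {10, 25, 40} Hz, lowest RMSE
  wins; relative tolerances 1e-8, bounded parameters. The reported area is
  the analytic integral of the fitted lineshape, not a numeric window sum;
  the absorption-mode area of a one-sided FID of amplitude A is A/2, which
  cancels in the muscle/phantom ratio. Convergence is honest: optimizer
  success plus fitted signal height above 2 × residual RMSE.

## Synthetic data generator

The generator exists because no raw spectra or per-subject tables were ever
deposited; it emulates the study's conditions so every stage is testable.

* **Spectra.** Damped complex sinusoids (Lorentzian or Gaussian envelopes)
  with per-peak area proportional to concentration × voxel volume, plus a
  partially suppressed residual water line (suppression factor 0.002,
  linewidth 25.7 Hz — the study's average shim). Relaxation attenuation and
  Curie 1/T polarization are folded into the amplitudes so the
  quantification corrections invert them exactly. Complex white noise with
  SD `noise_sd/√(n_averages)` models thermal noise after averaging;
  `noise_sd = 48000` (signal units) was calibrated once so a single
  128-average scan shows ≈11.5% CV on quantified concentration at the
  reference mean, matching the published 11.9%/13.2% test–retest CVs.
* **Cohort.** Per subject, a latent fast-twitch area fraction is drawn from
  a category-specific Beta distribution (control centered ≈45% to match the
  29–62% biopsy range; explosive ≈65%; endurance ≈30%; mixed ≈50% — the
  last three are free parameters of the generator, stated in config).
  Carnosine follows `1 + (ratio − 1)·f` with a 2:1 fast:slow concentration
  ratio, affinely rescaled per sex × group × category cell to the published
  cell means/SDs (4.94 ± 1.43 control, 6.58 ± 0.92 explosive elite,
  3.75 ± 0.74 endurance elite, etc.). The configured SD is interpreted as
  the SD of the *observed* bilateral mean, so the latent-truth SD is
  deflated by the measurement-noise variance share. Left/right leg values
  apply independent unit-mean lognormal noise with CV 0.12 (between the
  published 11.9% and 13.2%); lognormal keeps concentrations positive.
  Female cell means are not published ("data not shown") and default to
  ≈20–25% below the male cells — an assumption, not a published value.
* **Runner panel.** Z-scores follow a 4-parameter logistic of log10(best
  distance) with truth top 1.5, bottom −1.2, d50 = 1000 m, hill 3 (chosen to
  match the published curve's midpoint at ≈1000 m and its Z range), plus
  Gaussian noise (SD 0.25); carnosine is back-computed via the male
  reference mean/SD.
* **Calibration sets.** %FT areas uniform on 29–62%, carnosine = 0.07 +
  0.107·x + N(0, 1.0²) mM. Slope and residual SD follow from the published
  r = 0.714 at the control population's spread; expected sample r at n = 12
  is ≈0.70 after small-sample attenuation.

What the generator does **not** emulate: J-coupling evolution, spatial
localization artifacts, eddy currents, motion, baseline roll from
macromolecules, and frequency drift. Passing tests therefore demonstrate
correctness of the estimation chain under the stated signal model, not
robustness to every artifact of real scanner data.

## Statistics

* **Z-scores** are computed within sex against the control (reference)
  population mean/SD.
* **Group contrasts** are two-sample t-tests from summary statistics,
  pooled variance by default (recomputing the published ex-athlete contrast
  from its printed summaries gives p = 0.0120, matching the printed 0.012;
  the talent contrast gives 0.0183 against a printed 0.019, consistent with
  2-decimal input rounding). Welch is available by flag. All p-values are
  two-sided; the 0.05 threshold only labels, never gates computation.
* **Calibration** is OLS of carnosine (y) on %FT area (x) — the direction
  the data were collected — with r and its t-transform p. Fiber-type
  estimation is inverse regression: x̂ = (y − a)/b, with a Fieller-type
  interval obtained by exactly inverting the prediction pivot
  (y0 − a − bx)² ≤ t²s²(1 + 1/n + (x − x̄)²/Sxx). The quadratic's roots
  bound the interval; when the slope is not significant at the level the
  set is unbounded and (−∞, ∞) is returned, as calibration theory requires.
  Coverage is exactly nominal by construction. Estimates outside [0, 100]%
  are clamped and flagged.
* **Discipline model**: z = bottom + (top − bottom)/(1 + (d/d50)^hill) on
  log10(distance), least squares with multi-start d50 at {0.3, 1, 3} × the
  geometric-mean distance (≈{300, 1000, 3000} m for a 100 m–marathon
  panel), bounded parameters, R² on the fitted points, non-convergence
  flagged.

## Numerical choices and degenerate inputs

Tie-breaks and edge cases are explicit: empty spectra, windows with < 8
samples, zero-variance correlation inputs, absent phantom signal, distances
≤ 0, and sub-decade distance spans are hard errors; a failed peak fit
returns `converged=False` with diagnostics rather than a silent fallback.
Spectrum files round-trip losslessly at float text precision in all three
dialects (JSON, CSV, and a minimal JCAMP-DX NTUPLES/AFFN FID subset —
vendor compression schemes are out of scope).

## Problem sizes

The simulation-backed checks use 200 subjects per cohort cell, 200
test–retest repeats, 500 calibration replicates, 1000 coverage replicates,
200 sigmoid-recovery replicates and 100k permutation draws — sizes at which
the Monte-Carlo error of each check sits well inside its tolerance band.

## Known limitations

* The quantification formula's arrangement and temperature direction are a
  reconstruction from the published symbol list; the identity test pins the
  structure but not, for example, partial-volume or tissue-water-content
  effects, which the published method also ignores.
* Per-subject calibration and runner data were never published, so the
  printed r = 0.714, p = 0.009, R² = 0.9874 and the 1.9-fold sprinter ratio
  cannot be reproduced exactly; they parameterize the generators, and the
  corresponding checks are parameter-recovery properties under generator
  truth.
* The t-transform p-value and the exact permutation p-value of r differ by
  O(1/n) for a single small sample (and the permutation null is discrete at
  n = 5); agreement is therefore asserted in aggregate, not per sample.
* Absolute concentrations inherit any error in the configured relaxation
  times and temperatures; these cancel only in simulation round-trips.
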