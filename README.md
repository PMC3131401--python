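# carnotype

Non-invasive estimation of human muscle fiber-type composition from the
carnosine content of the gastrocnemius, measured by single-voxel proton
magnetic resonance spectroscopy (¹H-MRS).

Excellence in sprint disciplines requires a high proportion of fast-twitch
(type-II) muscle fibers, endurance disciplines the opposite — but the gold
standard for fiber typing is an invasive biopsy with high sampling variance.
Fast-twitch fibers carry roughly twice the carnosine of slow-twitch fibers,
and carnosine is a stable trait of a muscle, so its ¹H-MRS signal (imidazole
protons at ≈7.0 and ≈8.0 ppm) is a usable non-invasive proxy for fiber-type
composition. This package implements that method end to end, for exercise
physiologists, MRS methodologists and sports scientists:

* **Quantification.** Absolute carnosine concentration against an external
  20 mM reference phantom:

  `C_m = C_r · (S_m/S_r) · (V_r/V_m) · (C_T1m·C_T2m)/(C_T1r·C_T2r) · (T_m/T_r)`

  with `C_T1 = 1/(1 − e^(−TR/T1))`, `C_T2 = e^(TE/T2)`, voxel volumes `V`
  and absolute temperatures `T`. Peak areas `S` come from windowed
  Lorentzian fits of the carnosine C2-H resonance.
* **Fiber typing.** A biopsy calibration line (carnosine vs % type-II
  area) inverted to estimate % type-II area from a measured concentration,
  with exact Fieller-type prediction intervals.
* **Cohort analytics.** Sex-stratified Z-scores, group summaries and
  pooled/Welch t-tests, and a four-parameter logistic of Z-score against
  log10 of an athlete's best running distance, whose midpoint `d50` marks
  the sprint/endurance transition (≈1000 m).
* **Synthetic data.** No raw data were ever deposited for this method, so
  the package ships a generator that reproduces the study's conditions —
  PRESS timing, 25.7 Hz water linewidth, 128-average SNR, the published
  group means/SDs and the 2:1 fast:slow carnosine ratio — making every
  stage testable against known ground truth.

See `docs/methods.md` for the model, assumptions and design choices.

## Worked example

Simulate one athlete's scan pair (true concentration 6.2 mM), quantify it,
fit a calibration from a 12-subject biopsy table, and estimate fiber-type
composition:

```sh
$ carnotype simulate pair --concentration 6.2 --seed 42 \
      --out-muscle muscle.json --out-phantom phantom.json
wrote muscle -> muscle.json, phantom -> phantom.json (seed 42)

$ carnotype quantify --muscle muscle.json --phantom phantom.json
S_m = 18193.7    S_r = 70785.1
V_m = 13440 mm^3    V_r = 13440 mm^3
C_T1m = 1.273417    C_T2m = 1.822119
C_T1r = 1.674734    C_T2r = 1.127497
T_m/T_r = 1.050822    C_r = 20 mM
C_m = 6.6378 mM

$ carnotype calibrate --pairs biopsy.csv --out calibration.json
calibration: slope 0.1061 mM/% , intercept -0.572 mM, r = 0.778, p = 0.0029, n = 12 -> calibration.json

$ carnotype quantify --muscle muscle.json --phantom phantom.json \
      --calibration calibration.json | tail -2
C_m = 6.6378 mM
estimated type-II area = 68.0% (95% PI 48.2-108.3%)
```

Reading the output: the audit lines show every factor entering the
formula — fitted peak areas (`S_m`, `S_r`), voxel volumes, the four
relaxation corrections and the temperature ratio. The estimate of
6.64 mM differs from the 6.2 mM truth by one scan's measurement noise
(test–retest CV ≈ 12% at 128 averages). The calibration line converts
that concentration to an estimated 68% type-II fiber area; the wide
prediction interval reflects the n = 12 calibration honestly (a point
estimate alone would hide it). Here `biopsy.csv`
(`subject_id,ft_area_pct,carnosine_mM`) was itself produced by the
synthetic calibration generator.

Cohort-level analysis works the same way from CSV tables:

```sh
carnotype simulate cohort --seed 7 --out cohort.csv
carnotype cohort --table cohort.csv --out-prefix study
carnotype simulate runners --seed 7 --out runners.csv
carnotype sigmoid --table runners.csv --out sigmoid.json
```

All of this is also available as a library (`import carnotype`); the CLI is
a thin layer over it.

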