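# Methods

This note documents the models, conventions and numerical choices behind
`ovilog`, and what the synthetic studies do and do not establish.

## Onboard ECG emulation (`ovilog.onboard`)

The vendor firmware is proprietary; only its contract is public: 3-s strips
at 200 Hz in, (HR bpm, quality 0–3) out, quality based on R–R regularity,
with missed R peaks detected as doubled intervals, corrected, and penalized
in the grade. The emulator is therefore a *declared convention* with that
contract, not a reverse-engineered copy:

- **Detection signal.** Squared first difference of the trace. A QRS
  complex rendered as a biphasic spike of amplitude A produces a transition
  energy of ~4A², while the 95th percentile of the detection signal tracks
  the noise floor (QRS samples occupy < 5 % of a strip below ~250 bpm).
  Threshold = max(θ_abs, θ_rel · p95) with defaults θ_abs = 100 µV²,
  θ_rel = 5. The multiplier sits between the noise tail and the QRS energy:
  spurious exceedances of 5·p95 under Gaussian noise occur at ~10⁻⁵ per
  sample, and the threshold stays below 4A² as long as p95 remains
  noise-dominated. Local maxima above threshold are pruned with a 200-ms
  refractory period (peaks closer than that keep the stronger one).
  Above ~250 bpm p95 begins to absorb QRS energy and sensitivity drops;
  the physiologic envelope of the study species (≤ 197 bpm) is well inside
  the safe range.
- **Missed-beat correction.** Any interval within [1.6, 2.4] × median(R–R)
  is split into two equal halves, both flagged corrected. The window is
  symmetric about 2× with slack for sinus-arrhythmia jitter; the total
  strip span is preserved exactly. Fewer than three peaks: returned
  unchanged, flagged.
- **Rate.** HR = 60000 / mean(R–R ms) over all intervals. The firmware's
  choice between corrected and raw intervals is unknowable; corrected is
  the default with a `use_corrected` switch.
- **Quality rubric.** CV = sd/mean of the R–R intervals: grade 0 if
  CV ≤ 0.05 without corrections; 1 if CV ≤ 0.05 with a correction (a fixed
  missed beat always costs one grade) or CV ≤ 0.12; 2 if CV ≤ 0.25; else 3;
  3 whenever fewer than two usable intervals exist. The cut-offs were fixed
  so that clean and mildly noisy synthetic strips land at grades 0/1, the
  accepted range.
- **Reference rates.** The manual reference uses the mean of the first and
  last interval only (what a reader measures off a plotted strip); the
  all-interval rate bypasses correction and serves min/max-HR candidates.

## Synthetic data (`ovilog.synth`)

The generators define the study conditions; all parameters are seeded
`numpy` randomness and every dataset carries its generating truth.

- **ECG**: QRS as a 4-sample biphasic spike (default 800 µV) on a flat
  baseline, additive Gaussian "EMG" noise, multiplicative R–R jitter
  (CV, default 0.01), independent beat suppression. No P/T waves or
  baseline wander — the onboard chain keys only on R peaks, and the visual
  quality classes are noise classes. Ground-truth visual grades are defined
  from the noise-to-amplitude ratio: I < 0.05 ≤ II < 0.2 ≤ III < 0.5 ≤ IV
  (zero amplitude is IV). These bands are declared conventions giving the
  visual classes an objective synthetic analogue; no SNR figures exist for
  the original strips.
- **Series**: value = mesor + seasonal(day) + A·cos(2π(h − φ)/24)
  + A₁₂·cos(2π h/12 + φ₁₂) + ε. Defaults are the field conditions: T_b
  mesor 39.6 °C, circadian amplitude 1.0 °C (so the ±2-h-smoothed daily
  peak-to-trough is 0.9549 × 2.0 ≈ 1.91 °C), acrophase 19:46 GMT, noise SD
  0.15 °C; HR levels 119/122/107 bpm for juvenile females / juvenile males
  / adult females, circadian amplitude 8 bpm, daily noise SD 6 bpm.
  Seasonal drift is piecewise-linear through knots; the default HR dip
  (+6 → −6 → +6 bpm over the 90-day season) integrates to zero so group
  levels stay identifiable, and T_b gets a shallow convex bump of opposite
  phase. Quality grades are drawn i.i.d. from a configurable mix.
- **Cohort**: 7/4/7 animals per group, adults (ewes) inland with HR only,
  lambs in both herds with HR + T_b; birth/implant/slaughter dates and
  birth/spring/fall weights from per-herd growth rates (~320 coastal / ~220
  inland g/day, SD 40). T_b series default to 10-min sampling in the cohort
  (configurable down to 1 min) to keep full-cohort studies light.
- **Not emulated**: weather/behaviour covariates, sensor failure and
  ejection, non-stationary rhythm phase, herd-level random variation.
  Passing recovery tests therefore shows the estimators are correct under
  the declared signal model, not that real sheep behave this simply.

## Rhythm analysis (`ovilog.rhythm`)

- **Periodogram.** Classical normalized Lomb-Scargle: mean-subtracted,
  variance-normalized (ddof = 1), per-frequency offset τ so that power
  equals the least-squares SSR of a single-frequency sinusoid fit divided
  by 2·variance — this identity is enforced to 1e-8 in tests. Grid in
  frequency space from 1/30 to 1/2 h⁻¹, oversampling factor 4
  (Δf = 1/(4·span)). Near 24 h the grid spacing of a 9-day window is
  ~0.67 h, so a pure 24-h signal lands on the 24.13-h grid point and rounds
  to 24.0.
- **Significance.** p = 1 − (1 − e^(−z))^M for peak power z. M is the
  effective number of independent frequencies, estimated as
  2.4 × span × bandwidth: the constant was calibrated the way Horne and
  Baliunas calibrated their M ≈ N (matching the null distribution of the
  grid maximum over white-noise simulations), here for a 4× oversampled
  band-limited search. A seeded permutation test is provided as an
  independent check; the formula and the permutation p agree on moderate
  peaks, and the empirical false-positive rate at α = 0.05 sits inside the
  binomial 95 % CI over 1000 white-noise replicates. z ≤ 0 returns p = 1;
  tiny e^(−z) switches to the asymptotic M·e^(−z) to avoid cancellation.
- **Sliding windows.** One result per center day whose full ±4-day window
  lies inside the series, window [d−4 00:00, d+5 00:00) GMT; the highest
  peak is recorded with its p-value, rounded to the nearest 0.5 h (ties at
  .25/.75 round half-up). Reported shares use *all* analyzed windows as the
  denominator; significant periods with individual share < 5 % pool into
  an "other" bucket. HR series enter only at quality 0&1 on the 10-min
  base schedule; T_b enters unfiltered.
- **Acrophase.** Daily zenith/nadir of the ±2-h centered rolling mean
  (edges use available data; days under 50 % nominal coverage are skipped).
  Calendar days are GMT; zenith and nadir of a day are chosen
  independently. Summary times are circular means on the 24-h circle with
  circular SD √(−2 ln R̄) in minutes (linear SD available as an option);
  an antipodal configuration (R̄ ≈ 0) raises rather than returning an
  arbitrary direction. "Daily amplitude" is zenith − nadir of the smoothed
  series, averaged — so a cosine of amplitude A reports ≈ 0.9549 · 2A, the
  closed-form attenuation of a 4-h moving average at 24 h.

## Seasonal trends (`ovilog.trend`)

- **Filtering.** HR above the accepted grades, everything before
  implant + 3 days, and the slaughter day are dropped. Daily means are
  plain unweighted means per animal-day (uneven within-day sampling is
  deliberately not reweighted).
- **Smoother.** Cubic B-splines on *uniform* knots extended beyond the data
  (P-spline construction), default basis size 10, with a second-difference
  coefficient penalty. On uniform knots a straight line has linear
  coefficients, so the penalty null space contains all lines: noiseless
  linear data are reproduced exactly at any λ, and adding a constant to the
  responses shifts the fit by exactly that constant. λ by generalized
  cross-validation over a log grid (10⁻⁴–10⁶), or fixed.
- **AR(1).** ρ is the pooled per-animal residual autocorrelation at lag 2
  (the configured convention; lag 1 available), clamped to (−0.99, 0.99),
  estimated from a working unwhitened fit, then the design and response are
  pre-whitened within runs of consecutive days per animal (run starts
  scaled by √(1−ρ²)) and the model is refit. ρ = 0 reduces exactly to the
  ordinary penalized fit.
- **Uncertainty.** σ̂² = RSS/(n − edf) on the whitened scale;
  cov(β) = σ̂² (XᵀX + λP)⁻¹ XᵀX (XᵀX + λP)⁻¹; pointwise SE on the daily
  grid; 95 % CI = fit ± 1.96·SE. Group contrasts subtract fits on a shared
  grid with SEs combined in quadrature; a day is "significant" when the
  interval excludes zero.
- **Design choice.** This is deliberately a fixed-structure penalized
  smoother rather than a generalized additive *mixed* model: individual
  variation can be absorbed by optional per-animal centering instead of
  random intercepts/slopes, and herd enters as a stratification rather than
  a random effect. The scientific surface — trend shapes, group contrasts,
  AR(1) handling — is preserved while every number stays reproducible from
  closed-form linear algebra. No smooth-term F-tests or likelihood-based
  model comparison are attempted.

## Validation statistics (`ovilog.validation`)

Cross-tabulation rates as defined in the README. Two textual ambiguities are
resolved explicitly: "algorithm quality above 2" is read as quality = 3
(the narrow reading, which matches the published counts; quality ≥ 2 is
available via `algo_reading="ge2"`), and "class II or better" means classes
I and II. Printed percentages round half-up to one decimal (ties away from
zero, as in the published tables). The growth comparison is a Welch
two-sample test on g/day, optionally residualizing a straight-line birth-day
trend first; the mixed-model machinery of the original growth and agreement
analyses is out of scope, with the forced-origin slope retained as the
agreement calibration.

## Problem sizes

Defaults were chosen to make every study cheap enough to run routinely:
500 clean strips for detector accuracy, 1000 strips for the end-to-end
error-rate study, 1000 replicates for significance calibration and the
growth type-I error, 60-day series at 10-min sampling for rhythm recovery,
and the 18-animal 90-day cohort for seasonal recovery. The full test suite
runs in well under a minute; the acceptance script in about half a minute.

## Known limitations

- The detector and quality rubric are conventions consistent with the
  documented contract, not the firmware; absolute error rates on real
  strips are not predicted by the synthetic ones.
- The independent-frequency count M is calibrated for the default window
  geometry (9 days, 2–30 h band, 4× oversampling); strongly different
  geometries should re-check calibration or use the permutation test.
- Sliding 9-day windows overlap, so per-window outcomes are serially
  correlated; reported proportions are descriptive, not independent trials.
- The P-spline reports pointwise, not simultaneous, intervals; contrast
  "significant days" inherit that.
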