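# Methods

`thermohrv` estimates heart-rate-variability (HRV) metrics from facial
infrared-thermography (IRT) temperature traces, with
photoplethysmography (PPG)-derived HRV as the reference. This note
documents the models, conventions and numerical choices, what the
synthetic cohort does and does not emulate, and the known limitations.

## Measurement model

The premise is physiological: cardiac and respiratory activity modulate
facial skin blood volume and airflow, which leave band-limited
oscillations in the skin temperature of the glabella (G), nose tip (NT)
and nostrils (N). Thirty candidate predictors (10 features x 3 ROIs) are
computed from 60-s, 10-Hz ROI temperature traces, and each HRV metric is
estimated by an epsilon-insensitive support-vector regression (SVR) with
a linear kernel:

    y_hat = w . z(x) + b

where `z` denotes z-scoring of the selected features. A linear kernel
keeps the weights interpretable (sign and magnitude per predictor) and
resists overfitting at a cohort size (n = 32) that barely exceeds the
candidate count (30).

## PPG processing

* Band-pass 0.2-10 Hz, zero-phase (forward-backward) order-2
  Butterworth, with *even* edge extension. Odd (default) reflection of a
  record that ends mid-pulse-gap excites a slow high-pass transient that
  mimics a beat; even extension removed all such artifacts in testing.
* Z-score normalization (sample SD, ddof = 1 — the MATLAB convention,
  used consistently for every normalization in the package).
* Beats are local maxima above amplitude 0 on the z-scored signal, with
  a refractory distance of 0.33 s (maximum plausible heart rate 180 bpm)
  and a minimum prominence of 0.5 z-units: genuine pulse peaks sit at
  prominence >= 1 while filter/noise ripples stay below ~0.45, so 0.5 is
  the midpoint of an empty margin, not a tuned constant.
* Beat times are then re-localized as the argmax of a low-pass-only
  (10 Hz) zero-phase filtered signal within 0.1 s of the detected peak.
  The 0.2 Hz high-pass bends the baseline over ~5 s near record edges
  and can tilt a flat-topped pulse by a sample or more; the low-pass
  path has no such bend. With this two-stage scheme the synthetic
  round trip is exact to the half-sample quantization limit.
* No ectopic-beat correction is applied; RR intervals outside
  [300, 2000] ms are logged as warnings but never altered.

## HRV metrics and conventions

Seven metrics per subject: mean HR (bpm), mean RR (ms), SDNN (ms),
RMSSD (ms), pNN50 (%), TINN (ms), LF/HF. Where the literature admits
more than one convention, the package pins:

* **mean HR** — mean of instantaneous rates `60000/rr` (an `"overall"`
  mode computing `60000/mean(rr)` is exposed; the two differ by Jensen's
  inequality).
* **SDNN** — sample SD (n-1 denominator).
* **pNN50** — NN50 divided by the *total number of RR intervals*
  (`len(rr)`), not by the count of successive pairs. This follows the
  source definition the package implements; note that the Task Force
  convention divides by the number of successive differences, so values
  here are smaller by a factor `(n-1)/n`.
* **TINN** — RR histogram with 1/128 s (7.8125 ms) bins aligned to the
  bin grid; a triangle with apex at the modal bin's height is fit by
  exhaustive search over base endpoints N <= mode <= M on the bin-center
  grid, minimizing the squared error against the counts. N and M are
  confined to the occupied histogram range — allowing them outside it
  always admits a wider zero-error triangle, making the statistic
  degenerate — and error ties resolve toward the widest base. A
  single-occupied-bin histogram returns 0.
* **LF/HF** — tachogram (RR value at each interval's ending beat time)
  cubic-spline resampled at 4 Hz, mean-detrended, Welch periodogram
  (Hann window, segments up to 256 samples), powers integrated over
  LF = [0.03, 0.15) Hz and HF = [0.15, 0.35) Hz. On a 60-s record the
  0.03 Hz LF edge spans under two cycles; the package computes the
  printed band regardless and emits a warning. A numerically zero HF
  power flags LF/HF as missing (NaN) rather than failing the subject.

## Thermal features

Per ROI: mean, SD, kurtosis, skewness, delta, SampEn, 75th percentile,
and mean power spectral density over the myogenic (0.04-0.15 Hz),
respiratory (0.15-0.5 Hz) and cardiac (0.5-1 Hz) bands, all below the
5 Hz Nyquist limit of the 10-Hz camera.

* Kurtosis is non-excess (Gaussian -> 3); skewness and kurtosis of a
  constant trace are undefined and flagged (NaN + warning).
* delta = mean(last 5 s) - mean(first 5 s); positive means warming.
* SampEn(m = 2, r = 0.2 x SD, Chebyshev distance, self-matches
  excluded), the field-standard defaults, both exposed in configuration.
  A constant trace returns 0 (every template matches trivially); a
  series with no template matches at m or m+1 is flagged as missing.
* Band PSDs use a Welch estimate with 30-s Hann segments and 50%
  overlap, mean detrending, and half-open bands [lo, hi) so the shared
  0.15 Hz edge is never double-counted.
* ROI extraction from thermal video is out of scope; the package
  ingests precomputed per-frame ROI mean temperatures. `reduce_frames`
  (mean over a fixed half-open pixel box) exists for synthetic frame
  stacks only.

## Regression and stability

* Features and the target are z-scored (ddof = 1) *inside each training
  fold only*; held-out rows never influence the scaling. The target is
  z-scored so the epsilon tube (default 0.1) is unit-free; predictions
  are mapped back to physical units.
* SVR hyperparameters: C = 1, epsilon = 0.1, no hyperparameter search.
* **Wrapper selection** is greedy sequential forward selection scored by
  out-of-fold Spearman r, averaged over 5 seeded random fivefold
  partitions, capped at 12 predictors. A candidate is accepted only if
  it improves the score by more than one standard error of a null
  Spearman estimate, `1/sqrt(n-1)` (~0.18 at n = 32). This threshold is
  the load-bearing guard against selection overfitting: with 30
  candidates and 32 subjects, accepting arbitrarily small gains grows
  4-9 spurious predictors on pure-noise targets and inflates the null
  cross-validated correlation to 0.3-0.6, whereas the one-SE rule keeps
  null cohorts at |r| <= ~0.3 and leaves strong-signal recovery
  untouched. An explicit numeric threshold can be configured instead.
* Selection runs once on the full dataset before the bootstrap (one
  fixed predictor set per metric, mirroring a per-metric predictor
  table). This ordering carries residual selection optimism even with
  the one-SE rule — the single best-of-30 chance feature retains a null
  CV correlation of roughly 0.1-0.3 — which is why null calibration is
  part of the acceptance surface. A fully nested `select_per_fold` mode
  re-selects inside every training fold at substantial cost.
* **Fold bootstrap**: fivefold partitions (sizes {7,7,6,6,6} at n = 32)
  are re-drawn `n_bootstrap` times (default 1000; the test and
  acceptance surfaces use 200 to keep runs short) by seeded shuffle; the
  distribution of out-of-fold Spearman r quantifies fold sensitivity.
  The representative iteration is the one with r closest to the mean
  (ties: lowest index); its out-of-fold predictions feed the agreement
  analysis, and the model refit on all rows supplies the reported
  weights.

## Agreement evaluation

Spearman rank correlation, least-squares regression of predicted on
measured (slope, intercept, r^2), Bland-Altman bias with 1.96-SD limits
of agreement, and a two-sided paired t-test (df = n-1). Differences are
`predicted - measured` everywhere, so bias and t share a sign. Spearman
p-values are not computed; only the t-test carries a p.

## Synthetic cohort

Real paired recordings are not publicly deposited, so verification rests
on a generator with analytically known truth:

* **Rhythm**: instantaneous RR(t) = mean_rr + lf_amp sin(2 pi 0.1 t) +
  hf_amp sin(2 pi f_b t); beats placed iteratively (integral-pulse-
  frequency-modulation flavour). The 0.1 Hz tone is the LF band centre;
  f_b is the subject's breathing frequency. Beats start and stop 0.25 s
  inside the record so every pulse waveform fits and the band-pass
  filter has settling room; a boundary-truncated pulse loses most of
  its filtered amplitude and is undetectable in principle.
* **PPG**: one raised-cosine lobe (width 0.3 s, unit amplitude) per
  beat, plus white noise (default SD 0.1 a.u., ~ 23 dB below the pulse
  after band-passing).
* **Thermal**: per ROI, baseline (G 34.5, NT 33.8, N 33.2 degC) +
  half-period cosine drift (0.1 degC) + respiratory tone at f_b (largest
  at N: 0.08 degC, vs 0.05 NT, 0.01 G) + cardiac tone at the mean heart
  frequency with amplitude 0.002 degC/bpm x mean HR + myogenic tone at
  0.095 Hz with amplitude 0.002 degC/ms x RMSSD + white noise
  (0.01 degC). Coupling is linear by construction, matching the linear
  kernel's assumption.
* **Cohort defaults** (the study conditions): n = 32, 60-s records, PPG
  at 370 Hz, thermography at 10 Hz; per subject mean_rr ~ U[1050, 1400]
  ms, lf_amp, hf_amp ~ U[10, 60] ms, f_b ~ U[0.2, 0.33] Hz. The mean_rr
  range keeps the mean heart frequency (1000/mean_rr = 0.71-0.95 Hz)
  inside the 0.5-1 Hz cardiac analysis band; typical faster adult hearts
  would fall outside that band's upper edge, a constraint inherited from
  the band definition, not from physiology.

What the generator does *not* emulate: pulse-morphology variability and
motion artifacts in the PPG; thermal drift nonstationarity, tracking
jitter, vasomotion broadband structure, and nonlinear or lagged
HRV-temperature coupling. Passing recovery tests therefore shows the
pipeline is correct and calibrated under linear coupling with white
noise — not that real facial thermography carries this much recoverable
HRV information.

## Degenerate inputs and numerical edges

Constant series raise or flag rather than return garbage (z-score,
moments, Spearman, paired t on zero-variance differences); constant
predictor columns are dropped with a warning; a constant target makes
selection impossible and is reported as such. Ties in selection go to
the lowest column index, in the representative-iteration choice to the
lowest iteration index, and in the TINN fit to the widest base. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; repeated runs are byte-identical.

## Problem sizes

Default test and acceptance runs use 32-subject cohorts with 200
bootstrap iterations per metric (the full 1000 of the reference
procedure changes r_mean by < 0.01 in spot checks); end-to-end smoke
tests use 10-12 subjects with 5-25 iterations.

## Known limitations

* The 60-s window under-resolves the LF band (see above); LF/HF values
  are reported but carry that caveat.
* pNN50's denominator convention (see above) makes values incomparable
  with Task-Force-convention implementations at small n.
* Selection-before-bootstrap optimism is documented, quantified by the
  null-cohort calibration, and avoidable via `select_per_fold` at cost.
* The agreement analysis assumes one prediction per subject (the
  representative bootstrap iteration); it does not propagate bootstrap
  spread into the Bland-Altman limits.
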