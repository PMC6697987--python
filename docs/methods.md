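# Methods

This note documents the models, numerical choices and limitations behind
`tremorprofile`, in the order the pipeline applies them.

## Signal preprocessing

Movement parameters are 1-D signals: joint angles in degrees pass through
unchanged (the spectral stage is inherently band-limited), while the hand's
translational and rotational tremor are reduced to their dominant axes.

- **Band-pass filter.**  2–10 Hz, 4th-order Butterworth applied
  forward–backward (zero phase).  The double pass gives ≥ 20 dB attenuation
  one octave below the low edge and at 14 Hz; zero phase matters because the
  analysed segments are short (1.5–10 s).
- **Dominant axis.**  Principal-component analysis of the band-passed
  triaxial signal; the projection axis is the leading eigenvector of the
  3×3 covariance, with its sign fixed so the first nonzero loading is
  positive (PCA sign is otherwise arbitrary; a fixed rule makes runs
  reproducible).
- **Acceleration → displacement.**  Double integration performed in the
  frequency domain — division by `(i2πf)²` restricted to 2–10 Hz — which
  sidesteps the drift accumulation of time-domain integration entirely;
  output in millimetres.  Frequencies below 2 Hz never enter the analysis,
  so integration drift is a non-issue by construction.
- **Windows.**  Annotated in seconds; mapped to samples half-open,
  `[round(start·fs), round(end·fs))`.

## Amplitude extraction

The average tremor amplitude (ATA) of a windowed signal:

1. **Welch PSD** with rectangular (boxcar) 1 s segments at 50% overlap,
   zero-padded to a grid spacing ≤ 0.25 Hz (≥ 8 bins per ±1 Hz band).
   Tapering is deliberately avoided: on 1.5–3 s signals a taper discards a
   large fraction of the data; ambiguous spectra are instead *excluded* by
   the screening rules below.  Segments are linearly detrended, which
   suppresses in-band leakage from sub-2 Hz voluntary drift (a slow
   oscillation looks like a ramp within a 1 s segment) by roughly 3×
   relative to mean removal, at no cost to in-band tones.
2. **Tremor peak** `f_T`: the PSD maximum within 2–10 Hz; ties resolve to
   the lowest frequency.
3. **ATA band** `f1 = max(2, f_T − 1)`, `f2 = min(10, f_T + 1)` Hz.
4. **ATA** `= 2√2 · sqrt(Σ_band X(f) Δf)`.  The calibration contract — a
   pure sinusoid of zero-to-peak amplitude A must return its peak-to-peak
   amplitude 2A — is treated as normative, and band-integrated power is the
   estimator that satisfies it independently of sampling rate, duration and
   grid spacing: a sinusoid's band RMS is `A/√2`, and `2√2` converts RMS to
   peak-to-peak.  (A literal discrete sum of `√X(f)` with a fixed constant
   cannot satisfy the contract across grids; its printed normalisation is
   under-determined with respect to PSD convention.)  Measured worst-case
   calibration error across 2.5–9 Hz, 50–200 Hz sampling and 1.5–10 s
   durations: 6.9%.

### Screening (rejection heuristics)

Estimates are screened per repetition, in order:

- **R1 `short_window`** — the window is shorter than 1.5 s (three cycles at
  the 2 Hz lower band edge).
- **R2 `weak_peak`** — the tremor band `f_TB` spans the PSD bins between
  the local minima nearest the peak on either side (searched within
  1.5 Hz, clamped to 2–10 Hz); the comparison band `f_CB` is the remainder
  of 2–10 Hz.  Reject if `mean X(f_TB) < P50(X(f_CB))`.
- **R3 `ambiguous_peak_*`** — only evaluated when R2 passes.  `Δ_TB` is
  the PSD range over the tremor band; `Δ_CB` the **signed** differences
  between consecutive local-extremum values of `X(f_CB)` (the comparison
  band treated as one array in frequency order).  Reject if
  `Δ_TB < 2·P70(Δ_CB)` or `Δ_TB < mean(Δ_CB) + 3·sd(Δ_CB)` (sample SD).
  Keeping the differences signed makes their standard deviation capture the
  full swing between adjacent extrema: the alternating signs give a near-zero
  mean, so `mean + 3·sd` is a genuinely demanding threshold.  With absolute
  differences the same rule rejects only ~57% of pure-noise spectra; the
  signed form rejects ~84% (3 s at 100 Hz) while accepting essentially all
  clear tremor tones, with acceptance monotone in SNR.
- Local extrema are defined by a strict sign change of the first
  differences, with plateaus collapsing to their left edge.  A comparison
  band with fewer than 3 extrema leaves `Δ_CB` undefined: R3 is skipped and
  the estimate accepted, with a `sparse comparison band` warning logged —
  failing open preserves data while keeping the event auditable.
- Percentiles use linear interpolation between order statistics.

Surviving repetitions' natural-log ATA values are averaged into the
per-instance, per-parameter estimate; if none survive the estimate is null.
Null is a first-class value end-to-end (NaN in memory, empty field in CSV);
zero is a legal amplitude and never means missing.

## Profiling and change metrics

The characteristic vector is the element-wise mean of a subject's
measurement vectors over the valid entries (`m_j` counts them; an entry is
null iff `m_j = 0`), computed from *all* of the subject's measurements —
including the pair being compared.  Before any metric, parameters null in
any participating vector are excluded from all of them, and the reduced
characteristic vector is renormalised to unit length.

- Scale change is the dot product of the difference with the unit profile;
  scale2 uses the element-wise squared profile (renormalised), which raises
  the relative weight of the dominant joints on a continuous scale.
- Profile change is the norm of the perpendicular component
  (Gram–Schmidt rejection).  In 2-D/3-D this equals the cross-product
  magnitude; the rejection norm is its unique dimension-general equivalent,
  needed because profiles here have up to 17 parameters.
- For heterogeneous parameter sets (hand displacement in mm alongside hand
  rotation in deg/s) amplitudes are z-scored cohort-wide first; the SD is
  the sample SD (divide by n−1), and the stats used are always returned
  alongside the normalised vectors.  Homogeneous joint sets are *not*
  z-scored — that would artificially inflate joints that barely tremble.
- Joint subsets: the N parameters with the greatest characteristic
  amplitudes, nulls ranked last, ties broken by the canonical parameter
  order under a stable sort.
- Intrinsic-variability adjustment: the between-day metric (averaged over
  the two instance pairings, sign preserved) divided by the same-day metric.
  For signed metrics the denominator takes absolute values by default:
  signed same-day differences can cancel or go negative, which would make
  the ratio meaningless as a variability scale.  The literal signed form is
  available behind `denominator_mode="signed"`.  The adjusted value is null
  whenever a day lacks two valid instances or the denominator is zero —
  which is exactly why the same adjustment cannot be applied to coarse
  integer scales, whose same-day differences are typically zero.

## Statistical evaluation

Associations use squared Spearman rank correlations (robust to outliers, no
distributional assumptions) with the asymptotic two-sided p-value; pairs
with nulls are dropped and results with fewer than 3 complete pairs or a
constant series are null.  The N = 2..15 joint-count variants of each joint
metric form one Benjamini–Hochberg family per reference score; hand and
univariate metrics are reported unadjusted.  The BH adjustment is the
standard step-up procedure (via statsmodels), cross-checked in the tests
against an independent brute-force implementation.

The two discretisation experiments quantify scale-coarseness effects:
(1) continuous uniform values vs a copy rounded to k levels — ρ² rises
monotonically from 0.75 at two levels towards 1; (2) Gaussian changes of SD
σ applied to a continuous variable and to its 0–4 integer-rounded copy —
ρ²(Δx, Δy) falls well below 1 once σ drops under one scale interval.  The
shifted values in experiment 2 are rounded but not clipped: clipping would
saturate nearly all values at large σ and destroy the near-perfect
correlation the experiment is designed to demonstrate.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes — a
persistent per-subject blend with variable overall scale — not real
biomechanics:

- measurement vectors `a_i = s_d·c + η_d + ε_i` with unit-norm lognormal
  profiles `c` (a few joints dominate, as observed clinically), day scale
  `s_d = exp(N(0, scale_sd))`, per-day blend perturbation
  `η_d ~ N(0, profile_noise_sd)` and per-instance noise
  `ε_i ~ N(0, within_day_sd)`;
- defaults: 24 subjects, 15 parameters, 2 instances × 2 days,
  `scale_sd = 1.0` (typical severalfold between-visit amplitude ratios,
  matching the pronounced session-to-session variability of MS intention
  tremor), `profile_noise_sd = 0.1`, `within_day_sd = 0.15` (both relative
  to the unit profile norm);
- raw signals: per parameter a sinusoid at the subject's stable tremor
  frequency (drawn once per subject from 3–8 Hz) with amplitude from the
  vector-level truth and random phase, plus white noise and a 0.3 Hz
  voluntary-movement drift; three annotated 3 s repetitions per instance,
  mirroring the finger-to-nose hold;
- observer scores discretise a latent severity: one rounded clipped 0–4
  item (part A analogue) and sums of several noisy items (parts B/C
  analogues), with item noise proportional to severity so zero severity
  scores exactly zero.

What passing tests on this generator do **not** show: robustness to ataxia
or other non-tremor movement, nonstationary or intermittent tremor,
multi-harmonic spectra, sensor artefacts, or realistic joint coupling.  The
generator is additive and stationary by design; real recordings are not.

## Problem sizes and numerical conventions

Test and acceptance computations use 30-subject cohorts over 20 seeds for
parameter recovery, 100-seed Monte-Carlo rates for the screening rules
(3 s segments at 100 Hz, the protocol's minimum hold duration and the
typical IMU rate), 200 permutations for the FDR null, and 100,000 samples
for the discretisation experiments — sizes at which every Monte-Carlo
quantity asserted is stable to well within its tolerance.  Parameter
recovery is measured as one pooled Spearman correlation across the 20-seed
ensemble; per-seed coefficients at n = 30 carry substantial small-sample
noise.  All simulations take explicit seeds and are bit-reproducible; PSD
grids are uniform by construction; peak ties, ranking ties and PCA signs
all have fixed deterministic rules (documented above) so identical inputs
give byte-identical outputs.

## Known limitations

- The adjusted change `d'_X` is a ratio of noisy quantities with only two
  same-day differences in the denominator; it is heavy-tailed, and rank
  statistics (as used here) are the appropriate way to consume it.
- `d_S2` tracks the *linear* scale difference between days; against a
  log-scale ground truth the rank agreement has a structural ceiling
  (~0.9) independent of measurement noise.
- The screening rules were designed for spectra with a single dominant
  peak; strongly multi-peaked tremor (e.g. with harmonics) may be rejected
  even when genuine.
- The cohort fixture carries rating-scale summaries only; sensor recordings
  for real subjects must be supplied by the user.
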