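# Methods

## The experiment being modelled

A standing subject receives support-surface translations from a motion
platform while surface EMG is recorded at 4 kHz from three lower-leg muscles:
tibialis anterior (TA), soleus (SOL) and medial gastrocnemius (MG).  Three
translations are used — Anterior-large (7.0 cm, 25.0 cm/s), Anterior-small
(3.5 cm, 10.0 cm/s) and Posterior-large (7.0 cm, 25.0 cm/s) — arranged into
five conditions: NoPerturbation, Low (Anterior-small only), High
(Anterior-large only), Posterior (Posterior-large only) and Random (all three
interleaved unpredictably).  Each condition block has 15 trials: in 10, a TMS
pulse over the leg motor cortex is delivered 50 ms before perturbation onset
and elicits a motor-evoked potential (MEP); the remaining 5 are catch trials
without TMS, used to measure the perturbation-evoked long-latency EMG burst
uncontaminated by stimulation.  In the Random condition the three
perturbations occur with near-equal probability: the 10 MEP trials carry a
random permutation of (4, 3, 3) occurrences and the 5 catch trials a
permutation of (2, 2, 1).

The scientific quantity of interest is corticospinal *presetting*: the MEP
amplitude measured just before the perturbation indexes how strongly the
corticospinal pathway has been prepared for the predicted postural demand.

## Synthetic generator

Human EMG from this protocol is not redistributable, so the package ships a
generator whose output has the statistical structure the analysis assumes.
Each piece is simple enough to invert analytically, which is what makes the
pipeline testable against ground truth.

**Background activity.** Stationary zero-mean Gaussian noise, synthesized in
the frequency domain under a 15–1000 Hz mask (raised-cosine transitions at
15–20 and 950–1000 Hz, inside the band) and rescaled to an exact per-muscle
RMS.  Defaults: TA 8 µV (near-silent in quiet standing), SOL 20 µV, MG 15 µV
(postural tone).  Out-of-band power is exactly zero, so the band-limitation
contract is checkable by periodogram.

**MEP.** A biphasic Gaussian-windowed sinusoid (one positive, one negative
lobe; duration 10 ms) inserted at a per-muscle latency after the TMS marker
(TA 28 ms, SOL/MG 30 ms), scaled so its sampled peak-to-peak equals
`mep_mean_pct/100 × M-max × f_trial`, where `f_trial` is a mean-one lognormal
trial factor with CV 0.2.  Latency + duration never exceeds 40 ms, so the
analysis window captures the full waveform; violating configurations raise an
error.

**Long-latency burst.** Amplitude modulation of the background: the trace is
multiplied by an envelope that rises (raised cosine, 10 ms) from 1 to a
plateau `gain`, holds, and falls back (40 ms) within a 150-ms burst.  Because
the rectified mean of the carrier scales linearly with the envelope, iEMG
measurements are affine in `gain` and recoverable in closed form.  Gains are
expressed in multiples of background RMS and depend on muscle × perturbation
× predictability; direction-appropriate muscles (TA for anterior
translations, SOL/MG for the posterior one) get gain 8 at their primary
perturbation.  The Random condition multiplies the TA/Anterior-large gain
excess by 1.3, implementing the mismatch between a mid-level preset and a
large actual perturbation; this is the effect the two-way ANOVA stage is
meant to detect.

**M-max calibration.** Per muscle, a sweep of short stimulation trials whose
M-wave peak-to-peak follows a saturating recruitment sequence
(0.10 … 0.94, 1.0, 1.0, 1.0 × M-max), emulating a gradually increased
stimulus until the response stops growing.

**Platform trajectory.** Minimum-jerk displacement
`x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵)` with movement time `T = 1.875·A/v_peak`, so the
analytic peak velocity equals the profile's; posterior translations are
negative.  No biomechanics: the platform channel is descriptive only.

**Cohorts.** Amplitude-like parameters vary between subjects as mean-one
lognormal factors (a shared per-subject factor, CV 0.4, times a
condition-specific residual chosen so the total SD matches the calibrated
per-condition values); latencies vary as normals truncated symmetrically at
±2 SD (mean-preserving).  All draws descend from one integer seed through
`SeedSequence` spawning: identical configuration and seed reproduce a cohort
bit for bit.

**Deterministic carrier.** For closed-form round-trip tests the background
can be replaced by an alternating ±RMS square carrier whose rectified trace
is exactly RMS × envelope; several tests rely on this to check the pipelines
to float precision.

### Calibrated defaults and their provenance

| parameter | default | basis |
|---|---|---|
| TA MEP means (% M-max) | No-pert 6.5, Low 9.7, High 14.8, Posterior 7.3, Random 11.5 | Low/High/Posterior/Random are the reported group values; No-pert chosen below Posterior to reproduce the reported ordering |
| TA MEP between-subject SD | 3.7 / 5.5 / 8.0 / 4.2 / 6.6 | reported SEs × √12 |
| SOL / MG MEP means | 4.0 / 3.5 % M-max, flat across conditions | plantar-flexor MEPs are small and showed no clear condition modulation |
| burst onsets (ms) | TA·AntLarge 114.4, SOL·PostLarge 110.7, MG·PostLarge 109.5; other cells 115–122 | primary cells are the reported latencies; non-primary cells plausible values a few ms later |
| burst onset between-subject SD | 7.0 / 11.3 / 5.9 ms (primary cells) | the reported dispersion values used directly as SDs: scaling by √12 (as for amplitudes) would imply individual onsets spanning ~50–190 ms, outside the physiological range of long-latency responses |
| burst gains | 8 (primary), 4 (TA·AntSmall), 1.8–2.5 (non-primary); Random TA·AntLarge ×1.3 on the excess | chosen once so primary responses are unambiguous against background while non-primary muscles still respond weakly |
| M-max | TA 6 mV, SOL/MG 8 mV, between-subject CV 0.2 | typical maximal compound action potentials for these muscles |
| trial timing | 3.0-s trials, perturbation at 1.5 s, TMS at 1.45 s | leaves ≥50 ms of clean pre-TMS background and ≥350 ms of response window |

## Analysis pipelines

**Windows.** All event-anchored windows are half-open `[start, end)` after
rounding the event time to the nearest sample; abutting windows partition
samples exactly.  The MEP window is the 40 ms after the TMS sample, the MEP
background (BGA) window the 50 ms before it.

**MEP pipeline.** Per trial: peak-to-peak in the MEP window and BGA RMS.  Per
subject × condition × muscle cell, in this fixed order: (1) discard trials
with BGA above the cell mean + 2 sample SDs (threshold computed once, no
iteration); (2) discard survivors whose peak-to-peak lies beyond 1.5 × IQR
outside the quartiles; (3) normalize by the muscle's M-max (mean of the top-3
sweep peak-to-peaks); (4) average.  Running the artifact filter first keeps
high-BGA trials from distorting the quartiles; because normalization is a
positive scaling, applying the IQR rule on raw rather than normalized values
changes nothing (tested).  Quartiles default to Tukey hinges; a
linear-interpolation estimator is selectable (`quartile_method`).  With fewer
than four survivors quartiles are undefined and the IQR step is skipped.  An
empty cell yields an `n_used = 0` / NaN sentinel rather than an exception.

**Response pipeline.**  Catch-trial channels are rectified after DC
subtraction, aligned on perturbation onset and ensemble-averaged per
condition.  Amplitudes are normalized by the mean of the reference-condition
ensemble over the 250 ms post-onset — High for TA, Posterior for SOL/MG (the
condition in which each muscle is the prime mover).  Onset is detected on the
ensemble trace (not per trial): threshold = mean + 2 SD of the 100 ms
pre-onset ensemble, latency = first time the trace stays above threshold for
10 ms, searched over 0–300 ms post-onset; no crossing is a valid `None`
outcome.  iEMG is the trapezoidal integral of each trial's normalized
rectified trace over 100 ms starting at the *reference condition's* ensemble
onset for that muscle, applied to every trial of the muscle (including Random
trials); integrating each Random perturbation from its own ensemble onset is
the obvious alternative and can be composed from the public functions, but
the reference-onset convention is the default because the Random sub-ensembles
rest on only 1–2 trials.

**Statistics.** One-way repeated-measures ANOVAs (five conditions) on the
MEP means and BGA per muscle; a one-way across Low/High/Posterior on the
iEMG; a 2 × 3 (predictability × perturbation) two-way within-subject ANOVA on
the iEMG.  Every effect is tested against its own effect × subject
interaction mean square.  Mauchly's test (with the standard second-order
chi-square correction) at α = 0.05 gates the Greenhouse–Geisser correction;
when sphericity is rejected both degrees of freedom are scaled by the Box
epsilon ε = (Σλ)²/((k−1)Σλ²) over the eigenvalues of the double-centered
level covariance, clipped to [1/(k−1), 1].  The policy is configurable
(`mauchly` / `always` / `never`).  Zero error variance yields defined
sentinels (F = ∞, p = 0 with a real effect; F = 0, p = 1 without) so
simulation sweeps never crash.  Post hoc: all-pairs paired t-tests with
Bonferroni correction; with five conditions the per-test α is 0.05/10 =
0.005.  Zero-variance difference vectors give p = 1 (no evidence) when the
mean difference is zero.  Partial eta squared is SS_effect/(SS_effect +
SS_error) by construction.

## Recovery experiments and problem sizes

`posturemep.recovery` packages the headline experiments; the sizes below are
the package's standard desk-scale settings.

* **MEP condition means** — 100 cohort seeds × 12 subjects, full pipeline
  including M-max estimation from sweeps.  Residual bias sources: the noise
  floor adds ~0.1–0.2 %M-max to peak-to-peak extrema, the IQR rule clips the
  lognormal right tail slightly, and sweep-estimated M-max carries its own
  noise; net |bias| stays well under 0.5 %M-max.
* **Onset latencies** — 200 seeds × one subject's five catch trials per
  condition.  The detector is biased a few ms late by construction: the
  envelope needs ~1–2 ms to clear the 2 SD threshold and the 10-ms hold must
  fill with supra-threshold ensemble samples.  Measured mean error is ~+3–6 ms
  at the calibrated gains, within the 10-ms recovery tolerance.
* **Type-I calibration** — 2,000 null 12 × 5 matrices with the generator's
  variance structure.  With Gaussian components (the model under which the
  F-test's size is defined) the Mauchly-gated procedure rejects at ~4–6%.
  Drawing the generator's lognormal amplitude factors instead
  (`distribution="lognormal"`) gives ~3.5–4%: the F-test is mildly
  conservative under that skew.  This is a property of normal-theory F on
  skewed data, not of the implementation, and is why the Gaussian null is the
  calibration default.
* **Predictability power** — 100 cohorts of catch trials; the TA
  predictability main effect at the configured ×1.3 gain excess is detected
  in ~100% of cohorts, comfortably above the 90% design target, because
  reference normalization cancels the shared between-subject gain factor.

## What the generator does and does not emulate

Emulated: the condition/schedule structure with randomized orders, band-limited
stationary background with realistic per-muscle levels, time-locked biphasic
MEPs with lognormal amplitude variability at calibrated condition means,
direction-tuned long-latency bursts with a predictability effect, M-max
recruitment saturation, and between-subject heterogeneity.

Not emulated: non-stationary background (postural sway drifts), TMS and
stimulus artifacts, motion-platform mechanical artifacts in the EMG,
electrode noise and line interference, short/medium-latency response
components, any biomechanical coupling (no inverted pendulum, no COP), and
habituation or adaptation across trials.  Consequently, green recovery tests
demonstrate that the pipeline is an unbiased, correctly ordered implementation
of the stated rules — not that it is robust to every artifact class in real
recordings.  The one-way ANOVAs' normal-theory p-values are approximate under
the generator's lognormal amplitude distribution (see the calibration notes
above).

## Numerical choices

* Filtering: 4th-order Butterworth applied forward–backward (zero phase);
  the 15–1000 Hz digital reapplication is off by default (the acquisition
  chain is assumed to have band-passed in hardware) and available via
  `pipeline.refilter`.
* Event times are rounded to the nearest sample before window arithmetic.
* iEMG uses trapezoidal integration at native sample spacing (401 samples
  span 100 ms at 4 kHz).
* Peak-to-peak is max − min over the exact sample window; no interpolation.
* The M-max plateau is the mean of the top-3 sweep amplitudes (robust to a
  single weak final trial).
* Onset search is limited to 300 ms post-onset; long-latency responses occur
  at ~100–120 ms.
* All seeds are spawned from a single root via `numpy.random.SeedSequence`
  and kept below 2³¹.
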