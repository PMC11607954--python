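# Methods

This note documents the models, parameter choices and numerical decisions
behind `radarhr`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model

A continuous-wave radar at carrier wavelength λ (default 12.49 mm, the
24-GHz ISM band) observes a target at distance `r(t)` through the phase of
its complex baseband signal:

    z(t) = A·exp(i·4π·d(t)/λ) + c + n(t)

where `d(t)` is the chest-surface displacement, `c` a complex DC offset
(hardware leakage and static clutter) and `n(t)` circular Gaussian noise.
Displacement is recovered by estimating `c` with an algebraic least-squares
circle fit (Kåsa normal equations — closed-form and deterministic),
unwrapping the phase of the centred cloud, and scaling by λ/(4π).  The
estimate is offset- and global-phase-invariant and zero-meaned per
recording; a degenerate (zero-radius) cloud yields a flagged-invalid zero
signal rather than an exception.

Chest displacement is modelled as three additive components:

* **respiration** — a sinusoid at `resp_rate` (default 14/min) with mm
  amplitude (default 1 mm);
* **heart sounds** — per beat, S1 and S2 Gabor wavelets (40 Hz centre
  frequency, ~100 ms Gaussian envelope, i.e. σ = 16.7 ms) with µm
  amplitudes (defaults 30 and 15 µm) scaled by a per-channel geometric
  gain (1.0/0.85/0.7/0.55).  S2 is centred 0.33·IBI after S1, a
  physiological systolic fraction that also anchors the segmentation
  model;
* **motion artifacts** — Poisson-arriving (default 6/h) smooth mm-scale
  bumps, 0.2–0.8 s wide.  Artifacts are common-mode: the same patient
  movement hits every channel (gain-scaled).

Displacement is identically zero during configured absence intervals.

**Channel SNR** is carrier power over noise power *in a 1-kHz reference
bandwidth*, i.e. a noise density.  This makes the noise that lands in the
16–80 Hz heart-sound band — and hence task difficulty — independent of
the simulated sampling rate, so experiments can be run at 500 Hz with the
same statistical conditions as the 2000 Hz default.  At 30 dB the in-band
displacement noise is ≈5.6 µm RMS (comparable to S2), at 10 dB ≈56 µm
(beats are unrecoverable — which is what multi-channel selection is for).

## Beat model

Heart rate on a 1-s grid is `base_hr + drift(t) + trend(t)`, with `drift`
an AR(1) process (coefficient 0.99, innovation SD 0.05·hrv_sd) giving
smooth minute-scale wander, and `trend` optional piecewise-linear knots
for episodes such as a medication response.  Each IBI is `60/HR` with an
additional white Gaussian beat-to-beat term of SD `hrv_sd`, clipped to
[30, 200] bpm.  With `hrv_sd = 0` the generator is exactly metronomic.

Extrasystoles advance a beat by 40% (VES) or 20% (SVES) of the preceding
IBI while keeping the next beat fixed — a short interval followed by a
compensatory pause, so each event perturbs exactly two adjacent IBIs.
`ves_fraction` is the target fraction of *affected* beats; the number of
injected events is therefore `ves_fraction·n/2`.

All randomness flows from one seeded generator with labelled stream
splits; identical seeds give bit-identical recordings.

## Presence and signal quality

Presence uses windowed I/Q power variance (1-s windows, pooled over a
5-window context so the near-still breathing turning points stay flagged).
The empty-bed baseline is the smaller of the first decile of window powers
and a spectral noise-floor estimate (>100 Hz, rescaled); a window is
"present" when it exceeds the baseline by 10 dB.  The decile works when
the recording contains empty-bed stretches; the spectral floor covers
recordings where it does not.

The SQI compares 16–80 Hz band power against a 64-Hz-bandwidth noise
estimate taken as the *larger* of the >100 Hz density and the 8–12 Hz
density.  The mid-band reference sits above respiration and below the
heart sounds; it is essential because a failed phase unwrap at low SNR
produces random-walk (1/f²) noise that is strong in-band but invisible
above 100 Hz, and would otherwise score deceptively well.  White noise
scores ≈0 dB by construction.  Per window the module with the highest SQI
is selected (ties to the lowest index); window length follows the use
case: 60 s for overnight interval monitoring, 3 s for beat-synchronous
validation, 30 s for long-term trend monitoring.

## Segmentation (HSMM)

The heart-sound signal (zero-phase Butterworth band-pass, order 4 per
direction, 16–80 Hz — zero phase so S1/S2 timing is undistorted) is
reduced to two envelope features at 50 Hz: the analytic-signal envelope
and a homomorphic envelope (first-order 8-Hz low-pass of the log
envelope, re-exponentiated).  Features are normalised per decode window
by median/MAD with clipping to [−4, 10]; robust scaling matters because a
single motion artifact would otherwise compress the heart-sound peaks of
the whole window.

A coarse HR comes from the autocorrelation of the homomorphic envelope
(peak lag in 0.33–2.0 s, parabolic refinement), with a sub-harmonic
correction: when half the period is nearly as strong (≥0.7 of the peak)
the fundamental is preferred — without this, occasional octave errors
halve the decoded beat count for a whole window.  If no peak reaches 0.2
normalized autocorrelation, the estimate falls back to 75 bpm and is
flagged low-confidence.

The segmenter is a four-state hidden semi-Markov model on the fixed cycle
S1 → systole → S2 → diastole with Gaussian duration distributions:
S1 120 ± 25 ms, S2 90 ± 25 ms, systole 0.33·T − 120 ms, diastole
0.67·T − 90 ms (T = 60/coarse HR; SDs 0.05·T and 0.10·T; all durations
capped at mean + 3 SD).  Emissions are diagonal Gaussians with high means
for the sound states and low for the interval states, tempered by weight
0.3 so the duration model — the reliable rhythm prior — dominates when
the envelopes are noisy.  Decoding is exact duration-dependent Viterbi
(cost O(frames · states · max-duration), trivial at 50 Hz); S1/S2 times
are decoded-segment midpoints.  Nothing is trained: all parameters are
fixed configuration, which also means beats with altered morphology
(arrhythmias) are out of model — mirrored by the annotation-driven
exclusions downstream.

Recordings are decoded in 60-s chunks with 2-s overlap (beats straddling
chunk seams would otherwise be lost); duplicate events within 0.25 s are
collapsed at merge.

## HR series and exclusion rules

HR over any set of IBIs is `60/mean(IBI)` — the mean of the intervals,
not of the instantaneous rates.  Interval means require ≥10 IBIs and
subject presence to be valid (the 10-IBI floor guards against nearly
empty intervals).  Rolling means use k = 10 IBIs stamped at the window's
end beat; block means support both 30-beat and 30-s modes, since both
conventions are in use for trend monitoring.

Pairing: interval series join on identical interval starts; beat-wise
series match each reference beat to the nearest radar beat within half
the local reference IBI.  Reference values without a radar partner count
as `missing_radar`, and every excluded pair carries exactly one reason so
exclusion counts are additive.

The half/double rule targets the segmenter's characteristic failure
(missed or hallucinated alternate sounds): a pair is excluded when the
radar HR lies within 10% (relative) of half or double the reference HR.
The underlying description admits a second reading — the *difference*
lying within ±10% of half/double of the reference — which is available
behind `literal_difference=True`; the proximity form matches the failure
mode being targeted and is the default.  A label on beat b (extrasystole
or noisy reference) taints the IBI ending at b and hence the k rolling
windows containing it; patients whose affected-beat fraction reaches 20%
are excluded outright.

Long-term series pass a two-stage outlier filter: global thresholds
[25, 220] bpm (a generous physiological envelope), then per-60-value
segments an iterative median/MAD rule (k = 3, threshold floored at 5 bpm
so constant segments lose nothing) repeated to a fixpoint (≤10
iterations).  Segments are fixed position blocks, which makes the filter
deterministic and idempotent; genuine 10-bpm trends over tens of minutes
survive because they move the segment median rather than the residuals.

## Concordance statistics

All statistics use the sample SD (n−1).  The modified Bland–Altman plot
puts the *reference* HR on the x-axis and radar − reference on the y-axis;
limits of agreement are mean ± 1.96σ.  TOST: with bounds (−5, +5) bpm,
`t_lower = (m−lower)/se`, `t_upper = (m−upper)/se`, one-sided Student-t
p-values, equivalence iff both reject at α = 0.05 — equivalently iff the
90% CI lies strictly inside the bounds.  Zero-spread input is flagged
degenerate and decided on the mean alone, with limiting ±∞ t values.
Hedges g(z) = (m/s)·J with J = 1 − 3/(4·df − 1); standardized bounds
±5/s·J are reported alongside.  `tost_from_summary` accepts exactly one
of sd / se / a 90% CI (from which SE is recovered via the one-sided t
critical value), enabling published summary tables to be re-derived and
checked for self-consistency.  Rendered reports print p-values below
0.001 as "< 0.001"; machine output keeps full precision.

Sample-size planning: the LoA-precision criterion `z_{0.975}·σ·√(3/n) ≤ h`
gives `n = ⌈3(z·σ/h)²⌉` (= 30 at σ = 4, h = 2.5).  The TOST design is a
parallel-group additive-scale design with equal allocation: SE = σ·√(4/n),
df = n − 2, exact power from the noncentral t distribution, searched over
even totals from a normal-approximation start (= 28 at σ = 4, bounds ±5,
θ₀ = 1, power 0.8, α 0.05).  A crossover design with the same inputs
would give a different (smaller) n; the parallel additive design is the
one consistent with the planning numbers above.

Pairs are pooled across the whole recording set; no within-subject
clustering correction is applied, matching how such validation analyses
are typically reported.

## Problem sizes and runtime

Tests and the bundled experiments simulate at 500 Hz (exactly equivalent
to the 2000 Hz default under the reference-bandwidth SNR definition, and
well above the >160 Hz floor the 80-Hz band edge requires).  The largest
bundled experiment is an 8-hour, four-channel overnight run (SNRs
30/20/15/10 dB, 5-ms reference jitter, artifacts at 6/h), which runs in
~3 minutes on one CPU and yields ≥90% of 5-min intervals within ±5 bpm
with |mean difference| < 2 bpm.

## What the synthetic experiments do and do not show

The generator reproduces the *structure* the pipeline assumes —
µm heart-sound wavelets under mm respiration, graded channel quality,
presence gaps, motion artifacts, extrasystoles, a jittered beat reference
— with known ground truth, so correctness of every stage is testable.
It does not reproduce real heart-sound morphology variability (inotropy,
valve pathology), real artifact statistics (movements are smooth bumps,
not arbitrary limb motion), posture-dependent channel coupling, or
non-sinusoidal breathing.  Passing the synthetic acceptance experiments
therefore demonstrates algorithmic correctness under the stated model,
not clinical-grade accuracy on patients; the agreement percentages
printed for real cohorts can only be checked for internal statistical
consistency (which the summary-statistics round-trips do), not
regenerated.

## Known limitations

* The HSMM is untrained and its emission model is a two-Gaussian
  heuristic; arrhythmic or morphologically unusual beats are explicitly
  out of model.
* The SQI is a band-power ratio; it ranks channels by noise level, not by
  agreement with any reference, and a channel can win the SQI while
  losing on HR accuracy.
* Phase unwrapping assumes a single dominant target; multipath and
  multi-subject scenes are out of scope.
* Presence detection presumes the empty-bed noise floor is visible either
  in quiet windows or above 100 Hz; strong non-biological vibration would
  defeat it.
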