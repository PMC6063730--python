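# Methods

This note documents the models, conventions and parameter choices behind
`statephys`, in the order data flows through the pipeline.

## Session model and containers

A *session* is a bundle of uniformly sampled channels on one timeline:
membrane potential (V_m, mV, 20 kHz), local field potential (LFP, mV,
20 kHz), whisker angle (degrees, 200 Hz) and a juxtacellular channel for
the presynaptic cell (mV, 20 kHz), plus optogenetic stimulus onset times
and labeled state epochs.  All timing is in seconds from session start;
epochs are half-open intervals `[start, end)`; alignment across sampling
rates is always done in seconds, never in sample indices.  On disk a
session is a directory of raw little-endian float64 channel files with
JSON metadata (rates and units are read from metadata, never guessed);
an HDF5 mirror with the same logical layout is provided.  Round trips are
bit-exact, which the suite property-tests with generated sessions.

## Synthetic sessions (what the generator emulates)

The generator produces sessions with the statistical structure the
analysis assumes, plus the planted truth needed to test the analysis as
parameter recovery.

* **State process.** Quiet/active epochs alternate with exponential dwell
  times (mean `epoch_dwell_s` = 8 s) truncated below at `min_dwell_s` =
  2 s so that 2 s FFT windows fit inside epochs.
* **LFP.** A "delta" component — unit-variance Gaussian noise band-passed
  to 1–5 Hz — is amplitude-modulated per epoch: 0.4 mV during quiet,
  0.1 mV during active (a 4× amplitude, 16× power contrast), with 0.2 s
  raised-cosine ramps at epoch edges, plus 0.02 mV broadband noise.  A
  pure-tone mode replaces the narrowband noise for analytic tests.
* **Whisker.** The angle is exactly zero outside whisking bouts (so
  angular speed is exactly zero there — a tested contract) and a 15°,
  8 Hz sinusoid with 0.1 s on/off ramps inside bouts.  By default bouts
  coincide with active epochs; `state_agreement_fraction` < 1 plants
  disagreeing epochs to exercise the unassigned W∩H / NW∩L categories.
* **Membrane potential.**
  `V_m = rest + shift·1[active] + coupling·delta + noise + uEPSPs + spikes`.
  The PV-like default depolarizes (+3 mV) with strong delta coupling
  (gain 6), so quiet states carry large slow fluctuations; the Sst-like
  preset hyperpolarizes (−3 mV) with weak coupling (0.5) — the directions
  of the recorded cell-class effects.  Noise is Gaussian, low-passed at
  100 Hz, scaled to `vm_noise_sd_mV` (default 1.0 mV; V_m noise in vivo
  is dominated by synaptic frequencies well below 1 kHz).
* **Spikes.** A stylized template (2 ms Hann bump, +60 mV from threshold)
  is injected at upward threshold crossings of the subthreshold V_m with
  a 5 ms absolute refractory period.  Thresholds sit ~7 mV above rest so
  quiet-state rates land at a few Hz; because active-state variance drops
  faster than the mean rises (PV) or the cell hyperpolarizes (Sst), both
  presets fire less in the active state — an emergent, not hard-coded,
  property.  In cohorts the threshold tracks the jittered resting
  potential so per-cell excitability stays comparable.
* **Stimulation and uEPSPs.** 1 ms light pulses at 1 Hz, delivered in
  alternating 30 s stimulation / 30 s stimulus-free blocks (emulating
  interleaved evoked and spontaneous trials; without the gaps no clean
  1 s spontaneous segment would exist).  Each pulse triggers a
  presynaptic juxtacellular spike at 2.5 ms latency with 0.3 ms Gaussian
  jitter, followed after a 1.5 ms synaptic delay by a difference-of-
  exponentials uEPSP (rise 0.7 ms, decay 15 ms for the PV-like preset)
  normalized to unit peak and scaled to the planted per-state amplitude
  (quiet 1.0 mV, active 1.5 mV by default; the Sst preset plants equal
  amplitudes, matching the absence of a consistent state effect in that
  class).  With noise off, the planted peak is recovered to <1%
  (discretization only) — a tested contract.

What the generator does **not** emulate: conductance-based spike
initiation, spike-frequency adaptation, up/down-state bimodality,
whisker-contact events, electrode drift, or the real data's amplitude
distributions.  Passing recovery tests therefore demonstrates the
*analysis* is correct under the stated statistical structure, not that it
is robust to every pathology of real recordings.

## State segmentation

* **Whisking.** Speed = |d(angle)/dt| smoothed with a 25 ms boxcar;
  W requires speed strictly above 50 °/s (ties break to not-whisking).
  The threshold is a design choice — no published value exists — and the
  tests keep planted bout speeds far from it.  A ±0.1 s buffer around
  every threshold crossing stays unassigned, so W ∪ NW undercovers the
  session; epochs shorter than 0.2 s are dropped and gaps under 0.1 s
  merged (cleanup values are configurable; whether the original analysis
  applied any is unstated).
* **Band power.** The LFP is down-sampled to 2000 Hz, low-pass filtered
  at 200 Hz with a 4th-order zero-phase Butterworth (stated order of
  operations preserved), then a rectangular-window FFT of each 2 s window
  stepped by 10 ms gives band power = Σ|X(f)|² over bins with
  1 ≤ f ≤ 5 Hz (both edges inclusive).  "Overlap: 10 ms" is read as a
  10 ms step — near-total overlap — since stepping 2 s windows by
  1.99 s could not produce the smooth state traces the method yields.
  Power maps to the window's *center* time, so the first and last second
  are uncovered.  Only the nine in-band bins are needed, so the
  implementation projects windows onto those bins directly (chunked
  matmul); a unit test pins it to a per-window rFFT oracle at 1e-9.
* **Percentile rule.** L/H thresholds are the 40th/60th percentiles
  (linear interpolation) of the full per-recording window-power
  distribution, with strict inequalities: the middle quintile, and a
  degenerate all-equal distribution, stay unassigned.  By construction at
  most ~40% of windows can carry each label.
* **Joint states.** Active = W ∩ L, Quiet = NW ∩ H on half-open
  intervals; W∩H and NW∩L remain unassigned.  A stimulus belongs to a
  state only if `[t−20 ms, t+30 ms)` lies inside a single interval of
  that state; a window exactly coinciding with an interval's span is
  assigned (half-open containment).
* **Recovery metric.** Because the percentile rule caps each label near
  40% of the session, recall against planted epochs is bounded a priori;
  the meaningful recovery quantity is the fraction of *assigned*
  (Active ∪ Quiet) time carrying the correct planted label, which the
  acceptance suite requires to exceed 90% on every one of twenty
  20-minute sessions.

## V_m statistics

Spike peaks come from a dV/dt threshold detector (20 V/s, 2 ms
refractory, peak search 2 ms) — the original spike detector is not
described, and the planted-template recovery test pins recall and
precision at 1.0.  Mean and population SD pool state samples after
excising −1/+4 ms around each spike peak and 0–50 ms after each stimulus
(the excision window and the stimulus-response exclusion are choices; the
source states only "excluding APs" and "spontaneous").  Zero retained
samples yield NaN with a warning, never a silent 0.

Spectra use V_m decimated to 2000 Hz (its content of interest is far
below the decimated Nyquist) and median-filtered over 8 ms (window length
unstated in the source; 0 disables).  Non-overlapping 1 s segments are
taken greedily from each interval's start, skipping segments that touch a
stimulus-response window; per segment the single-sided amplitude is
2|X(f)|/N with DC excluded, averaged across segments; the 1–5 Hz band
amplitude is the mean over the bins at 1…5 Hz (1 Hz resolution).

The V_m–LFP cross-correlation z-scores *both* series per 1 s segment.
The source normalizes V_m only, but an asymmetric normalization leaves
the coefficient in LFP-dependent units that are not comparable across
cells; the symmetric (Pearson-style) version is bounded by 1 and matches
the dimensionless peak values reported.  Positive lag means the LFP lags
the V_m; the peak is the extremum of largest absolute value, returned
signed.  Zero-variance segments are skipped with a log entry.

## uEPSP quantification

Stimuli enter the per-state triggered average only if state-attributed
(20/30 ms continuity) and free of postsynaptic spike peaks in
`[t−20 ms, t+30 ms)`; eligible −20…+50 ms segments are averaged and
smoothed with a 0.5 ms boxcar (edge-replicated), and the derivative with
a centered 0.5 ms boxcar (the smoothing kernels are unstated in the
source; all choices are configurable arguments).  A centered, short
derivative window matters: a trailing window fires only after the
jitter-smeared rise has accumulated a visible foot, which leaks into the
baseline window and biases amplitudes low by several percent.
Onset = first time in (0, 30 ms] the smoothed derivative exceeds
100 mV/s (PV) or 60 mV/s (Sst); the first subsequent negative-derivative
sample brackets the peak and the waveform maximum inside the bracket is
taken as the peak sample, so smoothing delay does not bias it.
Amplitude = mean over a 0.25 ms window centered at the peak minus the
mean over the 0.25 ms window ending at onset ("immediately prior"); the
20–80% rise time is linearly interpolated on the rising phase.  If the
threshold is never crossed the result is "no uEPSP detected" (amplitude
NaN).  With averages built from few noisy trials the derivative threshold
can trigger on noise before the true rise — the bounded search window
limits but does not eliminate this; amplitude-recovery accuracy is
therefore specified at ≥40 usable stimuli per state, where the acceptance
suite shows <10% error at 0.3 mV noise.

## Exact tests

At five paired cells, asymptotic rank tests are meaningless, so both
Wilcoxon tests enumerate their exact null: the signed-rank over all 2^n
sign assignments (via subset-sum convolution, identical to enumeration —
a brute-force oracle asserts exact equality), the rank-sum over all
C(n1+n2, n1) group assignments, with mid-ranks for ties.  Conventions:
zero differences are dropped before ranking; one-tailed p for "greater"
is P(W⁺ ≥ w_obs); two-tailed p is twice the smaller one-tailed p capped
at 1.  Beyond n = 25 a continuity-corrected normal approximation is used
and flagged `exact=False`.  Five concordant differences give the exact
one-tailed p = 1/32 ≈ 0.031 — the smallest attainable value at n = 5 and
the pipeline's headline statistic.  Box summaries use linear-interpolated
quartiles and Tukey whiskers at the most extreme data points within
1.5×IQR of the quartiles.

## Problem sizes and determinism

Everything is a deterministic function of the master seed (cohort seeds
derive from it via the NumPy seed sequence).  The suite's problem sizes
are chosen to estimate each quantity at useful precision while keeping a
full run in minutes: classifier recovery uses twenty 20-minute sessions;
uEPSP recovery ten 400 s sessions (~150 usable stimuli per state);
cohort direction-of-effect twenty seeds of five cells per class at 120 s;
the analysis drivers use 360 s sessions, which yield roughly fifty usable
stimuli per state — the scale of the recorded data sets.

## Known limitations

* The whisker-speed threshold, epoch-cleanup rules, AP-excision and
  median-filter windows, smoothing kernels and segment taper are not
  specified by the source analysis; all are explicit parameters with the
  defaults above.
* The onset detector can fire on pre-onset noise in low-n averages (see
  above).
* The normal-approximation branch of the tests (n > 25) is not exercised
  by the study-scale analyses.
* Exactly periodic 1 Hz stimulation comb-samples the 1–5 Hz background:
  the harmonics of the stimulus clock lie inside the delta band, so the
  LFP-coupled component does not fully average out of the triggered
  average.  At ~50–80 usable stimuli this leaves a few-percent,
  seed-dependent wobble on recovered uEPSP amplitudes; it is a property
  of the stimulation protocol itself, not of the estimator.
* The generator's dwell process makes quiet/active roughly equal in
  duration; strongly asymmetric state occupancy would interact with the
  fixed 40th/60th percentile rule and is not explored.
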