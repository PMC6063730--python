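# statephys

Analysis pipeline for **state-dependent membrane-potential dynamics and
unitary synaptic inputs** in awake cortical recordings, with a synthetic
session generator that plants ground truth for end-to-end validation.

## The scientific problem

In awake head-restrained mice, the cortex alternates between a *quiet*
state — no whisker movement, large 1–5 Hz local-field-potential (LFP)
fluctuations — and an *active* state — whisking, suppressed low-frequency
LFP power.  Whole-cell recordings show that two classes of inhibitory
interneuron in layer 2/3 of barrel cortex behave oppositely across this
transition: parvalbumin-expressing (PV) cells depolarize while
somatostatin-expressing (Sst) cells hyperpolarize, and both fire less
during active states.  Optogenetic stimulation of a single presynaptic
excitatory neuron (1 ms light pulses at 1 Hz) evokes unitary excitatory
postsynaptic potentials (uEPSPs) whose amplitude can be compared across
states in the same cell.

This package implements every quantitative step of that analysis as a
tested library:

* **`statephys.states`** — behavioral/cortical state segmentation:
  whisking (W/NW) from thresholded smoothed whisker angular speed;
  high/low 1–5 Hz LFP power (H/L) from a sliding FFT (2 s window, 10 ms
  step) thresholded at the per-recording 40th/60th power percentiles;
  joint states Active = W ∩ L and Quiet = NW ∩ H; and the stimulus
  attribution rule (20 ms pre / 30 ms post continuity).
* **`statephys.vm`** — state-resolved spontaneous V_m statistics: mean and
  SD excluding action potentials, AP rate, the single-sided FFT amplitude
  spectrum of the median-filtered V_m on 1 s segments with its 1–5 Hz band
  mean, and the peak normalized V_m–LFP cross-correlation.
* **`statephys.uepsp`** — evoked-AP statistics (10 ms window, latency,
  jitter) and uEPSP quantification on the stimulus-triggered smoothed
  average: onset where the smoothed dV/dt exceeds 100 mV/s (PV) or
  60 mV/s (Sst), peak at the first subsequent negative derivative,
  amplitude from 0.25 ms windows at peak and baseline, 20–80% rise time.
* **`statephys.stats`** — exact Wilcoxon signed-rank and rank-sum tests by
  full enumeration of the null distribution (n ≤ 25), one- and two-tailed,
  plus Tukey box-plot descriptors.  At n = 5 paired cells, five concordant
  differences give the exact one-tailed p = 1/32 ≈ 0.031.
* **`statephys.synth`** — the synthetic session generator: a two-state
  semi-Markov epoch process, amplitude-modulated narrowband 1–5 Hz LFP,
  whisking bouts, V_m = rest + state shift + delta coupling + noise with
  stylized spikes, and planted double-exponential uEPSPs following
  jittered presynaptic APs — all deterministic in the seed and returned
  with a `GroundTruth` for parameter-recovery tests.
* **`statephys.io` / `statephys.pipeline` / `statephys.cli`** — a
  human-inspectable session container (JSON + raw float64 channels, with
  an HDF5 mirror), the end-to-end cohort orchestration, and the
  `statephys` command-line tool.

## Worked example

```python
import statephys as sp

# one PV-like synthetic cell: 360 s, planted quiet/active epochs,
# planted uEPSP amplitudes 1.0 mV (quiet) / 1.5 mV (active)
session, truth = sp.generate_session(sp.GeneratorConfig(duration_s=360, seed=3))

states = sp.classify_session(session)          # W/NW, L/H, Active/Quiet
spikes = sp.detect_aps(session.traces["vm"])

for name in ("Quiet", "Active"):
    mean, sd = sp.vm_mean_sd(session.traces["vm"], states[name], spikes,
                             session.stim_times_s)
    wf, n = sp.triggered_average(session.traces["vm"], session.stim_times_s,
                                 states[name], spikes)
    m = sp.quantify_uepsp(wf, "PV", n, name)
    print(f"{name}: Vm {mean:.2f} mV, uEPSP {m.amplitude_mV:.2f} mV ({n} stimuli)")
```

prints

```
Quiet: Vm -62.04 mV, uEPSP 0.88 mV (47 stimuli)
Active: Vm -59.01 mV, uEPSP 1.38 mV (84 stimuli)
```

— the planted +3 mV active-state depolarization and the planted positive
uEPSP contrast recovered from the raw traces (amplitudes carry a few
tenths of a millivolt of trial-sampling error at ~50–80 stimuli, as in
the recorded data sets).  The numbered scripts under
`analysis/` run the same chain over five-cell PV and Sst cohorts
(`01_simulate_cohorts.py` … `05_cohort_statistics.py`), writing per-cell
tables and the exact cohort tests under `results/`.

A command-line interface wraps the same functions:

```bash
statephys simulate --seed 3 --out session/
statephys classify session/
statephys analyze-uepsp session/ --out uepsp.json
statephys run --config cohort.yaml --out report.json
```

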