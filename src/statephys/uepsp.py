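"""Evoked-AP and unitary-EPSP quantification.

Presynaptic side: an AP counts as optogenetically evoked if its peak falls
within 10 ms of stimulus onset; latency is stimulus-to-peak time and jitter
its standard deviation.

Postsynaptic side: a stimulus-triggered smoothed Vm average is built from
stimuli free of postsynaptic APs in a 50 ms window starting 20 ms before
onset, separately per state.  On the averaged waveform, uEPSP onset is the
first post-stimulus time the smoothed dV/dt exceeds a cell-class threshold
(100 mV/s for PV, 60 mV/s for Sst), the peak is the first subsequent
negative-derivative time, amplitude is the difference between 0.25 ms mean
windows at the peak and immediately before onset, and the 20–80% rise time
is interpolated on the rising phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .session import IntervalSet, Trace
from .states import StateParams
from .vm import detect_aps
from .stats import signed_rank_exact

__all__ = [
    "EvokedAPStats",
    "UEPSPMeasurement",
    "evoked_ap_stats",
    "triggered_average",
    "quantify_uepsp",
    "state_contrast",
    "ONSET_THRESHOLD_MV_PER_S",
]

#: dV/dt onset-detection thresholds per postsynaptic cell class, mV/s.
ONSET_THRESHOLD_MV_PER_S = {"PV": 100.0, "Sst": 60.0, "NC": 100.0}

#: evoked-AP acceptance window after stimulus onset, s.
EVOKED_WINDOW_S = 0.010
#: postsynaptic-AP exclusion window around a stimulus, s (50 ms starting
#: 20 ms before onset).
EXCLUSION_WINDOW_S = (-0.020, 0.030)
#: stimulus-locked segment extracted for the triggered average, s.
SEGMENT_WINDOW_S = (-0.020, 0.050)


@dataclass
class EvokedAPStats:
    """Reliability and timing of optogenetically evoked presynaptic APs."""

    n_stimuli: int
    n_evoked: int
    latency_ms: float
    jitter_ms: float

    @property
    def reliability(self) -> float:
        return self.n_evoked / self.n_stimuli if self.n_stimuli else float("nan")


@dataclass
class UEPSPMeasurement:
    """Triggered-average uEPSP quantification for one state."""

    state: str
    n_stimuli_used: int
    average_waveform: Trace | None
    detected: bool = False
    amplitude_mV: float = float("nan")
    onset_latency_ms: float = float("nan")
    peak_time_ms: float = float("nan")
    rise_time_20_80_ms: float = float("nan")
    baseline_vm_mV: float = float("nan")


def evoked_ap_stats(juxta: Trace, stim_times_s: np.ndarray,
                    state: IntervalSet | None = None,
                    params: StateParams | None = None,
                    dvdt_threshold_V_per_s: float = 3.0,
                    peak_min_mV: float = 2.0) -> EvokedAPStats:
    """Latency/jitter/reliability of evoked presynaptic APs.

    If ``state`` is given, only stimuli whose 20 ms-pre / 30 ms-post window
    lies continuously inside it are pooled.  An AP is evoked iff its peak
    lies in ``(t_stim, t_stim + 10 ms]``; the first such AP defines latency.
    """
    params = params or StateParams()
    spikes = detect_aps(juxta, dvdt_threshold_V_per_s, peak_min_mV)
    stims = np.asarray(stim_times_s, dtype=np.float64)
    if state is not None:
        stims = np.array(
            [t for t in stims
             if state.covers_span(t - params.stim_pre_s, t + params.stim_post_s)]
        )
    if stims.size == 0:
        warnings.warn("no stimuli in the requested state; evoked-AP stats undefined")
        return EvokedAPStats(0, 0, float("nan"), float("nan"))
    latencies = []
    for t in stims:
        after = spikes[(spikes > t) & (spikes <= t + EVOKED_WINDOW_S)]
        if after.size:
            latencies.append((after[0] - t) * 1e3)
    if not latencies:
        return EvokedAPStats(int(stims.size), 0, float("nan"), float("nan"))
    lat = np.asarray(latencies)
    return EvokedAPStats(int(stims.size), lat.size, float(lat.mean()), float(lat.std()))


def _boxcar(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centered moving average with edge replication (no zero-pad droop)."""
    k = width_samples
    if k <= 1:
        return x
    pad = np.pad(x, (k // 2, k - 1 - k // 2), mode="edge")
    return np.convolve(pad, np.ones(k) / k, mode="valid")




def triggered_average(vm: Trace, stim_times_s: np.ndarray, state: IntervalSet,
                      spikes: np.ndarray, params: StateParams | None = None,
                      smooth_ms: float = 0.5) -> tuple[Trace | None, int]:
    """Stimulus-triggered smoothed Vm average for one state.

    A stimulus is used iff its 20 ms-pre / 30 ms-post window lies inside a
    single interval of ``state`` and no postsynaptic spike peak falls in
    ``[t - 20 ms, t + 30 ms)``.  Segments spanning −20 to +50 ms around onset
    are averaged and boxcar-smoothed over ``smooth_ms``.

    Returns ``(waveform, n_used)``; with no eligible stimulus the waveform
    is None (flagged undefined).
    """
    params = params or StateParams()
    spikes = np.asarray(spikes, dtype=np.float64)
    used = []
    n0 = int(round(SEGMENT_WINDOW_S[0] * vm.rate_hz))
    n1 = int(round(SEGMENT_WINDOW_S[1] * vm.rate_hz))
    for t in np.asarray(stim_times_s, dtype=np.float64):
        if not state.covers_span(t - params.stim_pre_s, t + params.stim_post_s):
            continue
        lo, hi = t + EXCLUSION_WINDOW_S[0], t + EXCLUSION_WINDOW_S[1]
        if np.any((spikes >= lo) & (spikes < hi)):
            continue
        i = int(round((t - vm.t0_s) * vm.rate_hz))
        if i + n0 < 0 or i + n1 > vm.n:
            continue
        used.append(vm.values[i + n0 : i + n1])
    if not used:
        warnings.warn(f"no eligible stimuli in state {state.label!r}")
        return None, 0
    avg = np.mean(used, axis=0)
    avg = _boxcar(avg, int(round(smooth_ms * 1e-3 * vm.rate_hz)))
    return Trace(avg, vm.rate_hz, t0_s=SEGMENT_WINDOW_S[0], units=vm.units), len(used)


def quantify_uepsp(average_waveform: Trace, cell_class: str = "PV",
                   n_stimuli_used: int = 0, state: str = "",
                   deriv_smooth_ms: float = 0.5, search_end_s: float = 0.030,
                   onset_threshold_mV_per_s: float | None = None,
                   ) -> UEPSPMeasurement:
    """Quantify a stimulus-locked average waveform.

    Onset is the first post-stimulus time the smoothed derivative exceeds
    the class threshold (search bounded to ``(0, search_end_s]``); the peak
    is the first later time the smoothed derivative turns negative.
    Amplitude = mean over a 0.25 ms window centered at the peak minus the
    mean over the 0.25 ms baseline window ending at onset; the 20–80% rise
    time is linearly interpolated on the rising phase.  If the derivative
    never crosses the threshold the result is flagged "no uEPSP detected"
    (amplitude NaN, not zero).
    """
    wf = average_waveform
    if wf.t0_s > 0 or wf.end_s < search_end_s:
        raise ValueError("waveform must cover the post-stimulus search window")
    thr = (onset_threshold_mV_per_s if onset_threshold_mV_per_s is not None
           else ONSET_THRESHOLD_MV_PER_S[cell_class])
    fs = wf.rate_hz
    v = wf.values
    t = wf.times()
    dvdt = np.gradient(v) * fs  # mV/s
    dvdt = _boxcar(dvdt, int(round(deriv_smooth_ms * 1e-3 * fs)))
    searchable = (t > 0) & (t <= search_end_s)
    idx = np.flatnonzero(searchable & (dvdt > thr))
    out = UEPSPMeasurement(state=state, n_stimuli_used=n_stimuli_used,
                           average_waveform=wf)
    if idx.size == 0:
        return out
    i_on = int(idx[0])
    after = np.flatnonzero((np.arange(v.size) > i_on) & (dvdt < 0))
    i_neg = int(after[0]) if after.size else v.size - 1
    # the derivative sign change brackets the peak; take the waveform maximum
    # inside the bracket so smoothing delay does not bias the peak sample
    i_pk = i_on + int(np.argmax(v[i_on : i_neg + 1]))
    half = max(1, int(round(0.000125 * fs)))  # half of the 0.25 ms window
    baseline = float(v[max(0, i_on - 2 * half) : i_on].mean())
    peak_v = float(v[max(0, i_pk - half) : i_pk + half + 1].mean())
    amp = peak_v - baseline
    # 20–80% crossing times on the rising phase, linear interpolation
    rise = float("nan")
    if amp > 0:
        lo, hi = baseline + 0.2 * amp, baseline + 0.8 * amp
        t20 = _first_crossing(t, v, i_on - 2 * half, i_pk, lo)
        t80 = _first_crossing(t, v, i_on - 2 * half, i_pk, hi)
        if t20 is not None and t80 is not None:
            rise = (t80 - t20) * 1e3
    out.detected = True
    out.amplitude_mV = amp
    out.onset_latency_ms = t[i_on] * 1e3
    out.peak_time_ms = t[i_pk] * 1e3
    out.rise_time_20_80_ms = rise
    out.baseline_vm_mV = baseline
    return out


def _first_crossing(t: np.ndarray, v: np.ndarray, i0: int, i1: int,
                    level: float) -> float | None:
    i0 = max(0, i0)
    for i in range(i0, min(i1 + 1, v.size - 1)):
        if v[i] < level <= v[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + f * (t[i + 1] - t[i]))
        if v[i] >= level:
            return float(t[i])
    return None


def state_contrast(per_cell: list[dict[str, UEPSPMeasurement]],
                   direction: str = "greater") -> dict:
    """Per-cell Active − Quiet contrasts and their one-tailed signed-rank tests.

    ``per_cell`` maps state name ('Active'/'Quiet') to a measurement for each
    cell; cells missing either state or without a detected uEPSP are dropped
    with a log entry.  ``direction`` is the hypothesized direction of the
    Active − Quiet amplitude difference ('greater' for PV-like amplitude
    increase and baseline depolarization, 'less' for Sst-like).
    """
    amp_diffs, base_diffs = [], []
    for i, cell in enumerate(per_cell):
        a, q = cell.get("Active"), cell.get("Quiet")
        if a is None or q is None or not (a.detected and q.detected):
            warnings.warn(f"cell {i}: missing state measurement; dropped from contrast")
            continue
        amp_diffs.append(a.amplitude_mV - q.amplitude_mV)
        base_diffs.append(a.baseline_vm_mV - q.baseline_vm_mV)
    result: dict[str, object] = {
        "amplitude_diffs_mV": amp_diffs,
        "baseline_diffs_mV": base_diffs,
        "n_cells": len(amp_diffs),
    }
    if amp_diffs:
        result["amplitude_test"] = signed_rank_exact(amp_diffs, sided="one", direction=direction)
        result["baseline_test"] = signed_rank_exact(base_diffs, sided="one", direction=direction)
    return result
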