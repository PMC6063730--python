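"""State-resolved spontaneous membrane-potential statistics.

Per state: mean and SD of Vm excluding action potentials, spontaneous AP
rate, the FFT amplitude spectrum of the median-filtered Vm on 1 s segments
with its 1–5 Hz band mean, and the peak Vm–LFP cross-correlation on
mean-subtracted, SD-normalized 1 s segments.  "Spontaneous" excludes a
response window after every optogenetic stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .session import IntervalSet, Trace, ValidationError
from .states import StateParams, preprocess_lfp

__all__ = [
    "VmStateStats",
    "detect_aps",
    "vm_mean_sd",
    "ap_rate",
    "vm_fft_amplitude",
    "vm_lfp_xcorr",
    "stim_exclusion_intervals",
    "analyze_vm_state",
]

#: Vm samples excised around each spike peak for mean/SD, seconds.
AP_EXCISION_S = (-0.001, 0.004)
#: post-stimulus response window excluded from spontaneous statistics, s.
STIM_EXCLUSION_S = (0.0, 0.050)


@dataclass
class VmStateStats:
    """Spontaneous Vm statistics for one state."""

    state: str
    mean_vm_mV: float
    sd_vm_mV: float
    ap_rate_hz: float
    fft_freq_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    fft_amplitude_mV: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_amp_1_5_mV: float = float("nan")
    peak_xcorr: float = float("nan")
    peak_xcorr_lag_s: float = float("nan")
    n_segments: int = 0


def detect_aps(vm: Trace, dvdt_threshold_V_per_s: float = 20.0,
               peak_min_mV: float = -20.0, refractory_s: float = 0.002,
               search_s: float = 0.002) -> np.ndarray:
    """Spike peak times from a rate-of-rise threshold.

    An event starts where dV/dt first exceeds the threshold; the peak is the
    maximum within ``search_s``.  Events whose peak stays below
    ``peak_min_mV`` are discarded and a refractory period of ``refractory_s``
    between peaks yields one event per suprathreshold excursion.
    """
    v = vm.values
    dvdt = np.diff(v) * vm.rate_hz * 1e-3  # mV/ms == V/s
    above = dvdt > dvdt_threshold_V_per_s
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above.size and above[0]:
        onsets = np.concatenate([[0], onsets])
    win = max(1, int(round(search_s * vm.rate_hz)))
    refr = refractory_s * vm.rate_hz
    peaks = []
    last = -np.inf
    for i in onsets:
        j = i + int(np.argmax(v[i : i + win + 1]))
        if v[j] < peak_min_mV or j - last < refr:
            continue
        peaks.append(j)
        last = j
    return vm.t0_s + np.asarray(peaks, dtype=np.float64) / vm.rate_hz


def stim_exclusion_intervals(stim_times_s: np.ndarray,
                             window_s: tuple[float, float] = STIM_EXCLUSION_S) -> IntervalSet:
    """Response windows around stimuli, merged into an IntervalSet."""
    iv = [(t + window_s[0], t + window_s[1]) for t in np.asarray(stim_times_s, float)]
    return IntervalSet("stim_exclusion", iv).merge_gaps(0.0) if iv else IntervalSet("stim_exclusion")


def _spontaneous_mask(vm: Trace, state: IntervalSet, spikes: np.ndarray,
                      stim_times_s: np.ndarray | None) -> np.ndarray:
    mask = state.sample_mask(vm)
    for t in np.asarray(spikes, float):
        i0 = max(0, vm.index_of(t + AP_EXCISION_S[0]))
        i1 = min(vm.n, vm.index_of(t + AP_EXCISION_S[1]))
        mask[i0:i1] = False
    if stim_times_s is not None and len(stim_times_s):
        mask &= ~stim_exclusion_intervals(stim_times_s).sample_mask(vm)
    return mask


def vm_mean_sd(vm: Trace, state: IntervalSet, spikes: np.ndarray,
               stim_times_s: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and population SD of Vm over a state, APs and stimuli excised.

    Samples within ``AP_EXCISION_S`` of a spike peak and within
    ``STIM_EXCLUSION_S`` of a stimulus are removed before pooling.  With no
    retained samples the result is flagged as NaN (never silently zero).
    """
    mask = _spontaneous_mask(vm, state, spikes, stim_times_s)
    if not mask.any():
        warnings.warn(f"no spontaneous samples in state {state.label!r}")
        return float("nan"), float("nan")
    x = vm.values[mask]
    return float(x.mean()), float(x.std())


def ap_rate(spikes: np.ndarray, state: IntervalSet) -> float:
    """Spike peaks inside the state divided by total state duration (Hz)."""
    dur = state.total_duration_s
    if dur == 0:
        warnings.warn(f"state {state.label!r} has zero duration; rate undefined")
        return float("nan")
    n = int(np.count_nonzero(state.contains_times(np.asarray(spikes, float))))
    return n / dur


def _segments(state: IntervalSet, seg_s: float, exclude: IntervalSet | None) -> list[float]:
    """Greedy non-overlapping segment start times fully inside the state."""
    starts = []
    for s, e in state:
        t = s
        while t + seg_s <= e + 1e-12:
            if exclude is None or exclude.intersect(
                IntervalSet("seg", [(t, t + seg_s)])
            ).total_duration_s == 0:
                starts.append(t)
                t += seg_s
            else:
                t += seg_s  # skip contaminated slot, stay on the greedy grid
    return starts


def vm_fft_amplitude(vm: Trace, state: IntervalSet, median_filter_ms: float = 8.0,
                     stim_times_s: np.ndarray | None = None,
                     analysis_rate_hz: float = 2000.0, segment_s: float = 1.0,
                     ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Single-sided FFT amplitude spectrum of the median-filtered Vm.

    The Vm is decimated to ``analysis_rate_hz`` (integer stride; its content
    of interest is far below the decimated Nyquist) and median-filtered over
    ``median_filter_ms`` to remove APs (0 disables the filter).  Spectra of
    non-overlapping ``segment_s`` segments fully inside the state — and clear
    of stimulus-response windows — are averaged; amplitude is ``2|X(f)|/N``
    with DC excluded.  The band amplitude is the mean over the bins in
    [1, 5] Hz (1 Hz resolution: bins at 1..5 Hz).

    Returns ``(freq_hz, amplitude_mV, band_amp_mV, n_segments)``; with no
    full segment the band amplitude is flagged NaN.
    """
    stride = int(round(vm.rate_hz / analysis_rate_hz))
    if stride < 1 or abs(vm.rate_hz - stride * analysis_rate_hz) > 1e-6:
        raise ValidationError("vm rate must be an integer multiple of the analysis rate")
    x = vm.values[::stride]
    fs = analysis_rate_hz
    if median_filter_ms > 0:
        k = int(round(median_filter_ms * 1e-3 * fs)) | 1
        x = ndimage.median_filter(x, size=k, mode="nearest")
    exclude = stim_exclusion_intervals(stim_times_s) if stim_times_s is not None else None
    starts = _segments(state, segment_s, exclude)
    nseg = int(round(segment_s * fs))
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)[1:]
    if not starts:
        warnings.warn(f"no full {segment_s} s segment in state {state.label!r}")
        return freqs, np.full(freqs.size, np.nan), float("nan"), 0
    amp = np.zeros(freqs.size)
    for t in starts:
        i0 = int(round((t - vm.t0_s) * fs))
        seg = x[i0 : i0 + nseg]
        amp += 2.0 * np.abs(np.fft.rfft(seg)[1:]) / nseg
    amp /= len(starts)
    band = (freqs >= 1.0) & (freqs <= 5.0)
    return freqs, amp, float(amp[band].mean()), len(starts)


def vm_lfp_xcorr(vm: Trace, lfp: Trace, state: IntervalSet, max_lag_s: float = 0.1,
                 stim_times_s: np.ndarray | None = None,
                 params: StateParams | None = None, segment_s: float = 1.0,
                 ) -> tuple[float, float, int]:
    """Peak normalized Vm–LFP cross-correlation over a state.

    Both series are brought to the common analysis rate (the LFP through the
    standard downsample + 200 Hz zero-phase low-pass, the Vm by decimation),
    then per 1 s segment mean-subtracted and SD-normalized.  Correlations
    over lags in ``[-max_lag_s, +max_lag_s]`` are averaged across segments;
    the peak is the extremum of largest absolute value and its signed value
    and lag are returned.  Positive lag means the LFP lags the Vm.  Zero-
    variance segments are skipped.

    Returns ``(peak, lag_s, n_segments)``.
    """
    params = params or StateParams()
    fs = params.lfp_analysis_rate_hz
    stride = int(round(vm.rate_hz / fs))
    if abs(vm.rate_hz - stride * fs) > 1e-6:
        raise ValidationError("vm rate must be an integer multiple of the analysis rate")
    x_all = vm.values[::stride]
    y_all = preprocess_lfp(lfp, params).values
    exclude = stim_exclusion_intervals(stim_times_s) if stim_times_s is not None else None
    starts = _segments(state, segment_s, exclude)
    nseg = int(round(segment_s * fs))
    maxlag = int(round(max_lag_s * fs))
    acc = np.zeros(2 * maxlag + 1)
    used = 0
    for t in starts:
        i0 = int(round((t - vm.t0_s) * fs))
        x = x_all[i0 : i0 + nseg]
        j0 = int(round((t - lfp.t0_s) * fs))
        y = y_all[j0 : j0 + nseg]
        if x.size < nseg or y.size < nseg:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            warnings.warn("zero-variance 1 s segment skipped")
            continue
        xn, yn = (x - x.mean()) / sx, (y - y.mean()) / sy
        # full[k] = sum_t y[t] x[t - (k - (nseg-1))]; lag tau = k - (nseg-1)
        # gives c(tau) = sum_t x[t] y[t + tau] / N
        full = signal.correlate(yn, xn, mode="full", method="fft")
        acc += full[nseg - 1 - maxlag : nseg + maxlag] / nseg
        used += 1
    if used == 0:
        warnings.warn(f"no usable segments in state {state.label!r}")
        return float("nan"), float("nan"), 0
    acc /= used
    k = int(np.argmax(np.abs(acc)))
    return float(acc[k]), (k - maxlag) / fs, used


def analyze_vm_state(vm: Trace, lfp: Trace, state: IntervalSet, spikes: np.ndarray,
                     stim_times_s: np.ndarray | None = None,
                     median_filter_ms: float = 8.0,
                     params: StateParams | None = None) -> VmStateStats:
    """All Vm statistics for one state, bundled."""
    mean, sd = vm_mean_sd(vm, state, spikes, stim_times_s)
    rate = ap_rate(spikes, state)
    freqs, amp, band, nseg = vm_fft_amplitude(
        vm, state, median_filter_ms, stim_times_s
    )
    peak, lag, _ = vm_lfp_xcorr(vm, lfp, state, stim_times_s=stim_times_s, params=params)
    return VmStateStats(
        state=state.label, mean_vm_mV=mean, sd_vm_mV=sd, ap_rate_hz=rate,
        fft_freq_hz=freqs, fft_amplitude_mV=amp, band_amp_1_5_mV=band,
        peak_xcorr=peak, peak_xcorr_lag_s=lag, n_segments=nseg,
    )
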