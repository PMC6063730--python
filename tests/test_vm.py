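"""Spike detection, state-resolved Vm statistics, spectra, cross-correlation."""

import numpy as np
import pytest

from statephys import (
    GeneratorConfig,
    IntervalSet,
    Trace,
    ap_rate,
    detect_aps,
    generate_session,
    vm_fft_amplitude,
    vm_lfp_xcorr,
    vm_mean_sd,
)
from tests.conftest import planted_states


def _spike_trace(peak_times_s, fs=20000.0, dur=1.0, base=-60.0):
    v = np.full(int(dur * fs), base)
    w = int(0.002 * fs)
    template = 60.0 * np.hanning(w)
    for t in peak_times_s:
        i = int(t * fs) - w // 2
        v[i : i + w] += template
    return Trace(v, fs)


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def test_spike_free_trace_yields_no_events():
    rng = np.random.default_rng(0)
    tr = Trace(-60 + 0.5 * rng.standard_normal(20000), 20000.0)
    assert detect_aps(tr).size == 0


def test_planted_spikes_recovered_exactly(pv_session):
    """Recall and precision 1.0 against the generator's planted peaks at a
    1 ms matching tolerance."""
    s, g = pv_session
    detected = detect_aps(s.traces["vm"])
    planted = g.spike_times_s
    assert planted.size > 5
    assert detected.size == planted.size
    assert np.all(np.abs(detected - planted) < 1e-3)


def test_refractory_merges_events_closer_than_two_ms():
    tr = _spike_trace([0.100, 0.101])  # two template peaks 1 ms apart
    assert detect_aps(tr).size == 1
    tr2 = _spike_trace([0.100, 0.104])
    assert detect_aps(tr2).size == 2


# ---------------------------------------------------------------------------
# mean / SD / rate
# ---------------------------------------------------------------------------

def test_constant_trace_mean_sd():
    tr = Trace(np.full(20000, -60.0), 20000.0)
    m, sd = vm_mean_sd(tr, IntervalSet("S", [(0.0, 1.0)]), [])
    assert (m, sd) == (-60.0, 0.0)


def test_empty_state_flagged_nan_not_zero():
    tr = Trace(np.full(2000, -60.0), 20000.0)
    with pytest.warns(UserWarning):
        m, sd = vm_mean_sd(tr, IntervalSet("S"), [])
    assert np.isnan(m) and np.isnan(sd)


def test_state_shift_recovered_noise_free(clean_session):
    s, g = clean_session
    cfg = GeneratorConfig(**s.meta["generator"])
    st = planted_states(g)
    ma, _ = vm_mean_sd(s.traces["vm"], st["Active"], [], s.stim_times_s)
    mq, _ = vm_mean_sd(s.traces["vm"], st["Quiet"], [], s.stim_times_s)
    assert ma - mq == pytest.approx(cfg.vm_state_shift_mV, abs=0.1)


def test_spike_excision_matches_spikeless_twin():
    """Mean with APs excised agrees with the same generator run with spiking
    disabled (paired-generator oracle)."""
    base = dict(duration_s=60.0, seed=33)
    s1, g1 = generate_session(GeneratorConfig(**base))
    s0, _ = generate_session(GeneratorConfig(**base, spikes_enabled=False))
    st = planted_states(g1)["Quiet"]
    spikes = detect_aps(s1.traces["vm"])
    m1, sd1 = vm_mean_sd(s1.traces["vm"], st, spikes, s1.stim_times_s)
    m0, _ = vm_mean_sd(s0.traces["vm"], st, [], s0.stim_times_s)
    assert m1 == pytest.approx(m0, abs=0.2)
    # SD excluding APs never exceeds SD including them
    _, sd_incl = vm_mean_sd(s1.traces["vm"], st, [], s1.stim_times_s)
    assert sd1 <= sd_incl


def test_ap_rate_counts_over_duration():
    spikes = np.arange(10) * 0.4 + 0.1  # 10 spikes inside [0, 5)
    assert ap_rate(spikes, IntervalSet("S", [(0.0, 5.0)])) == pytest.approx(2.0)
    assert ap_rate([], IntervalSet("S", [(0.0, 5.0)])) == 0.0
    with pytest.warns(UserWarning):
        assert np.isnan(ap_rate(spikes, IntervalSet("S")))


def test_state_dependent_rates_recovered_within_poisson_error():
    """Planted quiet-state firing exceeds active-state firing across seeds;
    pooled rates agree with the per-seed spike counts."""
    diffs = []
    for seed in range(5):
        s, g = generate_session(GeneratorConfig(duration_s=60.0, seed=seed))
        st = planted_states(g)
        spikes = detect_aps(s.traces["vm"])
        rq = ap_rate(spikes, st["Quiet"])
        ra = ap_rate(spikes, st["Active"])
        diffs.append(rq - ra)
    assert np.mean(diffs) > 0
    assert sum(d > 0 for d in diffs) >= 4


# ---------------------------------------------------------------------------
# FFT amplitude
# ---------------------------------------------------------------------------

def test_integer_tone_amplitude_closed_form():
    """4 Hz, 5 mV tone on 1 s windows: the 4 Hz bin reads 5 mV and the five
    1–5 Hz bins average to 1 mV."""
    fs = 20000.0
    t = np.arange(int(20 * fs)) / fs
    tr = Trace(5.0 * np.sin(2 * np.pi * 4 * t), fs)
    freqs, amp, band, nseg = vm_fft_amplitude(
        tr, IntervalSet("S", [(0.0, 20.0)]), median_filter_ms=0.0
    )
    assert nseg == 20
    assert amp[freqs == 4.0][0] == pytest.approx(5.0, rel=1e-6)
    assert band == pytest.approx(1.0, rel=1e-6)


def test_band_amplitude_matches_direct_dft_oracle():
    """Pipeline band amplitude equals a brute-force per-segment DFT on the
    same median-filtered signal to 1e-9 relative."""
    rng = np.random.default_rng(8)
    fs, dur = 20000.0, 8.0
    tr = Trace(rng.standard_normal(int(dur * fs)), fs)
    state = IntervalSet("S", [(0.0, dur)])
    freqs, amp, band, nseg = vm_fft_amplitude(tr, state, median_filter_ms=8.0)
    # oracle: own decimation, own sliding median, direct rfft per segment
    x = tr.values[::10]
    k = 17
    pad = np.pad(x, (k // 2, k // 2), mode="edge")
    med = np.array([np.median(pad[i : i + k]) for i in range(x.size)])
    oracle = np.zeros(1000)
    for seg in med.reshape(int(dur), 2000):
        oracle += 2 * np.abs(np.fft.rfft(seg)[1:]) / 2000
    oracle /= dur
    sel = (freqs >= 1) & (freqs <= 5)
    assert band == pytest.approx(oracle[sel].mean(), rel=1e-9)
    assert np.allclose(amp, oracle, rtol=1e-9, atol=1e-12)


def test_no_full_segment_flagged():
    tr = Trace(np.zeros(20000), 20000.0)
    with pytest.warns(UserWarning):
        _, _, band, nseg = vm_fft_amplitude(tr, IntervalSet("S", [(0.0, 0.5)]))
    assert np.isnan(band) and nseg == 0


def test_quiet_slow_fluctuations_exceed_active_for_pv_like():
    for seed in (0, 1, 2):
        s, g = generate_session(GeneratorConfig(duration_s=90.0, seed=seed))
        st = planted_states(g)
        _, _, bq, _ = vm_fft_amplitude(s.traces["vm"], st["Quiet"], 8.0, s.stim_times_s)
        _, _, ba, _ = vm_fft_amplitude(s.traces["vm"], st["Active"], 8.0, s.stim_times_s)
        assert bq > ba


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def _smooth_noise(n, fs, seed, cutoff=50.0):
    from scipy import signal as sg

    rng = np.random.default_rng(seed)
    sos = sg.butter(4, cutoff, fs=fs, output="sos")
    return sg.sosfiltfilt(sos, rng.standard_normal(n))


def test_identical_signals_peak_unity_at_zero_lag():
    fs = 2000.0
    x = _smooth_noise(int(30 * fs), fs, 1)
    peak, lag, n = vm_lfp_xcorr(Trace(x, fs), Trace(x.copy(), fs),
                                IntervalSet("S", [(0.5, 29.5)]))
    assert peak == pytest.approx(1.0, abs=1e-3)
    assert abs(lag) <= 1.0 / fs
    assert n >= 25


def test_shifted_copy_peaks_at_the_shift():
    fs = 2000.0
    x = _smooth_noise(int(30 * fs), fs, 2)
    y = np.roll(x, int(0.020 * fs))  # LFP delayed by 20 ms
    peak, lag, _ = vm_lfp_xcorr(Trace(x, fs), Trace(y, fs),
                                IntervalSet("S", [(0.5, 29.5)]))
    assert peak > 0.9
    assert lag == pytest.approx(0.020, abs=1e-3)


def test_independent_noise_peak_small_and_bounded():
    fs = 2000.0
    x = _smooth_noise(int(32 * fs), fs, 3)
    y = _smooth_noise(int(32 * fs), fs, 4)
    peak, _, n = vm_lfp_xcorr(Trace(x, fs), Trace(y, fs),
                              IntervalSet("S", [(0.5, 31.5)]))
    assert n >= 30
    assert abs(peak) < 0.15


def test_peak_magnitude_never_exceeds_one(pv_session):
    s, g = pv_session
    st = planted_states(g)
    for name in ("Active", "Quiet"):
        peak, _, _ = vm_lfp_xcorr(s.traces["vm"], s.traces["lfp"], st[name],
                                  stim_times_s=s.stim_times_s)
        assert abs(peak) <= 1.0 + 1e-12


def test_pv_positive_sst_negative_state_shift_across_seeds():
    """Directions of the planted state effects recovered in >= 19/20 runs:
    PV-like depolarizes, Sst-like hyperpolarizes in the active state."""
    good = 0
    for seed in range(10):
        for make, sign in ((GeneratorConfig.pv_like, 1), (GeneratorConfig.sst_like, -1)):
            s, g = generate_session(make(duration_s=45.0, seed=seed))
            st = planted_states(g)
            spikes = detect_aps(s.traces["vm"])
            ma, _ = vm_mean_sd(s.traces["vm"], st["Active"], spikes, s.stim_times_s)
            mq, _ = vm_mean_sd(s.traces["vm"], st["Quiet"], spikes, s.stim_times_s)
            good += (np.sign(ma - mq) == sign)
    assert good >= 19
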