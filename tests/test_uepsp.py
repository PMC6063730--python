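"""Evoked-AP statistics and triggered-average uEPSP quantification."""

import numpy as np
import pytest

from statephys import (
    GeneratorConfig,
    IntervalSet,
    Trace,
    UEPSPMeasurement,
    detect_aps,
    evoked_ap_stats,
    generate_session,
    psp_kernel,
    quantify_uepsp,
    state_contrast,
    triggered_average,
)
from tests.conftest import planted_states

FS = 20000.0


def _juxta_with_spikes(peak_times, dur=10.0):
    v = np.zeros(int(dur * FS))
    w = int(0.0015 * FS)
    template = 5.0 * np.hanning(w)
    for t in peak_times:
        i = int(t * FS) - w // 2
        v[i : i + w] += template
    return Trace(v, FS)


# ---------------------------------------------------------------------------
# evoked APs
# ---------------------------------------------------------------------------

def test_ap_within_ten_ms_is_evoked_with_its_latency():
    juxta = _juxta_with_spikes([1.005, 3.005, 5.005])
    e = evoked_ap_stats(juxta, [1.0, 3.0, 5.0])
    assert e.n_evoked == 3 and e.reliability == 1.0
    assert e.latency_ms == pytest.approx(5.0, abs=0.1)
    assert e.jitter_ms == pytest.approx(0.0, abs=0.1)


def test_ap_after_ten_ms_not_evoked():
    juxta = _juxta_with_spikes([1.012])
    e = evoked_ap_stats(juxta, [1.0])
    assert e.n_evoked == 0 and np.isnan(e.latency_ms)


def test_generator_evoked_aps_reliable_and_jittered(pv_session):
    s, _ = pv_session
    cfg = GeneratorConfig(**s.meta["generator"])
    e = evoked_ap_stats(s.traces["juxta"], s.stim_times_s)
    assert e.reliability == 1.0
    assert e.latency_ms == pytest.approx(cfg.pre_ap_latency_ms, abs=0.3)
    assert e.jitter_ms == pytest.approx(cfg.pre_ap_jitter_ms, rel=0.5)


# ---------------------------------------------------------------------------
# triggered average: stimulus exclusion
# ---------------------------------------------------------------------------

def _flat_vm(dur=10.0):
    return Trace(np.full(int(dur * FS), -60.0), FS)


def test_postsynaptic_spike_inside_window_excludes_stimulus():
    vm = _flat_vm()
    state = IntervalSet("Quiet", [(0.0, 10.0)])
    stims = [2.0, 4.0, 6.0]
    # spike at +10 ms falls inside [-20, +30) ms: stimulus excluded
    _, n = triggered_average(vm, stims, state, [4.010])
    assert n == 2
    # spike at +40 ms is outside the window: retained
    _, n = triggered_average(vm, stims, state, [4.040])
    assert n == 3
    # spike 20 ms before onset also excludes
    _, n = triggered_average(vm, stims, state, [3.981])
    assert n == 2


def test_all_stimuli_excluded_flagged():
    vm = _flat_vm()
    with pytest.warns(UserWarning):
        wf, n = triggered_average(vm, [2.0], IntervalSet("Quiet", [(0.0, 10.0)]), [2.005])
    assert wf is None and n == 0


def test_exclusion_count_matches_brute_force_recount(pv_session):
    s, _ = pv_session
    from statephys import classify_session

    states = classify_session(s)
    spikes = detect_aps(s.traces["vm"])
    for name in ("Active", "Quiet"):
        _, n = triggered_average(s.traces["vm"], s.stim_times_s, states[name], spikes)
        expected = 0
        for t in s.stim_times_s:
            if not states[name].covers_span(t - 0.020, t + 0.030):
                continue
            if np.any((spikes >= t - 0.020) & (spikes < t + 0.030)):
                continue
            expected += 1
        assert n == expected


def test_noise_free_average_equals_planted_kernel():
    """With noise and the slow LFP-coupled background off, the triggered
    average reproduces the planted double-exponential up to smoothing."""
    cfg = GeneratorConfig(
        duration_s=60.0, seed=13, vm_noise_sd_mV=0.0, lfp_noise_sd_mV=0.0,
        spikes_enabled=False, pre_ap_jitter_ms=0.0, juxta_noise_sd_mV=0.0,
        vm_delta_coupling=0.0,
    )
    s, g = generate_session(cfg)
    st = planted_states(g)["Quiet"]
    wf, n = triggered_average(s.traces["vm"], s.stim_times_s, st, [])
    assert n >= 5
    delay_s = (cfg.pre_ap_latency_ms + cfg.uepsp_latency_ms) * 1e-3
    kernel = cfg.uepsp_amp_quiet_mV * psp_kernel(
        cfg.uepsp_tau_rise_ms, cfg.uepsp_tau_decay_ms, FS
    )
    t = wf.times()
    recon = np.interp(t - delay_s, np.arange(kernel.size) / FS, kernel, left=0.0)
    from statephys.uepsp import _boxcar

    recon = _boxcar(recon, int(round(0.0005 * FS)))  # same smoothing as the average
    resid = wf.values - wf.values[: int(0.015 * FS)].mean() - recon
    assert np.abs(resid).max() < 0.02 * cfg.uepsp_amp_quiet_mV


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _kernel_waveform(amp=2.0, tau_r=0.7, tau_d=15.0, delay_ms=4.0, base=-60.0):
    n0, n1 = int(-0.020 * FS), int(0.050 * FS)
    t = np.arange(n0, n1) / FS
    k = np.where(t >= delay_ms * 1e-3,
                 np.exp(-(t - delay_ms * 1e-3) / (tau_d * 1e-3))
                 - np.exp(-(t - delay_ms * 1e-3) / (tau_r * 1e-3)), 0.0)
    k /= k.max()
    return Trace(base + amp * k, FS, t0_s=-0.020)


def analytic_rise_20_80(amp, tau_r, tau_d):
    """20–80% rise time of the difference-of-exponentials, densely sampled."""
    t = np.linspace(0, 20e-3, 400000)
    k = np.exp(-t / (tau_d * 1e-3)) - np.exp(-t / (tau_r * 1e-3))
    k = amp * k / k.max()
    t20 = t[np.argmax(k >= 0.2 * amp)]
    t80 = t[np.argmax(k >= 0.8 * amp)]
    return (t80 - t20) * 1e3


def test_planted_kernel_quantified_to_closed_form():
    wf = _kernel_waveform(amp=2.0, delay_ms=4.0)
    m = quantify_uepsp(wf, "PV")
    assert m.detected
    assert m.amplitude_mV == pytest.approx(2.0, abs=0.02)
    assert m.onset_latency_ms == pytest.approx(4.0, abs=0.3)
    assert m.onset_latency_ms < m.peak_time_ms
    expected_rise = analytic_rise_20_80(2.0, 0.7, 15.0)
    assert m.rise_time_20_80_ms == pytest.approx(expected_rise, rel=0.1)
    assert m.baseline_vm_mV == pytest.approx(-60.0, abs=0.02)


def test_flat_waveform_yields_no_uepsp():
    wf = Trace(np.full(int(0.070 * FS), -60.0), FS, t0_s=-0.020)
    m = quantify_uepsp(wf, "PV")
    assert not m.detected
    assert np.isnan(m.amplitude_mV)  # undefined, not zero


def test_lower_sst_threshold_never_delays_onset():
    wf = _kernel_waveform(amp=1.0, tau_r=2.0, tau_d=30.0, delay_ms=5.0)
    pv = quantify_uepsp(wf, "PV")
    sst = quantify_uepsp(wf, "Sst")
    assert sst.detected and pv.detected
    assert sst.onset_latency_ms <= pv.onset_latency_ms


# ---------------------------------------------------------------------------
# state contrast
# ---------------------------------------------------------------------------

def _meas(state, amp, base=-60.0):
    return UEPSPMeasurement(state=state, n_stimuli_used=30, average_waveform=None,
                            detected=True, amplitude_mV=amp, baseline_vm_mV=base)


def test_five_concordant_cells_give_exact_p():
    cells = [{"Active": _meas("Active", 1.5 + 0.1 * i), "Quiet": _meas("Quiet", 1.0)}
             for i in range(5)]
    c = state_contrast(cells, direction="greater")
    assert c["amplitude_test"].p_value == 1 / 32


def test_zero_differences_degenerate_p_one():
    cells = [{"Active": _meas("Active", 1.0), "Quiet": _meas("Quiet", 1.0)}
             for _ in range(4)]
    c = state_contrast(cells, direction="greater")
    assert c["amplitude_test"].p_value == 1.0
    assert c["amplitude_test"].degenerate


def test_missing_state_drops_cell():
    cells = [
        {"Active": _meas("Active", 1.5), "Quiet": _meas("Quiet", 1.0)},
        {"Active": _meas("Active", 1.5)},
    ]
    with pytest.warns(UserWarning):
        c = state_contrast(cells, direction="greater")
    assert c["n_cells"] == 1


def test_type_I_control_with_equal_planted_amplitudes():
    """Cohorts planted with no state contrast rarely reach p < 0.05 (n=5
    one-tailed can only reject when all five differences align)."""
    from statephys import generate_cohort

    cfg = GeneratorConfig(duration_s=60.0, uepsp_amp_quiet_mV=1.0,
                          uepsp_amp_active_mV=1.0, vm_noise_sd_mV=0.3)
    false_pos = 0
    for seed in range(20):
        cohort = generate_cohort(5, cfg, seed=seed)
        cells = []
        for s, g in cohort:
            st = planted_states(g)
            spikes = detect_aps(s.traces["vm"])
            cell = {}
            for name in ("Active", "Quiet"):
                wf, n = triggered_average(s.traces["vm"], s.stim_times_s, st[name], spikes)
                if wf is not None:
                    cell[name] = quantify_uepsp(wf, "PV", n, name)
            cells.append(cell)
        c = state_contrast(cells, direction="greater")
        if "amplitude_test" in c and c["amplitude_test"].p_value < 0.05:
            false_pos += 1
    assert false_pos <= 2


def test_default_generator_trial_counts_in_the_tens(pv_session):
    """Eligible per-state stimulus counts land in the tens, the scale of the
    recorded data sets."""
    s, g = pv_session
    st = planted_states(g)
    spikes = detect_aps(s.traces["vm"])
    for name in ("Active", "Quiet"):
        _, n = triggered_average(s.traces["vm"], s.stim_times_s, st[name], spikes)
        assert 10 <= n <= 100
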