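"""Synthetic awake-recording generator with planted ground truth.

Emulates the statistical structure the analysis pipeline assumes: a two-state
(quiet/active) behavioral alternation; a 1–5 Hz "delta" component in the LFP
whose amplitude is large in quiet and small in active epochs; whisking bouts
confined to active epochs; a membrane potential built as

``Vm = rest + state_shift * 1[active] + coupling * lfp_delta + noise
      + uEPSP train + stylized spikes``

so a PV-like cell (positive shift, strong delta coupling) depolarizes and
loses slow fluctuations in the active state, while an Sst-like cell (negative
shift, weak coupling) hyperpolarizes.  Optogenetic stimuli are delivered at
1 Hz; each triggers a presynaptic juxtacellular spike at a short jittered
latency, followed after a synaptic delay by a double-exponential uEPSP whose
peak amplitude depends on the planted state of the epoch.

Everything is a deterministic function of ``(config, seed)``; the planted
epochs, spike times and per-state uEPSP amplitudes are returned as a
:class:`GroundTruth` so downstream modules can be tested as parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy import signal

from .session import IntervalSet, Session, Trace

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "psp_kernel",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic session.

    Defaults describe a PV-like cell: depolarizing active-state shift, strong
    coupling of the LFP delta band into Vm, and a uEPSP that is larger during
    active epochs.  Use :meth:`sst_like` / :meth:`unconnected` for the other
    cell classes.
    """

    duration_s: float = 180.0
    seed: int = 0
    cell_class: str = "PV"

    # behavioral state process: two-state semi-Markov alternation with
    # exponential dwell times truncated below at min_dwell_s
    epoch_dwell_s: float = 8.0
    min_dwell_s: float = 2.0
    #: probability that an epoch's whisking behavior agrees with its LFP
    #: state (1.0 = whisking iff active); lower values exercise the
    #: unassigned W∩H / NW∩L categories
    state_agreement_fraction: float = 1.0

    # LFP
    quiet_lfp_delta_amp_mV: float = 0.4
    active_lfp_delta_amp_mV: float = 0.1
    lfp_noise_sd_mV: float = 0.02
    #: if set, the delta component is a pure tone at this frequency instead
    #: of narrowband 1–5 Hz noise (analytic test mode)
    lfp_pure_tone_hz: float | None = None
    lfp_ramp_s: float = 0.2

    # whisker
    whisk_amp_deg: float = 15.0
    whisk_freq_hz: float = 8.0
    whisk_noise_sd_deg: float = 0.0
    whisk_ramp_s: float = 0.1

    # membrane potential
    vm_rest_mV: float = -62.0
    vm_state_shift_mV: float = 3.0
    vm_delta_coupling: float = 6.0
    vm_noise_sd_mV: float = 1.0
    vm_noise_cutoff_hz: float = 100.0

    # spikes (stylized template, threshold crossing + refractory)
    spikes_enabled: bool = True
    ap_threshold_mV: float = -55.0
    ap_amp_mV: float = 60.0
    ap_width_ms: float = 2.0
    ap_refractory_ms: float = 5.0

    # optogenetic stimulation and planted uEPSPs; stimulation alternates with
    # stimulus-free blocks, emulating interleaved evoked and spontaneous
    # trials so that clean 1 s spontaneous segments exist alongside 1 Hz
    # stimulation
    stim_rate_hz: float = 1.0
    stim_start_s: float = 2.0
    stim_block_s: float = 30.0
    spont_block_s: float = 30.0
    uepsp_amp_quiet_mV: float = 1.0
    uepsp_amp_active_mV: float = 1.5
    uepsp_tau_rise_ms: float = 0.7
    uepsp_tau_decay_ms: float = 15.0
    uepsp_latency_ms: float = 1.5
    pre_ap_latency_ms: float = 2.5
    pre_ap_jitter_ms: float = 0.3

    # juxtacellular channel
    juxta_spike_amp_mV: float = 5.0
    juxta_spike_width_ms: float = 1.5
    juxta_noise_sd_mV: float = 0.02

    # sampling
    vm_rate_hz: float = 20000.0
    whisker_rate_hz: float = 200.0

    def validate(self) -> None:
        positive = (
            "duration_s", "epoch_dwell_s", "min_dwell_s", "whisk_freq_hz",
            "uepsp_tau_rise_ms", "uepsp_tau_decay_ms", "uepsp_latency_ms",
            "pre_ap_latency_ms", "ap_width_ms", "ap_refractory_ms",
            "vm_rate_hz", "whisker_rate_hz",
        )
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")
        nonneg = (
            "quiet_lfp_delta_amp_mV", "active_lfp_delta_amp_mV",
            "lfp_noise_sd_mV", "whisk_amp_deg", "whisk_noise_sd_deg",
            "vm_noise_sd_mV", "stim_rate_hz", "pre_ap_jitter_ms",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.state_agreement_fraction <= 1.0):
            raise ConfigurationError("state_agreement_fraction must be in [0, 1]")
        if self.uepsp_tau_rise_ms >= self.uepsp_tau_decay_ms:
            raise ConfigurationError("uepsp_tau_rise_ms must be < uepsp_tau_decay_ms")
        if self.epoch_dwell_s <= self.min_dwell_s:
            raise ConfigurationError("epoch_dwell_s must exceed min_dwell_s")

    # -- presets ---------------------------------------------------------
    @classmethod
    def pv_like(cls, **overrides) -> "GeneratorConfig":
        return cls(**overrides)

    @classmethod
    def sst_like(cls, **overrides) -> "GeneratorConfig":
        """Sst-like cell: hyperpolarizes in active, weakly coupled to LFP,
        no consistent state dependence of the uEPSP."""
        defaults = dict(
            cell_class="Sst",
            vm_rest_mV=-55.0,
            vm_state_shift_mV=-3.0,
            vm_delta_coupling=0.5,
            ap_threshold_mV=-52.5,
            uepsp_amp_quiet_mV=0.8,
            uepsp_amp_active_mV=0.8,
            uepsp_tau_rise_ms=2.0,
            uepsp_tau_decay_ms=30.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def unconnected(cls, **overrides) -> "GeneratorConfig":
        """Non-connected control: stimuli evoke presynaptic spikes but no uEPSP."""
        defaults = dict(cell_class="NC", uepsp_amp_quiet_mV=0.0, uepsp_amp_active_mV=0.0)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """Planted structure of a generated session (the test oracle)."""

    state_intervals: dict[str, IntervalSet]
    whisk_intervals: IntervalSet
    planted_uepsp_amp_mV: dict[str, float]
    spike_times_s: np.ndarray
    presyn_spike_times_s: np.ndarray
    stim_states: list[str]
    epoch_mean_vm_mV: list[tuple[float, float, float]] = field(default_factory=list)


def psp_kernel(tau_rise_ms: float, tau_decay_ms: float, rate_hz: float,
               duration_factor: float = 8.0) -> np.ndarray:
    """Difference-of-exponentials PSP kernel, normalized to unit peak.

    ``k(t) = exp(-t/tau_d) - exp(-t/tau_r)`` sampled at ``rate_hz`` over
    ``duration_factor * tau_decay``; the discrete maximum is scaled to 1 so a
    planted amplitude equals the peak deflection up to discretization.
    """
    n = int(round(duration_factor * tau_decay_ms * 1e-3 * rate_hz))
    t = np.arange(n) / rate_hz
    k = np.exp(-t / (tau_decay_ms * 1e-3)) - np.exp(-t / (tau_rise_ms * 1e-3))
    return k / k.max()


def _epoch_sequence(cfg: GeneratorConfig, rng: np.random.Generator):
    """Alternating (label, start, end) epochs covering [0, duration)."""
    epochs = []
    t = 0.0
    label = "quiet"
    while t < cfg.duration_s:
        dwell = cfg.min_dwell_s + rng.exponential(cfg.epoch_dwell_s - cfg.min_dwell_s)
        end = min(t + dwell, cfg.duration_s)
        epochs.append((label, t, end))
        t = end
        label = "active" if label == "quiet" else "quiet"
    return epochs


def _ramped_envelope(n: int, rate_hz: float, epochs, amp_by_label: dict[str, float],
                     ramp_s: float) -> np.ndarray:
    """Per-sample amplitude envelope with raised-cosine ramps at epoch edges."""
    levels = np.empty(n)
    for label, s, e in epochs:
        i0, i1 = int(round(s * rate_hz)), min(int(round(e * rate_hz)), n)
        levels[i0:i1] = amp_by_label[label]
    nr = int(round(ramp_s * rate_hz))
    if nr > 1:
        w = np.hanning(2 * nr + 1)
        w /= w.sum()
        levels = np.convolve(levels, w, mode="same")
    return levels


def _bout_envelope(n: int, rate_hz: float, bouts, ramp_s: float) -> np.ndarray:
    """0/1 envelope over whisking bouts with raised-cosine on/off ramps."""
    env = np.zeros(n)
    nr = max(2, int(round(ramp_s * rate_hz)))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    for s, e in bouts:
        i0, i1 = int(round(s * rate_hz)), min(int(round(e * rate_hz)), n)
        if i1 - i0 < 2 * nr:
            continue
        env[i0:i1] = 1.0
        env[i0:i0 + nr] = ramp
        env[i1 - nr:i1] = ramp[::-1]
    return env


def _upsample(x: np.ndarray, factor: int, n_out: int) -> np.ndarray:
    """Linear-interpolation upsampling by an integer factor."""
    n_in = x.size
    t_out = np.arange(n_out) / factor
    return np.interp(t_out, np.arange(n_in), x)


def _bandlimited_noise(n: int, rate_hz: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to ``band`` (zero-phase)."""
    x = rng.standard_normal(n)
    sos = signal.butter(2, band, btype="bandpass", fs=rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its planted ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.vm_rate_hz
    fw = cfg.whisker_rate_hz
    n = int(round(cfg.duration_s * fs))
    nw = int(round(cfg.duration_s * fw))

    # --- planted behavioral state process -------------------------------
    epochs = _epoch_sequence(cfg, rng)
    quiet_iv = IntervalSet("quiet", [(s, e) for lab, s, e in epochs if lab == "quiet"])
    active_iv = IntervalSet("active", [(s, e) for lab, s, e in epochs if lab == "active"])

    # whisking bouts: active epochs, with optional planted disagreement
    bouts = []
    for lab, s, e in epochs:
        agree = rng.random() < cfg.state_agreement_fraction
        whisks = (lab == "active") == agree
        if whisks:
            bouts.append((s, e))
    whisk_iv = IntervalSet("whisking", bouts)

    # --- LFP -------------------------------------------------------------
    amp_env_rate = 200.0
    amp_env = _ramped_envelope(
        int(round(cfg.duration_s * amp_env_rate)), amp_env_rate, epochs,
        {"quiet": cfg.quiet_lfp_delta_amp_mV, "active": cfg.active_lfp_delta_amp_mV},
        cfg.lfp_ramp_s,
    )
    if cfg.lfp_pure_tone_hz is not None:
        t = np.arange(n) / fs
        delta = _upsample(amp_env, int(round(fs / amp_env_rate)), n) * np.sin(
            2 * np.pi * cfg.lfp_pure_tone_hz * t
        )
    else:
        nb = _bandlimited_noise(amp_env.size, amp_env_rate, (1.0, 5.0), rng)
        delta = _upsample(amp_env * nb, int(round(fs / amp_env_rate)), n)
    lfp = delta.copy()
    if cfg.lfp_noise_sd_mV > 0:
        lfp = lfp + cfg.lfp_noise_sd_mV * rng.standard_normal(n)

    # --- whisker angle ---------------------------------------------------
    tw = np.arange(nw) / fw
    env_w = _bout_envelope(nw, fw, bouts, cfg.whisk_ramp_s)
    angle = env_w * cfg.whisk_amp_deg * np.sin(2 * np.pi * cfg.whisk_freq_hz * tw)
    if cfg.whisk_noise_sd_deg > 0:
        angle = angle + cfg.whisk_noise_sd_deg * rng.standard_normal(nw)

    # --- stimuli, presynaptic spikes, planted uEPSP amplitudes -----------
    if cfg.stim_rate_hz > 0:
        stim_times = np.arange(cfg.stim_start_s, cfg.duration_s - 0.5, 1.0 / cfg.stim_rate_hz)
        cycle = cfg.stim_block_s + cfg.spont_block_s
        if cfg.spont_block_s > 0:
            in_block = ((stim_times - cfg.stim_start_s) % cycle) < cfg.stim_block_s
            stim_times = stim_times[in_block]
    else:
        stim_times = np.empty(0)
    jitter = cfg.pre_ap_jitter_ms * rng.standard_normal(stim_times.size)
    presyn_times = stim_times + (cfg.pre_ap_latency_ms + jitter) * 1e-3
    stim_states = [
        "active" if active_iv.contains(t) else "quiet" for t in stim_times
    ]
    amp_by_state = {"quiet": cfg.uepsp_amp_quiet_mV, "active": cfg.uepsp_amp_active_mV}

    # --- membrane potential ----------------------------------------------
    active_mask = active_iv.contains_times(np.arange(n) / fs)
    vm = cfg.vm_rest_mV + cfg.vm_state_shift_mV * active_mask + cfg.vm_delta_coupling * delta
    if cfg.vm_noise_sd_mV > 0:
        fn = 2000.0
        noise = rng.standard_normal(int(round(cfg.duration_s * fn)))
        sos = signal.butter(4, cfg.vm_noise_cutoff_hz, btype="lowpass", fs=fn, output="sos")
        noise = signal.sosfiltfilt(sos, noise)
        noise /= noise.std()
        vm = vm + cfg.vm_noise_sd_mV * _upsample(noise, int(round(fs / fn)), n)

    kernel = psp_kernel(cfg.uepsp_tau_rise_ms, cfg.uepsp_tau_decay_ms, fs)
    for t_pre, state in zip(presyn_times, stim_states):
        amp = amp_by_state[state]
        if amp == 0:
            continue
        i0 = int(round((t_pre + cfg.uepsp_latency_ms * 1e-3) * fs))
        i1 = min(i0 + kernel.size, n)
        if i0 < n:
            vm[i0:i1] += amp * kernel[: i1 - i0]

    # --- stylized spikes --------------------------------------------------
    spike_times = np.empty(0)
    if cfg.spikes_enabled:
        above = vm >= cfg.ap_threshold_mV
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        w = int(round(cfg.ap_width_ms * 1e-3 * fs))
        template = cfg.ap_amp_mV * np.hanning(w)
        refr = cfg.ap_refractory_ms * 1e-3 * fs
        peaks = []
        last = -np.inf
        for i in crossings:
            if i - last < refr:
                continue
            last = i
            j1 = min(i + w, n)
            vm[i:j1] += template[: j1 - i]
            peaks.append(i + w // 2)
        spike_times = np.array(peaks) / fs

    # --- juxtacellular channel -------------------------------------------
    juxta = cfg.juxta_noise_sd_mV * rng.standard_normal(n)
    wj = int(round(cfg.juxta_spike_width_ms * 1e-3 * fs))
    jtemplate = cfg.juxta_spike_amp_mV * np.hanning(wj)
    for t_pre in presyn_times:
        i0 = int(round(t_pre * fs)) - wj // 2
        s0 = max(i0, 0)
        i1 = min(i0 + wj, n)
        if i1 > s0:
            juxta[s0:i1] += jtemplate[s0 - i0 : i1 - i0]

    session = Session(
        traces={
            "vm": Trace(vm, fs, units="mV"),
            "lfp": Trace(lfp, fs, units="mV"),
            "whisker_angle": Trace(angle, fw, units="deg"),
            "juxta": Trace(juxta, fs, units="mV"),
        },
        stim_times_s=stim_times,
        cell_class=cfg.cell_class,
        meta={"generator": cfg.to_dict()},
    )
    truth = GroundTruth(
        state_intervals={"quiet": quiet_iv, "active": active_iv},
        whisk_intervals=whisk_iv,
        planted_uepsp_amp_mV=amp_by_state,
        spike_times_s=spike_times,
        presyn_spike_times_s=presyn_times,
        stim_states=stim_states,
        epoch_mean_vm_mV=[
            (s, e, cfg.vm_rest_mV + (cfg.vm_state_shift_mV if lab == "active" else 0.0))
            for lab, s, e in epochs
        ],
    )
    return session, truth


def generate_cohort(
    n_cells: int,
    config: GeneratorConfig,
    seed: int,
    amp_jitter_frac: float = 0.1,
    rest_jitter_mV: float = 1.0,
) -> list[tuple[Session, GroundTruth]]:
    """Generate ``n_cells`` independent sessions from a per-class template.

    Per-cell parameters are jittered around the template: the resting
    potential receives additive Gaussian jitter (SD ``rest_jitter_mV``) and
    both per-state uEPSP amplitudes are scaled by one shared factor
    ``max(0.2, 1 + N(0, amp_jitter_frac))`` so the planted quiet/active
    contrast keeps its sign in every cell.  Per-cell seeds derive
    deterministically from ``seed``.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n_cells):
        child_seed = int(master.integers(0, 2**31 - 1))
        scale = max(0.2, 1.0 + amp_jitter_frac * master.standard_normal())
        rest_shift = rest_jitter_mV * master.standard_normal()
        cfg = replace(
            config,
            seed=child_seed,
            # the spike threshold tracks the resting potential so per-cell
            # excitability stays comparable across the cohort
            vm_rest_mV=config.vm_rest_mV + rest_shift,
            ap_threshold_mV=config.ap_threshold_mV + rest_shift,
            uepsp_amp_quiet_mV=config.uepsp_amp_quiet_mV * scale,
            uepsp_amp_active_mV=config.uepsp_amp_active_mV * scale,
        )
        out.append(generate_session(cfg))
    return out
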