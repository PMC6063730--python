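"""End-to-end cohort analysis: simulate → classify → analyze → test.

`run_cohort_analysis` generates PV-like and Sst-like cohorts, pushes every
session through the full segmentation and analysis chain starting from the
raw traces, and assembles a report mirroring the study's comparison
structure: per-cell state-resolved Vm statistics and uEPSP measurements,
cohort box-plot summaries, paired two-tailed signed-rank tests for the
Quiet-vs-Active Vm quantities, and one-tailed signed-rank tests for the
hypothesized uEPSP-amplitude and baseline-Vm state contrasts (PV increase /
depolarization, Sst decrease / hyperpolarization).  Undefined stage results
propagate as explicit nulls (NaN → ``null`` in JSON), never silent zeros.

The whole run is a deterministic function of the config; a report includes
every parameter block that produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .session import Session
from .states import StateParams, classify_session, state_agreement
from .stats import box_stats, signed_rank_exact
from .synth import GeneratorConfig, GroundTruth, generate_cohort
from .uepsp import (
    UEPSPMeasurement,
    evoked_ap_stats,
    quantify_uepsp,
    state_contrast,
    triggered_average,
)
from .vm import analyze_vm_state, detect_aps

__all__ = ["RunConfig", "run_cohort_analysis", "analyze_session"]

#: hypothesized direction of the Active − Quiet uEPSP/baseline contrast
CLASS_DIRECTION = {"PV": "greater", "Sst": "less", "NC": "greater"}


@dataclass
class RunConfig:
    """Fully serializable description of one cohort run."""

    seed: int = 0
    n_cells: int = 5
    classes: tuple[str, ...] = ("PV", "Sst")
    duration_s: float = 180.0
    generator_overrides: dict = field(default_factory=dict)
    per_class_overrides: dict = field(default_factory=dict)
    state_params: StateParams = field(default_factory=StateParams)
    median_filter_ms: float = 8.0
    amp_jitter_frac: float = 0.1
    rest_jitter_mV: float = 1.0
    include_uepsp: bool = True
    include_spectra: bool = True

    def generator_config(self, cell_class: str) -> GeneratorConfig:
        base = {"PV": GeneratorConfig.pv_like, "Sst": GeneratorConfig.sst_like,
                "NC": GeneratorConfig.unconnected}[cell_class]
        over = dict(duration_s=self.duration_s)
        over.update(self.generator_overrides)
        over.update(self.per_class_overrides.get(cell_class, {}))
        return base(**over)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["classes"] = list(self.classes)
        d["state_params"] = asdict(self.state_params)
        return d


def _stats_dict(s) -> dict:
    return {
        "state": s.state, "mean_vm_mV": s.mean_vm_mV, "sd_vm_mV": s.sd_vm_mV,
        "ap_rate_hz": s.ap_rate_hz, "band_amp_1_5_mV": s.band_amp_1_5_mV,
        "peak_xcorr": s.peak_xcorr, "peak_xcorr_lag_s": s.peak_xcorr_lag_s,
        "n_segments": s.n_segments,
    }


def _uepsp_dict(m: UEPSPMeasurement) -> dict:
    return {
        "state": m.state, "n_stimuli_used": m.n_stimuli_used, "detected": m.detected,
        "amplitude_mV": m.amplitude_mV, "onset_latency_ms": m.onset_latency_ms,
        "peak_time_ms": m.peak_time_ms, "rise_time_20_80_ms": m.rise_time_20_80_ms,
        "baseline_vm_mV": m.baseline_vm_mV,
    }


def analyze_session(session: Session, cfg: RunConfig,
                    truth: GroundTruth | None = None) -> dict:
    """Classify one session from its raw traces and compute all per-state
    quantities; with ground truth attached, add recovery diagnostics."""
    sp = cfg.state_params
    states = classify_session(session, sp)
    vm = session.traces["vm"]
    spikes = detect_aps(vm)
    out: dict = {"cell_class": session.cell_class, "n_spikes": int(spikes.size)}
    measurements: dict[str, UEPSPMeasurement] = {}
    for name in ("Active", "Quiet"):
        state = states[name]
        if cfg.include_spectra:
            s = analyze_vm_state(vm, session.traces["lfp"], state, spikes,
                                 session.stim_times_s, cfg.median_filter_ms, sp)
            out[name] = _stats_dict(s)
        else:
            from .vm import ap_rate, vm_mean_sd
            mean, sd = vm_mean_sd(vm, state, spikes, session.stim_times_s)
            out[name] = {"state": name, "mean_vm_mV": mean, "sd_vm_mV": sd,
                         "ap_rate_hz": ap_rate(spikes, state)}
        if cfg.include_uepsp:
            wf, n_used = triggered_average(vm, session.stim_times_s, state, spikes, sp)
            if wf is None:
                m = UEPSPMeasurement(state=name, n_stimuli_used=0, average_waveform=None)
            else:
                m = quantify_uepsp(wf, session.cell_class, n_used, name)
            measurements[name] = m
            out[name]["uepsp"] = _uepsp_dict(m)
    if cfg.include_uepsp:
        evoked = evoked_ap_stats(session.traces["juxta"], session.stim_times_s)
        out["evoked_ap"] = {
            "n_stimuli": evoked.n_stimuli, "n_evoked": evoked.n_evoked,
            "reliability": evoked.reliability, "latency_ms": evoked.latency_ms,
            "jitter_ms": evoked.jitter_ms,
        }
    out["_measurements"] = measurements
    if truth is not None:
        out["recovery"] = {
            "state_agreement": state_agreement(
                states["Active"], states["Quiet"],
                truth.state_intervals["active"], truth.state_intervals["quiet"]),
            "planted_uepsp_amp_mV": truth.planted_uepsp_amp_mV,
            "n_planted_spikes": int(truth.spike_times_s.size),
        }
    return out


def _paired_tests(cells: list[dict], keys: tuple[str, ...]) -> dict:
    """Two-tailed signed-rank Quiet-vs-Active tests on per-cell quantities."""
    tests = {}
    for key in keys:
        diffs = [c["Active"][key] - c["Quiet"][key] for c in cells
                 if np.isfinite(c["Active"].get(key, np.nan))
                 and np.isfinite(c["Quiet"].get(key, np.nan))]
        if not diffs:
            tests[key] = None
            continue
        r = signed_rank_exact(diffs, sided="two")
        tests[key] = {"diffs": diffs, "p_value": r.p_value, "statistic": r.statistic,
                      "n": r.n, "exact": r.exact,
                      "box": asdict(box_stats(diffs))}
    return tests


def run_cohort_analysis(cfg: RunConfig) -> dict:
    """Simulate cohorts for every configured cell class and analyze them."""
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config": cfg.to_dict(), "classes": {}}
    vm_keys = ("mean_vm_mV", "sd_vm_mV", "ap_rate_hz")
    if cfg.include_spectra:
        vm_keys = vm_keys + ("band_amp_1_5_mV", "peak_xcorr")
    for cls in cfg.classes:
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        gen_cfg = cfg.generator_config(cls)
        cohort = generate_cohort(cfg.n_cells, gen_cfg, cohort_seed,
                                 cfg.amp_jitter_frac, cfg.rest_jitter_mV)
        cells, measurements = [], []
        for session, truth in cohort:
            res = analyze_session(session, cfg, truth)
            measurements.append(res.pop("_measurements"))
            cells.append(res)
        entry = {
            "generator_config": gen_cfg.to_dict(),
            "cohort_seed": cohort_seed,
            "cells": cells,
            "vm_tests": _paired_tests(cells, vm_keys),
        }
        if cfg.include_uepsp:
            entry["uepsp_contrast"] = _contrast_dict(measurements, CLASS_DIRECTION[cls])
        report["classes"][cls] = entry
    return report


def _contrast_dict(measurements, direction: str) -> dict:
    c = state_contrast(measurements, direction)
    out = {"direction": direction,
           "amplitude_diffs_mV": c["amplitude_diffs_mV"],
           "baseline_diffs_mV": c["baseline_diffs_mV"],
           "n_cells": c["n_cells"]}
    for key in ("amplitude_test", "baseline_test"):
        if key in c:
            r = c[key]
            out[key] = {"statistic": r.statistic, "p_value": r.p_value,
                        "sided": r.sided, "direction": r.direction,
                        "n": r.n, "exact": r.exact}
    return out


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (NaN → null)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, float) and not np.isfinite(o):
            return None
        return o

    return json.dumps(clean(report), indent=1, sort_keys=True, default=default)
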