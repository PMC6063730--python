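"""Shared fixtures: small synthetic sessions generated at test time."""

import warnings

import numpy as np
import pytest

from statephys import GeneratorConfig, generate_session


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Analysis code flags undefined results with warnings; keep test output
    readable without hiding genuine errors."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def pv_session():
    """A default PV-like 120 s session with ground truth (shared, read-only)."""
    return generate_session(GeneratorConfig(duration_s=120.0, seed=11))


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free, spike-free session: Vm is exactly the deterministic part
    plus the planted uEPSP train."""
    cfg = GeneratorConfig(
        duration_s=60.0, seed=13, vm_noise_sd_mV=0.0, lfp_noise_sd_mV=0.0,
        spikes_enabled=False, pre_ap_jitter_ms=0.0, juxta_noise_sd_mV=0.0,
    )
    return generate_session(cfg)


def planted_states(truth):
    """Planted quiet/active epochs relabeled to the classifier's names."""
    from statephys import IntervalSet

    return {
        "Active": IntervalSet("Active", truth.state_intervals["active"].intervals),
        "Quiet": IntervalSet("Quiet", truth.state_intervals["quiet"].intervals),
    }
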