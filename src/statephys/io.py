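"""On-disk session format.

A session is a directory holding

* ``meta.json`` — format version, cell class, stimulus times, per-channel
  metadata (file name, sampling rate, start time, units, sample count) and
  free-form metadata;
* one raw little-endian float64 array per channel (``vm.f64``, ``lfp.f64``,
  ``whisker.f64``, ``juxta.f64``, other roles ``<role>.f64``);
* ``states.json`` — labeled half-open intervals.

The layout is human-inspectable (JSON + flat arrays) and round-trips
bit-for-bit.  An optional single-file HDF5 mirror with the same logical
layout (groups ``/traces/<role>``, ``/states/<label>``, metadata in attrs)
is provided for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .session import IntervalSet, Session, Trace, ValidationError

__all__ = [
    "read_session",
    "write_session",
    "read_session_hdf5",
    "write_session_hdf5",
    "SessionFormatError",
]

FORMAT_VERSION = 1

_ROLE_FILES = {"vm": "vm.f64", "lfp": "lfp.f64", "whisker_angle": "whisker.f64", "juxta": "juxta.f64"}


class SessionFormatError(ValueError):
    """Raised when an on-disk session is malformed or incomplete."""


def _channel_file(role: str) -> str:
    return _ROLE_FILES.get(role, f"{role}.f64")


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` to directory ``path`` (created if needed)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traces_meta = {}
    for role, tr in session.traces.items():
        fname = _channel_file(role)
        tr.values.astype("<f8").tofile(path / fname)
        traces_meta[role] = {
            "file": fname,
            "rate_hz": tr.rate_hz,
            "t0_s": tr.t0_s,
            "units": tr.units,
            "n_samples": int(tr.n),
        }
    meta = {
        "format_version": FORMAT_VERSION,
        "cell_class": session.cell_class,
        "stim_times_s": session.stim_times_s.tolist(),
        "traces": traces_meta,
        "meta": session.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    states = {label: iv.intervals.tolist() for label, iv in session.states.items()}
    (path / "states.json").write_text(json.dumps(states, indent=1, sort_keys=True))


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Sampling rates and units are taken from the metadata, never guessed;
    missing mandatory keys raise :class:`SessionFormatError` naming the key,
    and invariant violations raise :class:`ValidationError`.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionFormatError(f"{path}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    for key in ("format_version", "cell_class", "stim_times_s", "traces"):
        if key not in meta:
            raise SessionFormatError(f"{meta_path}: missing mandatory key {key!r}")
    traces = {}
    for role, tm in meta["traces"].items():
        for key in ("file", "rate_hz", "t0_s", "units", "n_samples"):
            if key not in tm:
                raise SessionFormatError(f"{meta_path}: trace {role!r} missing key {key!r}")
        values = np.fromfile(path / tm["file"], dtype="<f8")
        if values.size != tm["n_samples"]:
            raise SessionFormatError(
                f"{path / tm['file']}: expected {tm['n_samples']} samples, found {values.size}"
            )
        traces[role] = Trace(values, rate_hz=tm["rate_hz"], t0_s=tm["t0_s"], units=tm["units"])
    states = {}
    states_path = path / "states.json"
    if states_path.exists():
        for label, iv in json.loads(states_path.read_text()).items():
            states[label] = IntervalSet(label, np.asarray(iv, dtype=np.float64).reshape(-1, 2))
    return Session(
        traces=traces,
        stim_times_s=np.asarray(meta["stim_times_s"], dtype=np.float64),
        cell_class=meta["cell_class"],
        states=states,
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# HDF5 mirror
# ---------------------------------------------------------------------------

def write_session_hdf5(session: Session, path: str | Path) -> None:
    import h5py

    session.validate()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["cell_class"] = session.cell_class
        f.attrs["meta_json"] = json.dumps(session.meta, sort_keys=True)
        f.create_dataset("stim_times_s", data=session.stim_times_s)
        g = f.create_group("traces")
        for role, tr in session.traces.items():
            d = g.create_dataset(role, data=tr.values)
            d.attrs["rate_hz"] = tr.rate_hz
            d.attrs["t0_s"] = tr.t0_s
            d.attrs["units"] = tr.units
        s = f.create_group("states")
        for label, iv in session.states.items():
            s.create_dataset(label, data=iv.intervals)


def read_session_hdf5(path: str | Path) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        traces = {
            role: Trace(
                d[()],
                rate_hz=float(d.attrs["rate_hz"]),
                t0_s=float(d.attrs["t0_s"]),
                units=str(d.attrs["units"]),
            )
            for role, d in f["traces"].items()
        }
        states = {
            label: IntervalSet(label, d[()].reshape(-1, 2)) for label, d in f["states"].items()
        }
        return Session(
            traces=traces,
            stim_times_s=f["stim_times_s"][()],
            cell_class=str(f.attrs["cell_class"]),
            states=states,
            meta=json.loads(f.attrs["meta_json"]),
        )
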