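"""Core in-memory containers for a recording session.

A session bundles uniformly sampled channels (membrane potential, local field
potential, whisker angle, juxtacellular signal), optogenetic stimulus onset
times, cell metadata and labeled state epochs.  All timing is expressed in
seconds from session start; state epochs are half-open intervals ``[start,
end)`` and every cross-rate alignment is done in seconds, never in sample
indices.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "IntervalSet",
    "Session",
    "ValidationError",
    "CELL_CLASSES",
    "TRACE_UNITS",
]

#: Recognised postsynaptic / presynaptic cell classes.
CELL_CLASSES = ("PV", "Sst", "NC", "presynaptic")

#: Canonical units per channel role.
TRACE_UNITS = {"vm": "mV", "lfp": "mV", "juxta": "mV", "whisker_angle": "deg"}


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class Trace:
    """A uniformly sampled channel.

    Parameters
    ----------
    values : ndarray
        Sample values (mV for electrophysiological channels, degrees for the
        whisker angle).
    rate_hz : float
        Sampling rate in samples/s; must be positive.
    t0_s : float
        Session time of the first sample, seconds.
    units : str
        Unit string, kept with the data so files are self-describing.
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace contains non-finite samples")
        if not (self.rate_hz > 0):
            raise ValidationError(f"rate_hz must be > 0, got {self.rate_hz}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Index of the sample at or immediately after session time ``t_s``."""
        return int(np.ceil((t_s - self.t0_s) * self.rate_hz - 1e-9))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.rate_hz == other.rate_hz
            and self.t0_s == other.t0_s
            and self.units == other.units
            and np.array_equal(self.values, other.values)
        )


@dataclass
class IntervalSet:
    """Labeled, sorted, pairwise-disjoint half-open intervals ``[start, end)``."""

    label: str
    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.float64).reshape(-1, 2)
        if iv.size and not np.all(iv[:, 0] < iv[:, 1]):
            raise ValidationError(f"{self.label}: every interval needs start < end")
        if iv.size and not np.all(iv[1:, 0] >= iv[:-1, 1]):
            raise ValidationError(
                f"{self.label}: intervals must be sorted and non-overlapping"
            )
        self.intervals = iv

    # -- basic queries ---------------------------------------------------
    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def covers_span(self, start_s: float, end_s: float) -> bool:
        """True iff ``[start_s, end_s)`` lies inside a single interval."""
        if len(self) == 0 or end_s <= start_s:
            return False
        i = bisect_right(self.intervals[:, 0].tolist(), start_s) - 1
        if i < 0:
            return False
        s, e = self.intervals[i]
        return s <= start_s and end_s <= e

    def contains(self, t_s: float) -> bool:
        return self.covers_span(t_s, t_s + 1e-12)

    def contains_times(self, times_s: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of time points."""
        t = np.asarray(times_s, dtype=np.float64)
        if len(self) == 0:
            return np.zeros(t.shape, dtype=bool)
        starts, ends = self.intervals[:, 0], self.intervals[:, 1]
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] < ends[idx[ok]]
        return out

    # -- algebra ---------------------------------------------------------
    def intersect(self, other: "IntervalSet", label: str | None = None) -> "IntervalSet":
        """Set intersection on half-open intervals (two-pointer sweep)."""
        a, b = self.intervals, other.intervals
        out: list[tuple[float, float]] = []
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i, 0], b[j, 0])
            e = min(a[i, 1], b[j, 1])
            if s < e:
                out.append((s, e))
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(label or f"{self.label}&{other.label}", np.array(out).reshape(-1, 2))

    def intersection_duration_s(self, other: "IntervalSet") -> float:
        return self.intersect(other).total_duration_s

    def union_duration_s(self, other: "IntervalSet") -> float:
        return (
            self.total_duration_s
            + other.total_duration_s
            - self.intersection_duration_s(other)
        )

    def jaccard(self, other: "IntervalSet") -> float:
        u = self.union_duration_s(other)
        return self.intersection_duration_s(other) / u if u > 0 else 0.0

    def merge_gaps(self, max_gap_s: float) -> "IntervalSet":
        """Merge intervals separated by gaps shorter than ``max_gap_s``."""
        if len(self) == 0:
            return self
        out = [list(self.intervals[0])]
        for s, e in self.intervals[1:]:
            if s - out[-1][1] < max_gap_s:
                out[-1][1] = e
            else:
                out.append([s, e])
        return IntervalSet(self.label, np.array(out))

    def drop_short(self, min_duration_s: float) -> "IntervalSet":
        iv = self.intervals
        keep = (iv[:, 1] - iv[:, 0]) >= min_duration_s
        return IntervalSet(self.label, iv[keep])

    def sample_mask(self, trace: Trace) -> np.ndarray:
        """Boolean mask over ``trace`` samples whose time lies in the set."""
        mask = np.zeros(trace.n, dtype=bool)
        for s, e in self.intervals:
            i0 = max(0, trace.index_of(s))
            i1 = min(trace.n, trace.index_of(e))
            if i1 > i0:
                mask[i0:i1] = True
        return mask

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.label == other.label and np.array_equal(self.intervals, other.intervals)


@dataclass
class Session:
    """One recording: channels, stimulus times, cell metadata, state epochs."""

    traces: dict[str, Trace]
    stim_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    cell_class: str = "NC"
    states: dict[str, IntervalSet] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=np.float64).ravel()
        self.validate()

    def validate(self) -> None:
        if not self.traces:
            raise ValidationError("session needs at least one trace")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"cell_class must be one of {CELL_CLASSES}, got {self.cell_class!r}"
            )
        if self.stim_times_s.size and not np.all(np.diff(self.stim_times_s) > 0):
            raise ValidationError("stim_times_s must be strictly increasing")
        # all traces must cover a common span (within one sample period)
        starts = [tr.t0_s for tr in self.traces.values()]
        ends = [tr.end_s for tr in self.traces.values()]
        tols = [1.0 / tr.rate_hz for tr in self.traces.values()]
        tol = max(tols)
        if max(starts) - min(starts) > tol or max(ends) - min(ends) > tol:
            raise ValidationError("traces do not cover a common session span")

    @property
    def duration_s(self) -> float:
        return max(tr.end_s for tr in self.traces.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.traces == other.traces
            and np.array_equal(self.stim_times_s, other.stim_times_s)
            and self.cell_class == other.cell_class
            and self.states == other.states
            and self.meta == other.meta
        )
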