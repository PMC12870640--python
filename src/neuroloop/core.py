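"""Shared containers and interval utilities.

Time convention used throughout the package: seconds from recording start,
half-open intervals ``[start, end)``.  Absolute (wall-clock) alignment is
carried by :class:`EEGRecording.start_time` and applied only where a rule
depends on the time of day (notification quiet hours, 12-h sleep reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Literal, Sequence

import numpy as np

Modality = Literal["scalp", "ieeg"]

EVENT_SOURCES = ("model", "push_button", "patient", "clinician", "ground_truth")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class SeizureEvent:
    """A half-open seizure interval ``[start, end)`` in seconds.

    ``mean_prob`` / ``max_prob`` summarise the model probability over the
    event and are NaN for events that did not come from a probability trace
    (push-button alarms, ground truth).
    """

    start: float
    end: float
    source: str = "model"
    mean_prob: float = float("nan")
    max_prob: float = float("nan")

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"event end ({self.end}) must exceed start ({self.start})"
            )
        if self.source not in EVENT_SOURCES:
            raise ValidationError(f"unknown event source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "SeizureEvent") -> bool:
        return self.start < other.end and other.start < self.end


def intervals_overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> bool:
    """True iff half-open intervals [a_start,a_end) and [b_start,b_end) intersect."""
    return a_start < b_end and b_start < a_end


def merge_intervals(
    intervals: Sequence[tuple[float, float]], gap: float, *, strict: bool = True
) -> list[tuple[float, float]]:
    """Merge sorted-or-not intervals whose separation is < gap (strict) or <= gap.

    Runs to fixpoint; output is sorted and pairwise non-adjacent under the rule.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        sep = s - out[-1][1]
        mergeable = sep < gap if strict else sep <= gap
        if mergeable:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class EEGRecording:
    """Timestamped multichannel EEG in microvolts.

    ``data`` is channels x samples; ``modality`` selects scalp vs intracranial
    processing rules downstream.
    """

    data: np.ndarray
    channel_names: list[str]
    fs: float
    start_time: datetime | None = None
    modality: Modality = "scalp"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.modality not in ("scalp", "ieeg"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "EEGRecording":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)


@dataclass
class ProbabilityTrace:
    """Windowed seizure probabilities on a uniform grid.

    ``p`` is 1-D (scalar trace, scalp path) or channels x windows (per-channel
    trace, intracranial path).  Window ``i`` covers
    ``[window_start_times[i], window_start_times[i] + stride)``.
    """

    p: np.ndarray
    window_start_times: np.ndarray
    stride: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.window_start_times = np.asarray(self.window_start_times, dtype=np.float64)
        if self.p.ndim not in (1, 2):
            raise ValidationError("p must be 1-D or channels x windows")
        if self.n_windows != self.window_start_times.shape[0]:
            raise ValidationError("p and window_start_times length mismatch")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if not self.stride > 0:
            raise ValidationError("stride must be positive")
        if self.n_windows > 1:
            d = np.diff(self.window_start_times)
            if not np.allclose(d, d[0], rtol=0, atol=1e-9):
                raise ValidationError("window grid must be uniform")

    @property
    def is_multichannel(self) -> bool:
        return self.p.ndim == 2

    @property
    def n_windows(self) -> int:
        return self.p.shape[-1]

    def scalar(self) -> np.ndarray:
        """Per-window scalar series (max over channels for multichannel traces)."""
        return self.p.max(axis=0) if self.is_multichannel else self.p


@dataclass
class WindowBatch:
    """Fixed-length analysis windows cut from a recording on a uniform grid."""

    windows: np.ndarray  # n x channels x samples
    window_start_times: np.ndarray
    window_length: float
    stride: float
    fs_out: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.window_start_times = np.asarray(self.window_start_times, dtype=np.float64)
        if self.windows.ndim != 3:
            raise ValidationError("windows must be n x channels x samples")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class LabelSeries:
    """Per-window weak labels: 1 (seizure), 0 (non-seizure) or NaN (excluded)."""

    labels: np.ndarray
    window_start_times: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.window_start_times = np.asarray(self.window_start_times, dtype=np.float64)
        if self.labels.shape != self.window_start_times.shape:
            raise ValidationError("labels and grid length mismatch")
        finite = self.labels[~np.isnan(self.labels)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValidationError("labels must be 0, 1 or NaN")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.labels)


def events_to_intervals(events: Iterable[SeizureEvent]) -> list[tuple[float, float]]:
    return [(e.start, e.end) for e in events]


def window_overlap_mask(
    window_start_times: np.ndarray, stride: float, events: Iterable[SeizureEvent]
) -> np.ndarray:
    """Boolean mask of windows whose half-open span intersects any event."""
    t = np.asarray(window_start_times, dtype=np.float64)
    mask = np.zeros(t.shape[0], dtype=bool)
    for ev in events:
        mask |= (t < ev.end) & (t + stride > ev.start)
    return mask
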