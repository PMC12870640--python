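"""Weak labels from patient interactions.

Converts push-button alarms, in-app yes/no/uncertain annotation responses and
spike timestamps into time-aligned training labels and derived events.
Label semantics: windows overlapping a patient-confirmed ('yes') event are 1,
windows under an unanswered or 'uncertain' event are NaN (excluded from
training), everything else — including windows under events answered 'no' —
is 0 (hard negatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    LabelSeries,
    SeizureEvent,
    ValidationError,
    merge_intervals,
    window_overlap_mask,
)

RESPONSES = ("yes", "no", "uncertain")

# push-button alarm padding: one minute before to two minutes after the press
ALARM_PRE_S = 60.0
ALARM_POST_S = 120.0


@dataclass(frozen=True)
class AnnotationResponse:
    """A patient's answer to one detected event.

    ``event_ref`` is the index of the event in the detected-event list it
    refers to.  One response per event; when several arrive the latest
    ``response_time`` wins.
    """

    event_ref: int
    response: str
    response_time: float

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValidationError(f"unknown response {self.response!r}")


def pushbutton_to_events(
    alarm_times: Sequence[float],
    recording_duration: float | None = None,
) -> list[SeizureEvent]:
    """Expand alarm presses into seizure events [t-60, t+120), merged on overlap.

    Events are clipped to [0, recording_duration) when a duration is given.
    """
    if len(alarm_times) == 0:
        return []
    intervals = []
    for t in sorted(alarm_times):
        s, e = t - ALARM_PRE_S, t + ALARM_POST_S
        s = max(0.0, s)
        if recording_duration is not None:
            e = min(e, recording_duration)
        if e > s:
            intervals.append((s, e))
    # overlapping (gap <= 0) alarm windows merge into one event
    merged = merge_intervals(intervals, gap=0.0, strict=False)
    return [SeizureEvent(s, e, source="push_button") for s, e in merged]


def resolve_responses(responses: Sequence[AnnotationResponse]) -> dict[int, str]:
    """Latest-wins response per event index."""
    best: dict[int, tuple[float, str]] = {}
    for r in responses:
        cur = best.get(r.event_ref)
        if cur is None or r.response_time >= cur[0]:
            best[r.event_ref] = (r.response_time, r.response)
    return {k: v for k, (_, v) in best.items()}


def responses_to_labels(
    detected: Sequence[SeizureEvent],
    responses: Sequence[AnnotationResponse],
    window_start_times: np.ndarray,
    stride: float,
    pre_margin: float = 60.0,
    probabilities: np.ndarray | None = None,
) -> LabelSeries:
    """Weak per-window labels from annotation responses on detected events.

    Detected event boundaries lag the underlying seizure at both ends, so a
    confirmed ('yes') event is an event-level statement, not a window-level
    one.  Two refinements keep boundary windows from becoming mislabelled
    hard examples:

    * windows within ``pre_margin`` seconds before a 'yes' event are
      excluded (NaN) rather than hard-zeroed — they are often ictal
      (detection onset latency), and hard-zeroing them teaches the
      classifier to suppress seizure onsets;
    * when the per-window ``probabilities`` that produced the detections
      are supplied, windows inside a 'yes' event that the model itself
      scored below 0.5 (typically the post-event accumulator drain) are
      excluded rather than labelled 1, since forcing them positive teaches
      the classifier that plain background is ictal.
    """
    n_ev = len(detected)
    for r in responses:
        if not (0 <= r.event_ref < n_ev):
            raise ValidationError(f"response references unknown event {r.event_ref}")
    by_event = resolve_responses(responses)
    grid = np.asarray(window_start_times, dtype=np.float64)
    labels = np.zeros(grid.shape[0], dtype=np.float64)
    # order matters: NaN (unanswered/uncertain) applied after zeros, 'yes' last
    # so that a window under both an uncertain and a confirmed event counts as 1
    nan_events = [
        ev
        for i, ev in enumerate(detected)
        if by_event.get(i, "unanswered") in ("unanswered", "uncertain")
    ]
    yes_events = [ev for i, ev in enumerate(detected) if by_event.get(i) == "yes"]
    labels[window_overlap_mask(grid, stride, nan_events)] = np.nan
    if pre_margin > 0 and yes_events:
        onset_pads = [
            SeizureEvent(ev.start - pre_margin, ev.start, source=ev.source)
            for ev in yes_events
            if ev.start > 0
        ]
        labels[window_overlap_mask(grid, stride, onset_pads)] = np.nan
    yes_mask = window_overlap_mask(grid, stride, yes_events)
    labels[yes_mask] = 1.0
    if probabilities is not None:
        p = np.asarray(probabilities, dtype=np.float64)
        if p.shape != grid.shape:
            raise ValidationError("probabilities must align with the window grid")
        labels[yes_mask & (p < 0.5)] = np.nan
    return LabelSeries(labels=labels, window_start_times=grid)


def labels_from_truth(
    truth: Sequence[SeizureEvent], window_start_times: np.ndarray, stride: float
) -> LabelSeries:
    """Ground-truth 0/1 labels (clinician or simulation oracle)."""
    grid = np.asarray(window_start_times, dtype=np.float64)
    labels = window_overlap_mask(grid, stride, truth).astype(np.float64)
    return LabelSeries(labels=labels, window_start_times=grid)


def spike_rate_events(
    spike_times: Sequence[float],
    rate_threshold: float = 10.0,
    merge_gap: float = 60.0,
    bin_length: float = 60.0,
) -> list[SeizureEvent]:
    """Elevated-spike-rate events from spike timestamps.

    Spikes are counted on non-overlapping 1-minute bins; bins whose count
    strictly exceeds ``rate_threshold`` become candidate segments, and
    candidates separated by ``merge_gap`` seconds or less are merged.
    """
    times = np.asarray(sorted(spike_times), dtype=np.float64)
    if times.size == 0:
        return []
    if np.any(times < 0):
        raise ValidationError("spike times must be non-negative")
    n_bins = int(times.max() // bin_length) + 1
    counts, _ = np.histogram(times, bins=n_bins, range=(0.0, n_bins * bin_length))
    hot = [
        (i * bin_length, (i + 1) * bin_length)
        for i in range(n_bins)
        if counts[i] > rate_threshold
    ]
    merged = merge_intervals(hot, gap=merge_gap, strict=False)
    return [SeizureEvent(s, e, source="model") for s, e in merged]
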