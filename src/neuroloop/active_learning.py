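"""Clinician-in-the-loop daily refinement.

At the end of each day the deployed model's probability trace over the
day's recording is scanned for the segments it is least confident about
(least-confidence score 1 - max(p, 1-p), averaged per segment).  The ten
most uncertain non-overlapping 90-s segments are sent for expert review;
returned labels fine-tune the model with the same loss, freezing and
distillation machinery as the patient-in-the-loop sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import LabelSeries, ProbabilityTrace, SeizureEvent, ValidationError, WindowBatch
from .finetune import FineTuneConfig, run_finetune_session
from .model import SurrogateClassifier

SEGMENT_S = 90.0
N_QUERIES = 10


@dataclass
class QuerySegment:
    start: float
    end: float
    uncertainty: float
    clinician_label: str = "unlabeled"  # seizure | non_seizure | unlabeled

    def __post_init__(self) -> None:
        if self.clinician_label not in ("seizure", "non_seizure", "unlabeled"):
            raise ValidationError(f"unknown label {self.clinician_label!r}")


@dataclass
class QueryBatch:
    segments: list[QuerySegment] = field(default_factory=list)
    partial: bool = False  # fewer than the requested n segments fit the trace


def segment_uncertainty(trace: ProbabilityTrace, start: float, length: float) -> float:
    """Mean least-confidence score of windows overlapping [start, start+length)."""
    p = trace.scalar()
    t = trace.window_start_times
    sel = (t < start + length) & (t + trace.stride > start)
    if not sel.any():
        return 0.0
    u = 1.0 - np.maximum(p[sel], 1.0 - p[sel])
    return float(u.mean())


def least_confidence_select(
    trace: ProbabilityTrace,
    n: int = N_QUERIES,
    segment_length: float = SEGMENT_S,
) -> QueryBatch:
    """Greedy selection of the n most uncertain non-overlapping segments.

    Candidate segments start at every window start (dense grid).  At each
    round the highest-uncertainty candidate is taken — earliest start on
    ties — and all candidates overlapping it are excluded.  The result is
    the lexicographically optimal feasible selection: each chosen segment's
    uncertainty is at least that of every remaining non-overlapping
    candidate.
    """
    t = trace.window_start_times
    end_of_grid = t[-1] + trace.stride
    cand_starts = t[t + segment_length <= end_of_grid + 1e-9]
    if cand_starts.size == 0:
        return QueryBatch(segments=[], partial=True)
    scores = np.array(
        [segment_uncertainty(trace, s, segment_length) for s in cand_starts]
    )
    alive = np.ones(cand_starts.size, dtype=bool)
    chosen: list[QuerySegment] = []
    while len(chosen) < n and alive.any():
        live = np.flatnonzero(alive)
        best = live[np.argmax(scores[live])]  # argmax takes first max: earliest start
        s = cand_starts[best]
        chosen.append(QuerySegment(start=float(s), end=float(s + segment_length),
                                   uncertainty=float(scores[best])))
        alive &= ~(
            (cand_starts < s + segment_length) & (cand_starts + segment_length > s)
        )
    chosen.sort(key=lambda q: q.start)
    return QueryBatch(segments=chosen, partial=len(chosen) < n)


def label_segments_from_truth(
    batch: QueryBatch, truth: list[SeizureEvent]
) -> QueryBatch:
    """Oracle clinician: label each query segment by overlap with ground truth."""
    for q in batch.segments:
        hit = any(q.start < ev.end and ev.start < q.end for ev in truth)
        q.clinician_label = "seizure" if hit else "non_seizure"
    return batch


def clinician_update(
    model: SurrogateClassifier,
    batch: QueryBatch,
    windows: WindowBatch,
    cfg: FineTuneConfig | None = None,
    seed: int = 0,
) -> SurrogateClassifier:
    """Fine-tune on clinician-labelled segments; windows outside labelled
    segments are excluded (NaN).  With no labelled segments the model is
    returned unchanged (with a warning)."""
    labelled = [q for q in batch.segments if q.clinician_label != "unlabeled"]
    if not labelled:
        warnings.warn("no labelled segments; clinician update is a no-op")
        return model
    t = windows.window_start_times
    y = np.full(t.shape[0], np.nan)
    for q in labelled:
        sel = (t < q.end) & (t + windows.stride > q.start)
        y[sel] = 1.0 if q.clinician_label == "seizure" else 0.0
    labels = LabelSeries(labels=y, window_start_times=t)
    res = run_finetune_session(model, windows, labels, cfg=cfg, seed=seed)
    if res.status != "trained":
        return model
    return res.best_checkpoint
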