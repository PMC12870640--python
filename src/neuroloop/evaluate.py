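"""Event-level and sample-level scoring of seizure detections.

Implements event-based scoring in the style of seizure-community scoring
frameworks: reference and hypothesis events are first canonicalised (merge
events separated by < 90 s, split events longer than 5 min), then a
reference event counts as detected if any predicted event overlaps it within
a 30-s preictal / 60-s postictal tolerance.  Sensitivity, precision, F1 and
false alarms per hour are event-wise; AUROC/AUPRC are sample-wise.  A paired
baseline-vs-fine-tuned comparison uses one-sided Wilcoxon signed-rank tests
on per-patient median deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import SeizureEvent, ValidationError, merge_intervals

MERGE_GAP_S = 90.0
SPLIT_S = 300.0
PRE_TOL_S = 30.0
POST_TOL_S = 60.0


@dataclass
class EvalResult:
    """Event- and sample-level performance for one evaluation span.

    Fractions are in [0, 1]; metrics that are undefined on the span (e.g.
    sensitivity with zero reference events) are None.
    """

    event_sensitivity: float | None = None
    event_precision: float | None = None
    event_f1: float | None = None
    false_alarms_per_hour: float = 0.0
    auroc: float | None = None
    auprc: float | None = None
    n_true_events: int = 0
    n_pred_events: int = 0
    duration_h: float = 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def canonicalize_events(events: list[SeizureEvent]) -> list[SeizureEvent]:
    """Merge events separated by < 90 s (to fixpoint), then split events
    longer than 5 min into consecutive 300-s chunks plus a remainder."""
    if not events:
        return []
    source = events[0].source
    merged = merge_intervals([(e.start, e.end) for e in events], gap=MERGE_GAP_S, strict=True)
    out: list[SeizureEvent] = []
    for s, e in merged:
        while e - s > SPLIT_S:
            out.append(SeizureEvent(s, s + SPLIT_S, source=source))
            s += SPLIT_S
        out.append(SeizureEvent(s, e, source=source))
    return out


def score_events(
    pred: list[SeizureEvent],
    truth: list[SeizureEvent],
    duration_h: float,
    pre_tol: float = PRE_TOL_S,
    post_tol: float = POST_TOL_S,
) -> EvalResult:
    """Event-level scoring with pre/postictal tolerance.

    A reference event is detected iff any prediction overlaps its extension
    [start - pre_tol, end + post_tol); a prediction is a false alarm iff it
    overlaps no extended reference event.
    """
    if not duration_h > 0:
        raise ValidationError("duration must be positive")
    ext = [(max(0.0, t.start - pre_tol), t.end + post_tol) for t in truth]
    detected = sum(
        1 for (s, e) in ext if any(p.start < e and s < p.end for p in pred)
    )
    fp = sum(
        1 for p in pred if not any(p.start < e and s < p.end for (s, e) in ext)
    )
    res = EvalResult(
        n_true_events=len(truth),
        n_pred_events=len(pred),
        duration_h=duration_h,
        false_alarms_per_hour=fp / duration_h,
    )
    if truth:
        res.event_sensitivity = detected / len(truth)
    if pred:
        res.event_precision = (len(pred) - fp) / len(pred)
    if res.event_sensitivity is not None and res.event_precision is not None:
        denom = res.event_sensitivity + res.event_precision
        res.event_f1 = 0.0 if denom == 0 else 2 * res.event_sensitivity * res.event_precision / denom
    return res


def sample_auc(
    probabilities: np.ndarray, labels: np.ndarray
) -> tuple[float | None, float | None]:
    """Sample-level (AUROC, AUPRC); NaN labels excluded.

    With a single class present AUROC is None; AUPRC falls back to the
    prevalence (the average-precision value of an uninformative ranking).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    keep = ~np.isnan(y)
    p, y = p[keep], y[keep]
    if p.size == 0:
        return None, None
    if len(np.unique(y)) < 2:
        prevalence = float(y.mean())
        return None, prevalence
    return float(roc_auc_score(y, p)), float(average_precision_score(y, p))


@dataclass
class ComparisonReport:
    """Paired per-patient comparison of baseline vs fine-tuned performance."""

    metric_deltas: dict[str, list[float]] = field(default_factory=dict)
    median_delta: dict[str, float] = field(default_factory=dict)
    percent_change: dict[str, float | None] = field(default_factory=dict)
    wilcoxon: dict[str, dict] = field(default_factory=dict)


_METRICS = ("event_sensitivity", "event_f1", "false_alarms_per_hour")
# expected direction of improvement per metric for the one-sided test
DEFAULT_DIRECTIONS = {
    "event_sensitivity": "greater",
    "event_f1": "greater",
    "false_alarms_per_hour": "less",
}


def percent_change(before: float, after: float) -> float | None:
    """Signed percent change from before to after (None if before == 0)."""
    if before == 0:
        return None
    return 100.0 * (after - before) / before


def _wilcoxon_one_sided(deltas: np.ndarray, alternative: str) -> dict:
    """One-sided signed-rank test of median(delta) vs 0.

    Exact null for n <= 25 (scipy's exact method, zeros dropped per the
    standard convention), normal approximation above.
    """
    nz = deltas[deltas != 0]
    if deltas.size < 2 or nz.size == 0:
        return {"statistic": None, "p_value": None, "n": int(deltas.size)}
    method = "exact" if nz.size <= 25 and not _has_tied_ranks(nz) else "approx"
    res = stats.wilcoxon(deltas, alternative=alternative, method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n": int(deltas.size),
        "method": method,
    }


def _has_tied_ranks(x: np.ndarray) -> bool:
    a = np.abs(x)
    return np.unique(a).size < a.size


def compare_models(
    per_patient_baseline: list[EvalResult],
    per_patient_finetuned: list[EvalResult],
    directions: dict[str, str] | None = None,
) -> ComparisonReport:
    """Per-patient deltas (fine-tuned minus baseline) with one-sided
    Wilcoxon signed-rank tests in the expected direction of each metric."""
    if len(per_patient_baseline) != len(per_patient_finetuned):
        raise ValidationError("paired result lists must have equal length")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    rep = ComparisonReport()
    for m in _METRICS:
        deltas = []
        for b, f in zip(per_patient_baseline, per_patient_finetuned):
            vb, vf = getattr(b, m), getattr(f, m)
            if vb is None or vf is None:
                continue
            deltas.append(vf - vb)
        rep.metric_deltas[m] = deltas
        if not deltas:
            continue
        arr = np.asarray(deltas)
        rep.median_delta[m] = float(np.median(arr))
        base_vals = [getattr(b, m) for b in per_patient_baseline if getattr(b, m) is not None]
        fin_vals = [getattr(f, m) for f in per_patient_finetuned if getattr(f, m) is not None]
        if base_vals and fin_vals:
            rep.percent_change[m] = percent_change(
                float(np.median(base_vals)), float(np.median(fin_vals))
            )
        rep.wilcoxon[m] = _wilcoxon_one_sided(arr, directions[m])
    return rep
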