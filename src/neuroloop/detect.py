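"""Seizure-event detection from probability traces.

The detector turns a per-window seizure-probability series into discrete
events in four stages:

1. a data-adaptive threshold k(t) — trailing-window mean plus a multiple of
   the standard deviation, recomputed on a coarse stride and held
   piecewise-constant;
2. a one-sided CUSUM accumulator  S(t) = max(0, S(t-1) + p(t) - k(t)),
   flagging samples where S exceeds the decision threshold h;
3. morphological smoothing (binary opening then closing), merging of nearby
   runs and removal of short events;
4. for multichannel (intracranial) traces, per-channel CUSUM followed by a
   channel-fraction vote.

A separate notification filter applies the patient-facing gating rules
(probability thresholds for scalp, minimum duration for intracranial,
overnight quiet hours).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import binary_closing, binary_opening

from .core import ProbabilityTrace, SeizureEvent, ValidationError, merge_intervals

QUIET_START_H = 21  # push notifications disabled 21:00-08:00
QUIET_END_H = 8

SCALP_MEAN_PROB_MIN = 0.80
SCALP_MAX_PROB_MIN = 0.95
IEEG_MIN_NOTIFY_S = 60.0


@dataclass
class DetectorConfig:
    """Detection parameters.

    Defaults follow the scalp pathway (sd_multiplier 1.2); the intracranial
    pathway uses sd_multiplier 0.8 with a 10% channel-fraction vote.
    """

    sd_multiplier: float = 1.2
    adapt_window: float = 400.0
    adapt_stride: float = 100.0
    h: float = 3.0
    merge_gap: float = 2.0
    min_duration: float = 10.0
    channel_fraction: float = 0.10
    struct_element: int = 3

    def __post_init__(self) -> None:
        for name in (
            "sd_multiplier", "adapt_window", "adapt_stride", "h",
            "merge_gap", "min_duration", "struct_element",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.channel_fraction < 1:
            raise ValidationError("channel_fraction must be in (0, 1)")

    @classmethod
    def scalp(cls) -> "DetectorConfig":
        return cls(sd_multiplier=1.2)

    @classmethod
    def ieeg(cls) -> "DetectorConfig":
        return cls(sd_multiplier=0.8)


def adaptive_threshold(p: np.ndarray, stride: float, cfg: DetectorConfig) -> np.ndarray:
    """Piecewise-constant k(t) = mean + sd_multiplier * SD over the trailing
    adaptation window, recomputed every ``adapt_stride`` seconds.

    Population statistics; before a full window has accrued, all available
    history (including the current sample) is used.  Causal: later samples
    never change earlier thresholds.
    """
    p = np.asarray(p, dtype=np.float64)
    n = p.shape[0]
    if n == 0:
        return np.empty(0)
    win = max(1, int(round(cfg.adapt_window / stride)))
    step = max(1, int(round(cfg.adapt_stride / stride)))
    k = np.empty(n)
    for u in range(0, n, step):
        hist = p[max(0, u + 1 - win) : u + 1]
        val = hist.mean() + cfg.sd_multiplier * hist.std()
        k[u : u + step] = val
    return k


def cusum_detect(p: np.ndarray, k: np.ndarray, h: float = 3.0) -> np.ndarray:
    """One-sided CUSUM: S(t) = max(0, S(t-1) + p(t) - k(t)), S(0-) = 0;
    sample t flagged iff S(t) > h (strict)."""
    p = np.asarray(p, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if p.shape != k.shape:
        raise ValidationError("p and k must have equal length")
    flags = np.zeros(p.shape[0], dtype=bool)
    s = 0.0
    for t in range(p.shape[0]):
        s = max(0.0, s + p[t] - k[t])
        flags[t] = s > h
    return flags


def eventize(
    flags: np.ndarray,
    window_start_times: np.ndarray,
    stride: float,
    cfg: DetectorConfig,
    p: np.ndarray | None = None,
) -> list[SeizureEvent]:
    """Flagged samples -> events: binary opening then closing (flat element of
    ``struct_element`` samples), runs to intervals, merge gaps < merge_gap,
    drop events shorter than min_duration; per-event mean/max probability
    from ``p`` when provided."""
    flags = np.asarray(flags, dtype=bool)
    t = np.asarray(window_start_times, dtype=np.float64)
    if flags.shape != t.shape:
        raise ValidationError("flags and window grid length mismatch")
    if flags.size == 0 or not flags.any():
        return []
    st = np.ones(int(cfg.struct_element), dtype=bool)
    sm = binary_closing(binary_opening(flags, structure=st), structure=st)
    # runs of 1s -> half-open intervals on the window grid
    padded = np.concatenate([[False], sm, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    intervals = [(t[i], t[j - 1] + stride) for i, j in zip(starts, ends)]
    merged = merge_intervals(intervals, gap=cfg.merge_gap, strict=True)
    events = []
    for s, e in merged:
        if e - s < cfg.min_duration:
            continue
        if p is not None:
            sel = (t < e) & (t + stride > s)
            pw = np.asarray(p)[..., sel]
            mean_p = float(pw.mean()) if pw.size else float("nan")
            max_p = float(pw.max()) if pw.size else float("nan")
        else:
            mean_p = max_p = float("nan")
        events.append(SeizureEvent(s, e, source="model", mean_prob=mean_p, max_prob=max_p))
    return events


def aggregate_channels(channel_flags: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    """Channel-fraction vote: sample flagged iff the fraction of flagged
    channels strictly exceeds ``channel_fraction``."""
    cf = np.asarray(channel_flags, dtype=bool)
    if cf.ndim != 2 or cf.shape[0] == 0:
        raise ValidationError("channel_flags must be channels x windows, >= 1 channel")
    return cf.mean(axis=0) > cfg.channel_fraction


def detect_events(trace: ProbabilityTrace, cfg: DetectorConfig | None = None) -> list[SeizureEvent]:
    """Full chain: adaptive threshold -> CUSUM -> (channel vote) -> eventize."""
    if cfg is None:
        cfg = DetectorConfig.ieeg() if trace.is_multichannel else DetectorConfig.scalp()
    if trace.is_multichannel:
        ch_flags = np.stack(
            [
                cusum_detect(row, adaptive_threshold(row, trace.stride, cfg), cfg.h)
                for row in trace.p
            ]
        )
        flags = aggregate_channels(ch_flags, cfg)
        p_summary = trace.scalar()
    else:
        k = adaptive_threshold(trace.p, trace.stride, cfg)
        flags = cusum_detect(trace.p, k, cfg.h)
        p_summary = trace.p
    return eventize(flags, trace.window_start_times, trace.stride, cfg, p=p_summary)


def notification_filter(
    events: list[SeizureEvent],
    modality: str,
    recording_start: datetime,
) -> tuple[list[SeizureEvent], list[SeizureEvent]]:
    """Patient-notification gating.

    Scalp events qualify iff mean_prob >= 0.80 and max_prob >= 0.95;
    intracranial events iff duration > 60 s.  Qualifying events whose
    wall-clock start falls in the overnight quiet hours [21:00, 08:00) are
    suppressed (stored but not pushed).  Returns (notify, suppress);
    non-qualifying events appear in neither list.
    """
    if modality not in ("scalp", "ieeg"):
        raise ValidationError(f"unknown modality {modality!r}")
    notify, suppress = [], []
    for ev in events:
        if modality == "scalp":
            ok = (
                not np.isnan(ev.mean_prob)
                and ev.mean_prob >= SCALP_MEAN_PROB_MIN
                and ev.max_prob >= SCALP_MAX_PROB_MIN
            )
        else:
            ok = ev.duration > IEEG_MIN_NOTIFY_S
        if not ok:
            continue
        wall = recording_start + timedelta(seconds=ev.start)
        in_quiet = wall.hour >= QUIET_START_H or wall.hour < QUIET_END_H
        (suppress if in_quiet else notify).append(ev)
    return notify, suppress
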