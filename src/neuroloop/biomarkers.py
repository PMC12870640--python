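"""Derived EEG and medication biomarkers.

Sleep-stage post-processing (mode-filter smoothing, sleep-bout events,
12-hour reports), the alpha-delta band-power ratio, global phase synchrony
via the Hilbert analytic signal, and anti-seizure-medication (ASM) load from
dose logs under a first-order (bolus absorption, exponential elimination)
pharmacokinetic model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert, welch

from .core import EEGRecording, SeizureEvent, ValidationError, merge_intervals

SLEEP_STAGES = ("wake", "REM", "N1", "N2", "N3")
EPOCH_S = 30.0

ALPHA_BAND = (8.0, 13.0)
DELTA_BAND = (1.0, 4.0)

LN2 = float(np.log(2.0))


# --------------------------------------------------------------------- sleep


@dataclass
class SleepStageSeries:
    """Hypnogram: one stage per 30-s epoch on a uniform grid."""

    stages: list[str]
    epoch_start_times: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=np.float64)
        if len(self.stages) != self.epoch_start_times.shape[0]:
            raise ValidationError("stages and epoch grid length mismatch")
        bad = set(self.stages) - set(SLEEP_STAGES)
        if bad:
            raise ValidationError(f"unknown sleep stages {sorted(bad)}")
        if len(self.stages) > 1:
            d = np.diff(self.epoch_start_times)
            if not np.allclose(d, EPOCH_S, rtol=0, atol=1e-6):
                raise ValidationError("epochs must lie on a uniform 30-s grid")

    def __len__(self) -> int:
        return len(self.stages)


def smooth_hypnogram(series: SleepStageSeries, window: int = 15) -> SleepStageSeries:
    """Mode-filter the hypnogram with a centred window.

    Each epoch is replaced by the modal stage within the centred window
    (truncated at the edges); ties are broken toward the epoch's original
    stage, and otherwise toward the stage order wake < REM < N1 < N2 < N3.
    """
    if window % 2 != 1 or window < 1:
        raise ValidationError("mode-filter window must be odd and positive")
    half = window // 2
    stages = series.stages
    out = []
    for i in range(len(stages)):
        lo, hi = max(0, i - half), min(len(stages), i + half + 1)
        counts = Counter(stages[lo:hi])
        best = max(counts.values())
        candidates = [s for s, c in counts.items() if c == best]
        if stages[i] in candidates:
            out.append(stages[i])
        else:
            candidates.sort(key=SLEEP_STAGES.index)
            out.append(candidates[0])
    return SleepStageSeries(stages=out, epoch_start_times=series.epoch_start_times.copy())


def sleep_events(
    series: SleepStageSeries, max_gap: float = 90.0, min_duration: float = 300.0
) -> list[SeizureEvent]:
    """Sleep bouts: runs of non-wake epochs, bridging wake gaps <= max_gap,
    discarding merged bouts shorter than min_duration."""
    t = series.epoch_start_times
    runs: list[tuple[float, float]] = []
    start = None
    for i, s in enumerate(series.stages):
        asleep = s != "wake"
        if asleep and start is None:
            start = t[i]
        if not asleep and start is not None:
            runs.append((start, t[i]))
            start = None
    if start is not None:
        runs.append((start, t[-1] + EPOCH_S))
    merged = merge_intervals(runs, gap=max_gap, strict=False)
    return [
        SeizureEvent(s, e, source="model")
        for s, e in merged
        if e - s >= min_duration
    ]


def sleep_report(
    series: SleepStageSeries,
    recording_start: datetime,
    period: str = "19:00-07:00",
) -> dict:
    """Per-stage minutes and fractions over one 12-hour reporting period.

    ``period`` is ``"19:00-07:00"`` (overnight) or ``"07:00-19:00"`` (daytime).
    Fractions are computed over the epochs actually recorded inside the
    period; ``coverage`` reports the fraction of the 12-h window covered.
    """
    if period not in ("19:00-07:00", "07:00-19:00"):
        raise ValidationError(f"unknown reporting period {period!r}")
    start_h = 19 if period.startswith("19") else 7
    # first period boundary at or before the recording start
    day0 = recording_start.replace(hour=start_h, minute=0, second=0, microsecond=0)
    if day0 > recording_start:
        day0 -= timedelta(days=1)
    p_start = (day0 - recording_start).total_seconds()
    p_end = p_start + 12 * 3600.0

    minutes = {s: 0.0 for s in SLEEP_STAGES}
    covered = 0.0
    for i, stage in enumerate(series.stages):
        t0 = series.epoch_start_times[i]
        lo, hi = max(t0, p_start), min(t0 + EPOCH_S, p_end)
        if hi > lo:
            minutes[stage] += (hi - lo) / 60.0
            covered += (hi - lo) / 60.0
    fractions = {
        s: (m / covered if covered > 0 else 0.0) for s, m in minutes.items()
    }
    return {
        "period": period,
        "minutes": minutes,
        "fractions": fractions,
        "covered_minutes": covered,
        "coverage": covered / 720.0,
    }


# ------------------------------------------------------------ spectral ratio


def _band_mean_psd(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError(f"no PSD bins inside band {band}")
    return psd[..., sel].mean(axis=-1)

def alpha_delta_ratio(
    rec: EEGRecording,
    window_s: float = 60.0,
    exclude_channels: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha (8-13 Hz) over delta (1-4 Hz) mean-power ratio per 1-min window.

    Operates on common-average-referenced data; PSD by Welch with 4-s
    segments and 50% overlap, averaged across non-excluded channels.
    Returns (window_start_times, ratios); a trailing partial window is dropped.
    """
    keep = [i for i, c in enumerate(rec.channel_names) if c not in set(exclude_channels)]
    if not keep:
        raise ValidationError("all channels excluded")
    n_win = int(rec.n_samples // (window_s * rec.fs))
    nper = int(min(4.0 * rec.fs, window_s * rec.fs))
    starts, ratios = [], []
    wlen = int(window_s * rec.fs)
    for w in range(n_win):
        seg = rec.data[keep, w * wlen : (w + 1) * wlen]
        freqs, psd = welch(seg, fs=rec.fs, nperseg=nper, noverlap=nper // 2, axis=-1)
        alpha = _band_mean_psd(freqs, psd, ALPHA_BAND)
        delta = _band_mean_psd(freqs, psd, DELTA_BAND)
        ratios.append(float(np.mean(alpha / np.maximum(delta, 1e-300))))
        starts.append(w * window_s)
    return np.asarray(starts), np.asarray(ratios)


# ----------------------------------------------------------------- synchrony


def phase_synchrony(
    rec: EEGRecording,
    window_s: float = 60.0,
    exclude_channels: Sequence[str] = (),
    method: str = "resultant",
) -> tuple[np.ndarray, np.ndarray]:
    """Global phase-synchrony index per non-overlapping window.

    Instantaneous phases come from the Hilbert analytic signal of each
    (common-average-referenced, non-artifact) channel; at each sample the
    synchrony is the circular resultant R(t) = |mean_c exp(i phi_c(t))|,
    and the window index is the time average of R(t).  R lies in [0, 1]:
    1 for identical phases, 0 for an exactly antiphase pair.  With
    ``method="pairwise_plv"`` the per-sample index is instead the mean
    cosine phase difference magnitude over channel pairs.
    """
    keep = [i for i, c in enumerate(rec.channel_names) if c not in set(exclude_channels)]
    if len(keep) < 2:
        raise ValidationError("phase synchrony requires >= 2 usable channels")
    data = rec.data[keep]
    phases = np.angle(hilbert(data, axis=-1))
    if method == "resultant":
        resultant = np.abs(np.exp(1j * phases).mean(axis=0))  # R(t), per sample
    elif method == "pairwise_plv":
        c = len(keep)
        # mean over unordered pairs of |cos(dphi)| at each sample
        acc = np.zeros(data.shape[1])
        for i in range(c):
            for j in range(i + 1, c):
                acc += np.abs(np.cos(phases[i] - phases[j]))
        resultant = acc / (c * (c - 1) / 2)
    else:
        raise ValidationError(f"unknown synchrony method {method!r}")
    wlen = int(window_s * rec.fs)
    n_win = data.shape[1] // wlen
    starts = np.arange(n_win) * window_s
    idx = np.array(
        [resultant[w * wlen : (w + 1) * wlen].mean() for w in range(n_win)]
    )
    return starts, idx


# ----------------------------------------------------------------------- ASM


@dataclass(frozen=True)
class DoseRecord:
    drug: str
    dose_mg: float
    time_h: float

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValidationError("dose must be non-negative")


@dataclass
class DoseLog:
    """Medication administration records, sorted by time (stable within ties)."""

    records: list[DoseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.time_h)

    def drugs(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.drug not in seen:
                seen.append(r.drug)
        return seen


@dataclass(frozen=True)
class PKParams:
    """Per-drug pharmacokinetic parameters.

    By default absorption is instantaneous (bolus) with first-order
    elimination; an optional first-order absorption phase is enabled by
    setting ``absorption_half_life_h``.
    """

    half_life_h: float
    scale: float = 1.0  # dose (mg) -> concentration units
    absorption_half_life_h: float | None = None

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValidationError("half-life must be positive")
        if self.absorption_half_life_h is not None and not self.absorption_half_life_h > 0:
            raise ValidationError("absorption half-life must be positive")


def _drug_concentration(
    records: list[DoseRecord], params: PKParams, t_h: np.ndarray
) -> np.ndarray:
    c = np.zeros_like(t_h)
    ke = LN2 / params.half_life_h
    ka = (
        LN2 / params.absorption_half_life_h
        if params.absorption_half_life_h is not None
        else None
    )
    for r in records:
        dt = t_h - r.time_h
        on = dt >= 0
        if ka is None:
            c[on] += r.dose_mg * params.scale * np.exp(-ke * dt[on])
        else:
            # one-compartment first-order absorption (Bateman), normalized
            # so the elimination-limited tail matches the bolus model
            c[on] += (
                r.dose_mg * params.scale * ka / (ka - ke)
                * (np.exp(-ke * dt[on]) - np.exp(-ka * dt[on]))
            )
    return c


def _steady_state_reference(records: list[DoseRecord], params: PKParams) -> float:
    """Steady-state mean concentration of the drug's logged maintenance regimen.

    For a regular regimen of dose D every tau hours the time-averaged
    steady-state concentration is D*scale/(ke*tau).  With a single logged
    dose (no interval) the peak D*scale is used instead.
    """
    doses = [r.dose_mg for r in records]
    d_ref = float(np.median(doses))
    if len(records) < 2:
        return max(d_ref * params.scale, 1e-300)
    taus = np.diff([r.time_h for r in records])
    tau = float(np.median(taus))
    if tau <= 0:
        return max(d_ref * params.scale, 1e-300)
    ke = LN2 / params.half_life_h
    return max(d_ref * params.scale / (ke * tau), 1e-300)


def asm_load(
    log: DoseLog,
    params: Mapping[str, PKParams],
    duration_h: float,
    grid_min: float = 1.0,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Total anti-seizure-medication load on a 1-minute grid.

    Each drug's concentration is the superposition of exponentially decaying
    boluses c(t) = sum_i dose_i * scale * exp(-ln2 (t - t_i)/t_half).  With
    ``normalize`` the per-drug concentration is divided by that drug's
    steady-state reference so different drugs are commensurable before
    summation.  Returns (times_h, load).
    """
    missing = [d for d in log.drugs() if d not in params]
    if missing:
        raise ValidationError(f"no PK parameters for drug(s): {missing}")
    t_h = np.arange(0.0, duration_h + 1e-12, grid_min / 60.0)
    total = np.zeros_like(t_h)
    for drug in log.drugs():
        recs = [r for r in log.records if r.drug == drug]
        c = _drug_concentration(recs, params[drug], t_h)
        if normalize:
            c = c / _steady_state_reference(recs, params[drug])
        total += c
    return t_h, total
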