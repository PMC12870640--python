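"""Canonical EEG preprocessing.

Band-pass and notch filtering (zero-phase), bad-channel detection,
re-referencing (common average or bipolar), first-difference prewhitening,
and windowing with optional resampling and robust scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import butter, iirnotch, resample_poly, sosfiltfilt, tf2sos, welch

from .core import EEGRecording, ValidationError, WindowBatch

SCALP_BAND = (0.5, 100.0)
IEEG_BAND = (0.5, 250.0)
NOTCH_FREQS = (60.0, 120.0)
NOTCH_Q = 30.0


@dataclass
class BadChannelReport:
    bad: set[str] = field(default_factory=set)
    reasons: dict[str, set[str]] = field(default_factory=dict)
    contaminated_pairs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for ch in self.bad:
            if not self.reasons.get(ch):
                raise ValidationError(f"bad channel {ch!r} has no reason")


def filter_record(
    rec: EEGRecording,
    band: tuple[float, float] | None = None,
    notch_freqs: tuple[float, ...] = NOTCH_FREQS,
) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass plus IIR notches (Q=30).

    Defaults: 0.5-100 Hz for scalp, 0.5-250 Hz for intracranial recordings;
    notches at 60 and 120 Hz.  Requires fs > 2x the upper band edge.
    """
    lo, hi = band if band is not None else (
        SCALP_BAND if rec.modality == "scalp" else IEEG_BAND
    )
    if rec.fs <= 2 * hi:
        raise ValidationError(
            f"fs={rec.fs} Hz too low for band ({lo}, {hi}) Hz on modality "
            f"{rec.modality!r}; need fs > {2 * hi}"
        )
    sos = butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sosfiltfilt(sos, rec.data, axis=-1)
    for f0 in notch_freqs:
        if f0 < rec.fs / 2:
            b, a = iirnotch(f0, NOTCH_Q, fs=rec.fs)
            out = sosfiltfilt(tf2sos(b, a), out, axis=-1)
    return rec.copy_with(data=out)


def detect_bad_channels(
    rec: EEGRecording,
    flat_tol: float = 1e-3,
    amp_tol: float = 10.0,
    ln_tol: float = 0.5,
) -> BadChannelReport:
    """Flag flat, high-amplitude and line-noise-dominated channels.

    flat: variance < flat_tol (uV^2); high_amplitude: 99th percentile of |x|
    exceeds amp_tol times the cross-channel median of that percentile;
    line_noise: power within 2 Hz of 60 Hz exceeds ln_tol of broadband power.
    Deterministic; thresholds are declared, configurable surrogates for a
    clinical artifact-rejection algorithm.
    """
    if rec.duration < 10.0:
        raise ValidationError("need >= 10 s of data for bad-channel detection")
    reasons: dict[str, set[str]] = {}

    var = rec.data.var(axis=-1)
    p99 = np.percentile(np.abs(rec.data), 99, axis=-1)
    med_p99 = np.median(p99[var >= flat_tol]) if (var >= flat_tol).any() else 0.0

    nper = int(min(rec.fs * 4, rec.n_samples))
    freqs, psd = welch(rec.data, fs=rec.fs, nperseg=nper, axis=-1)
    line = (freqs >= 58.0) & (freqs <= 62.0)
    broad = freqs > 0

    for i, ch in enumerate(rec.channel_names):
        r: set[str] = set()
        if var[i] < flat_tol:
            r.add("flat")
        elif med_p99 > 0 and p99[i] > amp_tol * med_p99:
            r.add("high_amplitude")
        if line.any() and psd[i, broad].sum() > 0:
            if psd[i, line].sum() / psd[i, broad].sum() > ln_tol:
                r.add("line_noise")
        if r:
            reasons[ch] = r
    return BadChannelReport(bad=set(reasons), reasons=reasons)


def rereference(
    rec: EEGRecording,
    scheme: str = "car",
    bad: BadChannelReport | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[EEGRecording, BadChannelReport]:
    """Common-average or bipolar re-referencing with bad channels excluded.

    CAR subtracts the mean of non-bad channels from every channel.  Bipolar
    returns anode-minus-cathode differences for the supplied pairs (default:
    consecutive channels); pairs touching a bad channel are retained but
    listed in ``contaminated_pairs``.
    """
    bad = bad or BadChannelReport()
    if scheme == "car":
        good = [i for i, c in enumerate(rec.channel_names) if c not in bad.bad]
        if not good:
            raise ValidationError("all channels are bad; cannot rereference")
        ref = rec.data[good].mean(axis=0)
        return rec.copy_with(data=rec.data - ref[None, :]), bad
    if scheme == "bipolar":
        if pairs is None:
            names = rec.channel_names
            pairs = [(names[i], names[i + 1]) for i in range(len(names) - 1)]
        if not pairs:
            raise ValidationError("bipolar montage requires at least one pair")
        idx = {c: i for i, c in enumerate(rec.channel_names)}
        rows, labels, contaminated = [], [], set(bad.contaminated_pairs)
        for a, b in pairs:
            if a not in idx or b not in idx:
                raise ValidationError(f"montage pair ({a}, {b}) not in channels")
            label = f"{a}-{b}"
            rows.append(rec.data[idx[a]] - rec.data[idx[b]])
            labels.append(label)
            if a in bad.bad or b in bad.bad:
                contaminated.add(label)
        report = BadChannelReport(
            bad=set(bad.bad), reasons=dict(bad.reasons), contaminated_pairs=contaminated
        )
        out = rec.copy_with(data=np.asarray(rows), channel_names=labels)
        return out, report
    raise ValidationError(f"unknown rereference scheme {scheme!r}")


def prewhiten(rec: EEGRecording, method: str = "diff") -> EEGRecording:
    """Flatten the EEG spectrum before model input.

    ``diff`` (default): per-channel first difference,
    x'[t] = x[t] - x[t-1], first sample 0.  ``ar1``: subtract an estimated
    AR(1) prediction, x'[t] = x[t] - rho x[t-1] with rho the per-channel
    lag-1 autocorrelation.
    """
    if rec.n_samples < 2:
        raise ValidationError("need >= 2 samples to prewhiten")
    if method == "diff":
        out = np.diff(rec.data, axis=-1, prepend=rec.data[:, :1])
    elif method == "ar1":
        x = rec.data
        num = (x[:, 1:] * x[:, :-1]).sum(axis=-1)
        den = (x[:, :-1] ** 2).sum(axis=-1)
        rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        out = np.empty_like(x)
        out[:, 0] = 0.0
        out[:, 1:] = x[:, 1:] - rho[:, None] * x[:, :-1]
    else:
        raise ValidationError(f"unknown prewhitening method {method!r}")
    return rec.copy_with(data=out)


@dataclass
class RobustScalerState:
    """Per-channel (median, IQR) fitted once on an early data segment."""

    median: np.ndarray
    iqr: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        iqr = np.where(self.iqr > 0, self.iqr, 1.0)
        return (x - self.median[:, None]) / iqr[:, None]


def fit_robust_scaler(rec: EEGRecording, fit_seconds: float = 600.0) -> RobustScalerState:
    """Fit median/IQR per channel on the first ``fit_seconds`` of data
    (a proxy for a non-ictal segment)."""
    n = min(rec.n_samples, int(fit_seconds * rec.fs))
    seg = rec.data[:, :n]
    q25, q50, q75 = np.percentile(seg, [25, 50, 75], axis=-1)
    return RobustScalerState(median=q50, iqr=q75 - q25)


def make_windows(
    rec: EEGRecording,
    window_length: float = 10.0,
    overlap: float = 2.0,
    fs_out: float | None = None,
    scaler: RobustScalerState | None = None,
) -> WindowBatch:
    """Cut uniform windows (stride = window_length - overlap), resampled to
    ``fs_out``; trailing partial window dropped; empty batch if too short.

    The robust scaler, when given, is applied to the resampled signal before
    windowing (statistics are fitted by the caller, once, on early data).
    """
    if not window_length > overlap >= 0:
        raise ValidationError("require window_length > overlap >= 0")
    fs_out = fs_out or rec.fs
    if fs_out > rec.fs:
        raise ValidationError("fs_out must not exceed the recording rate")
    if fs_out != rec.fs:
        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    else:
        data = rec.data
    if scaler is not None:
        data = scaler.apply(data)
    stride = window_length - overlap
    wlen = int(round(window_length * fs_out))
    step = int(round(stride * fs_out))
    n_win = 0 if data.shape[1] < wlen else (data.shape[1] - wlen) // step + 1
    windows = np.stack(
        [data[:, i * step : i * step + wlen] for i in range(n_win)], axis=0
    ) if n_win else np.empty((0, rec.n_channels, wlen))
    starts = np.arange(n_win) * stride
    return WindowBatch(
        windows=windows,
        window_start_times=starts,
        window_length=window_length,
        stride=stride,
        fs_out=fs_out,
    )
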