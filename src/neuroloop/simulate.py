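"""Synthetic EEG, probability traces, patient responses and dose logs.

The generators reproduce the statistical structure the detection and
fine-tuning pipeline assumes, without claiming physiological realism:

* background EEG is per-channel 1/f (pink) noise with a small 60 Hz
  powerline component, so notch filtering is exercised;
* ictal activity is a chirped sinusoid (ictal_freq falling to half) with a
  linear amplitude ramp, planted on a fixed fraction of channels — enough
  discriminative structure for a classifier to learn;
* patient annotation behaviour (answer rate, correctness, 'uncertain'
  fraction, lognormal latency) follows a simple response model;
* the probability-trace generator is an oracle stand-in for a pretrained
  seizure model, producing high probabilities over planted events, a low
  floor elsewhere, and optional false-positive bursts.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import chirp

from .core import (
    EEGRecording,
    ProbabilityTrace,
    SeizureEvent,
    ValidationError,
    window_overlap_mask,
)
from .biomarkers import DoseLog, DoseRecord, PKParams
from .labels import AnnotationResponse
from .model import SurrogateClassifier

FP_BURST_S = 15.0  # false-positive bursts are 15-s plateaus at p_ictal


@dataclass
class SimConfig:
    """Synthetic-recording parameters.

    Amplitudes are RMS in microvolts; ``seizure_times`` are half-open
    ``(start, end)`` intervals in seconds, sorted and non-overlapping.
    """

    n_channels: int = 4
    fs: float = 64.0
    duration: float = 3600.0
    seizure_times: list[tuple[float, float]] = field(default_factory=list)
    seizure_channel_fraction: float = 0.5
    background_amplitude: float = 20.0
    ictal_amplitude: float = 100.0
    ictal_freq: float = 6.0
    noise_seed: int = 0
    line_noise_amplitude: float = 1.0
    flat_channels: tuple[int, ...] = ()
    modality: str = "scalp"
    # intermittent rhythmic background bursts (alpha-like physiological
    # activity, no chirp or ramp); off by default
    burst_rate_per_h: float = 0.0
    burst_freq: float = 10.0
    burst_amplitude: float = 50.0
    burst_duration: float = 40.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("need at least one channel")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if not 0 < self.seizure_channel_fraction <= 1:
            raise ValidationError("seizure_channel_fraction must be in (0, 1]")
        prev_end = -math.inf
        for s, e in self.seizure_times:
            if not (0 <= s < e <= self.duration):
                raise ValidationError(f"seizure ({s}, {e}) outside [0, {self.duration})")
            if s < prev_end:
                raise ValidationError("seizure intervals must be sorted, non-overlapping")
            prev_end = e


@dataclass
class ResponseModel:
    """Patient annotation behaviour.

    ``response_rate`` is the probability an alert is answered at all;
    answered alerts are 'uncertain' with probability ``uncertain_rate``,
    otherwise 'yes' iff the event overlaps a true seizure and a
    Bernoulli(``correct_rate``) draw succeeds, else 'no'.  Latencies are
    lognormal, parameterised by the median and geometric sd in minutes.
    """

    response_rate: float = 0.706
    correct_rate: float = 0.9
    uncertain_rate: float = 0.1
    latency_median_min: float = 10.0
    latency_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("response_rate", "correct_rate", "uncertain_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be a probability, got {v}")


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-power noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0 / n))
    spec = amp * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x**2))


def simulate_eeg(config: SimConfig) -> tuple[EEGRecording, list[SeizureEvent]]:
    """Generate a synthetic recording plus its ground-truth seizure events."""
    rng = np.random.default_rng(config.noise_seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        data[c] = config.background_amplitude * _pink_noise(rng, n, config.fs)
    if config.line_noise_amplitude > 0 and config.fs > 120:
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
        data += config.line_noise_amplitude * np.sqrt(2.0) * np.sin(
            2 * np.pi * 60.0 * t[None, :] + phases[:, None]
        )
    if config.burst_rate_per_h > 0:
        n_bursts = rng.poisson(config.burst_rate_per_h * config.duration / 3600.0)
        blen = int(round(config.burst_duration * config.fs))
        for _ in range(n_bursts):
            start = rng.uniform(0.0, config.duration - config.burst_duration)
            # keep rhythmic bursts clear of planted seizures
            if any(
                start < e + config.burst_duration and s - config.burst_duration < start
                for s, e in config.seizure_times
            ):
                continue
            i0 = int(round(start * config.fs))
            tt = np.arange(blen) / config.fs
            env = np.sin(np.pi * tt / config.burst_duration) ** 2  # Hann-like
            wave = np.sin(2 * np.pi * config.burst_freq * tt + rng.uniform(0, 2 * np.pi))
            gains = rng.uniform(0.5, 1.0, size=config.n_channels)
            data[:, i0 : i0 + blen] += (
                config.burst_amplitude * np.sqrt(2.0) * gains[:, None] * (env * wave)[None, :]
            )
    n_ictal = math.ceil(config.seizure_channel_fraction * config.n_channels)
    for s, e in config.seizure_times:
        i0, i1 = int(round(s * config.fs)), int(round(e * config.fs))
        dur = (i1 - i0) / config.fs
        tt = np.arange(i1 - i0) / config.fs
        wave = chirp(tt, f0=config.ictal_freq, t1=dur, f1=config.ictal_freq / 2.0)
        ramp = tt / dur  # linear amplitude ramp over the event
        seg = config.ictal_amplitude * np.sqrt(2.0) * ramp * wave
        gains = rng.uniform(0.9, 1.1, size=n_ictal)
        data[:n_ictal, i0:i1] += gains[:, None] * seg[None, :]
    for c in config.flat_channels:
        data[c] = 0.0
    rec = EEGRecording(
        data=data,
        channel_names=[f"ch{i:02d}" for i in range(config.n_channels)],
        fs=config.fs,
        modality=config.modality,  # type: ignore[arg-type]
    )
    truth = [SeizureEvent(s, e, source="ground_truth") for s, e in config.seizure_times]
    return rec, truth


def simulate_probability_trace(
    events: list[SeizureEvent],
    window_start_times: np.ndarray,
    stride: float,
    p_ictal: float,
    p_background: float,
    jitter_sd: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    deterministic_fp_spacing: bool = False,
) -> ProbabilityTrace:
    """Oracle probability trace over a window grid.

    Windows overlapping a true event get mean probability ``p_ictal``, all
    others ``p_background``, with Gaussian jitter clipped to [0, 1].
    Spurious 15-s plateaus at ``p_ictal`` are injected at ``fp_rate``
    bursts/hour — Poisson-counted with uniform placement by default, or
    exactly ``round(rate x hours)`` evenly spaced bursts in deterministic
    mode (for exact tests).
    """
    if not 0 <= p_background < p_ictal <= 1:
        raise ValidationError("require 0 <= p_background < p_ictal <= 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(window_start_times, dtype=np.float64)
    p = np.full(grid.shape[0], p_background)
    p[window_overlap_mask(grid, stride, events)] = p_ictal

    if fp_rate > 0 and grid.size:
        duration = grid[-1] + stride - grid[0]
        hours = duration / 3600.0
        if deterministic_fp_spacing:
            n_bursts = int(round(fp_rate * hours))
            centers = grid[0] + (np.arange(n_bursts) + 0.5) * duration / max(n_bursts, 1)
        else:
            n_bursts = rng.poisson(fp_rate * hours)
            centers = rng.uniform(grid[0], grid[0] + duration, size=n_bursts)
        for c in np.sort(centers):
            burst = SeizureEvent(c - FP_BURST_S / 2, c + FP_BURST_S / 2, source="model")
            p[window_overlap_mask(grid, stride, [burst])] = p_ictal

    if jitter_sd > 0:
        p = p + rng.normal(0.0, jitter_sd, size=p.shape)
    return ProbabilityTrace(p=np.clip(p, 0.0, 1.0), window_start_times=grid, stride=stride)


def simulate_responses(
    detected: list[SeizureEvent],
    truth: list[SeizureEvent],
    model: ResponseModel,
) -> list[AnnotationResponse]:
    """Imperfect patient answers to detected events.

    Unanswered events produce no record at all.  Response times are the
    event end plus a lognormal latency.
    """
    rng = np.random.default_rng(model.seed)
    out: list[AnnotationResponse] = []
    for i, ev in enumerate(detected):
        if rng.random() >= model.response_rate:
            continue
        latency_min = float(
            np.exp(rng.normal(np.log(model.latency_median_min), model.latency_sigma))
        )
        if rng.random() < model.uncertain_rate:
            answer = "uncertain"
        else:
            overlaps = any(ev.overlaps(tr) for tr in truth)
            answer = "yes" if (overlaps and rng.random() < model.correct_rate) else "no"
        out.append(
            AnnotationResponse(
                event_ref=i, response=answer, response_time=ev.end + 60.0 * latency_min
            )
        )
    return out


def simulate_dose_log(
    drugs: list[tuple[str, float, float]],
    schedule: list[float],
    duration_h: float,
) -> tuple[DoseLog, dict[str, PKParams]]:
    """Dose log applying each (name, dose_mg, half_life_h) drug at each
    scheduled time (hours), restricted to [0, duration_h].  Also returns the
    matching per-drug PK parameters (unit scale)."""
    params: dict[str, PKParams] = {}
    records: list[DoseRecord] = []
    for name, dose, t_half in drugs:
        if dose < 0:
            raise ValidationError(f"negative dose for {name}")
        params[name] = PKParams(half_life_h=t_half)
    for t in schedule:
        if not 0 <= t <= duration_h:
            continue
        for name, dose, _ in drugs:
            records.append(DoseRecord(drug=name, dose_mg=dose, time_h=t))
    return DoseLog(records=records), params


def make_surrogate_model(
    architecture_seed: int,
    n_channels: int,
    window_samples: int,
    per_channel: bool = False,
) -> SurrogateClassifier:
    """Fresh (untrained) surrogate classifier satisfying the ModelHandle
    contract; stands in for a pretrained seizure-detection network."""
    return SurrogateClassifier(
        n_channels=n_channels,
        window_samples=window_samples,
        seed=architecture_seed,
        per_channel=per_channel,
    )


def surrogate_training_set(
    n_per_class: int,
    n_channels: int,
    window_samples: int,
    fs: float,
    seed: int = 0,
    background_amplitude: float = 20.0,
    ictal_amplitude: float = 100.0,
    ictal_freq: float = 6.0,
    seizure_channel_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled windows for surrogate (pre)training.

    Background windows are pink noise; ictal windows add the chirp-with-ramp
    ictal morphology at a random phase of its ramp, matching simulate_eeg's
    event structure.  Returns (X: n x channels x samples, y: n).
    """
    rng = np.random.default_rng(seed)
    n_ictal_ch = math.ceil(seizure_channel_fraction * n_channels)
    tt = np.arange(window_samples) / fs
    X = np.empty((2 * n_per_class, n_channels, window_samples))
    y = np.zeros(2 * n_per_class)
    for i in range(2 * n_per_class):
        for c in range(n_channels):
            X[i, c] = background_amplitude * _pink_noise(rng, window_samples, fs)
        if i >= n_per_class:
            y[i] = 1.0
            # random position within a nominal 60-s seizure's ramp
            frac = rng.uniform(0.2, 1.0)
            f0 = ictal_freq * (1 - frac / 2)  # instantaneous freq partway down the chirp
            wave = chirp(tt, f0=f0, t1=tt[-1] + 1 / fs, f1=f0 * 0.95,
                         phi=rng.uniform(0.0, 360.0))
            gains = rng.uniform(0.9, 1.1, size=n_ictal_ch)
            X[i, :n_ictal_ch] += (
                ictal_amplitude * np.sqrt(2.0) * frac * gains[:, None] * wave[None, :]
            )
    perm = rng.permutation(2 * n_per_class)
    return X[perm], y[perm]
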