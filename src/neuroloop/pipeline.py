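"""EMU-stay replay harness.

Replays an epilepsy-monitoring-unit stay against a deployed classifier:
every three hours the model's own detections over the elapsed block are
annotated (simulated patient responses, push-button alarms, or an oracle
clinician), gated, and — when the gate passes — fine-tuned; each resulting
checkpoint is evaluated on all data strictly after its boundary against the
baseline on the same span.  Daily clinician active-learning updates can be
interleaved.  A prospective pass composes the deployed checkpoints over
time, emulating live deployment, and is compared with the baseline over the
full stay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .active_learning import (
    clinician_update,
    label_segments_from_truth,
    least_confidence_select,
)
from .core import (
    EEGRecording,
    LabelSeries,
    ProbabilityTrace,
    SeizureEvent,
    ValidationError,
    WindowBatch,
)
from .detect import DetectorConfig, detect_events
from .evaluate import EvalResult, canonicalize_events, sample_auc, score_events
from .finetune import FineTuneConfig, pretrain, run_finetune_session, session_gate, stratified_split
from .labels import labels_from_truth, pushbutton_to_events, responses_to_labels
from .model import SurrogateClassifier
from .preprocess import make_windows
from .simulate import (
    ResponseModel,
    SimConfig,
    make_surrogate_model,
    simulate_eeg,
    simulate_responses,
    surrogate_training_set,
)

LABEL_SOURCES = ("push_button", "patient_responses", "clinician")


@dataclass
class StayConfig:
    """Replay schedule and labelling policy for one synthetic EMU stay."""

    stay_duration_h: float = 12.0
    session_interval_h: float = 3.0
    clinician_interval_h: float = 24.0
    label_source: str = "patient_responses"
    response_model: ResponseModel = field(default_factory=ResponseModel)
    detector: DetectorConfig = field(default_factory=DetectorConfig.scalp)
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    window_length: float = 10.0
    overlap: float = 2.0
    fs_out: float = 32.0
    clinician_loop: bool = False

    def __post_init__(self) -> None:
        if self.label_source not in LABEL_SOURCES:
            raise ValidationError(f"unknown label source {self.label_source!r}")
        ratio = self.clinician_interval_h / self.session_interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("session interval must divide clinician interval")


def predict_trace(
    model: SurrogateClassifier, windows: WindowBatch, batch: int = 512
) -> ProbabilityTrace:
    """Model probabilities over a window batch as a ProbabilityTrace."""
    probs = []
    for b0 in range(0, windows.n_windows, batch):
        probs.append(model.predict(windows.windows[b0 : b0 + batch]))
    p = np.concatenate(probs) if probs else np.empty(0)
    if p.ndim == 2:  # per-channel model -> channels x windows
        p = p.T
    return ProbabilityTrace(
        p=p, window_start_times=windows.window_start_times, stride=windows.stride
    )


def _slice_windows(windows: WindowBatch, t0: float, t1: float) -> tuple[WindowBatch, np.ndarray]:
    sel = (windows.window_start_times >= t0) & (windows.window_start_times < t1)
    sub = WindowBatch(
        windows=windows.windows[sel],
        window_start_times=windows.window_start_times[sel],
        window_length=windows.window_length,
        stride=windows.stride,
        fs_out=windows.fs_out,
    )
    return sub, np.flatnonzero(sel)


def _truth_in_span(truth: list[SeizureEvent], t0: float, t1: float) -> list[SeizureEvent]:
    out = []
    for ev in truth:
        if ev.start < t1 and ev.end > t0:
            out.append(SeizureEvent(max(ev.start, t0), min(ev.end, t1), source=ev.source))
    return out


def evaluate_span(
    model: SurrogateClassifier,
    windows: WindowBatch,
    truth: list[SeizureEvent],
    t0: float,
    t1: float,
    detector: DetectorConfig,
) -> EvalResult:
    """Detect with ``model`` on [t0, t1) and score against ground truth."""
    sub, _ = _slice_windows(windows, t0, t1)
    if sub.n_windows == 0:
        return EvalResult(duration_h=(t1 - t0) / 3600.0)
    trace = predict_trace(model, sub)
    pred = canonicalize_events(detect_events(trace, detector))
    ref = canonicalize_events(_truth_in_span(truth, t0, t1))
    res = score_events(pred, ref, duration_h=(t1 - t0) / 3600.0)
    y = labels_from_truth(truth, sub.window_start_times, sub.stride)
    res.auroc, res.auprc = sample_auc(trace.scalar(), y.labels)
    return res


def _session_labels(
    cfg: StayConfig,
    detected: list[SeizureEvent],
    truth: list[SeizureEvent],
    grid: np.ndarray,
    stride: float,
    seed: int,
    probabilities: np.ndarray | None = None,
) -> LabelSeries:
    if cfg.label_source == "patient_responses":
        rm = ResponseModel(**{**cfg.response_model.__dict__, "seed": seed})
        responses = simulate_responses(detected, truth, rm)
        return responses_to_labels(
            detected, responses, grid, stride, probabilities=probabilities
        )
    if cfg.label_source == "push_button":
        rng = np.random.default_rng(seed)
        alarms = [
            ev.start + 5.0
            for ev in truth
            if grid.size and grid[0] <= ev.start < grid[-1] + stride
            and rng.random() < cfg.response_model.response_rate
        ]
        events = pushbutton_to_events(alarms)
        return labels_from_truth(events, grid, stride)
    return labels_from_truth(truth, grid, stride)  # oracle clinician labels


def replay_stay(
    baseline: SurrogateClassifier,
    cfg: StayConfig,
    sim_config: SimConfig | None = None,
    recording: EEGRecording | None = None,
    truth: list[SeizureEvent] | None = None,
    seed: int = 0,
) -> dict:
    """Replay one stay; returns the stay report.

    Provide either ``sim_config`` (a synthetic stay is generated with
    ``noise_seed`` derived from ``seed``) or an explicit ``recording`` with
    its ground-truth ``truth`` events — not both.
    """
    if (sim_config is None) == (recording is None):
        raise ValidationError("provide exactly one of sim_config or recording")
    if sim_config is not None:
        sim = SimConfig(**{**sim_config.__dict__, "noise_seed": seed,
                           "duration": cfg.stay_duration_h * 3600.0})
        recording, truth = simulate_eeg(sim)
    if truth is None:
        raise ValidationError("recording requires ground-truth events")

    windows = make_windows(
        recording, cfg.window_length, cfg.overlap, fs_out=cfg.fs_out
    )
    stay_end = cfg.stay_duration_h * 3600.0
    session_s = cfg.session_interval_h * 3600.0
    n_sessions = int(stay_end // session_s)

    deployed = baseline.clone()
    checkpoints: list[tuple[float, SurrogateClassifier]] = [(0.0, baseline)]
    iterations: list[dict] = []
    audit: list[dict] = []

    for k in range(1, n_sessions + 1):
        b = k * session_s
        t0 = b - session_s
        block, _ = _slice_windows(windows, t0, b)
        if block.n_windows == 0:
            continue
        trace = predict_trace(deployed, block)
        detected = detect_events(trace, cfg.detector)
        labels = _session_labels(
            cfg, detected, truth, block.window_start_times, block.stride,
            seed=(seed * 131 + k) % (2**31 - 1),
            probabilities=trace.scalar(),
        )
        # deployed model's AUROC on the session's validation split drives the gate
        val_auroc = None
        try:
            _, val_idx = stratified_split(labels, cfg.finetune.split_ratio)
            if val_idx.size:
                val_auroc, _ = sample_auc(trace.scalar()[val_idx], labels.labels[val_idx])
        except ValidationError:
            pass
        gate = session_gate(len(detected), labels, val_auroc, cfg.finetune)
        record = {
            "boundary_h": b / 3600.0,
            "n_detected": len(detected),
            "gate": gate,
            "baseline_val_auroc": val_auroc,
        }
        if gate == "proceed":
            res = run_finetune_session(
                deployed, block, labels, cfg.finetune,
                seed=(seed * 977 + k) % (2**31 - 1),
                reference=baseline,
            )
            record["status"] = res.status
            if res.status == "trained" and b < stay_end:
                ckpt = res.best_checkpoint
                record["eval_finetuned"] = evaluate_span(
                    ckpt, windows, truth, b, stay_end, cfg.detector
                ).to_dict()
                record["eval_baseline"] = evaluate_span(
                    baseline, windows, truth, b, stay_end, cfg.detector
                ).to_dict()
                audit.append({"train_span": [t0, b], "eval_span": [b, stay_end]})
                deployed = ckpt
                checkpoints.append((b, deployed))
        else:
            record["status"] = gate
        iterations.append(record)

        if cfg.clinician_loop and (b / 3600.0) % cfg.clinician_interval_h == 0:
            day_block, _ = _slice_windows(windows, b - cfg.clinician_interval_h * 3600.0, b)
            if day_block.n_windows:
                day_trace = predict_trace(deployed, day_block)
                batch = least_confidence_select(day_trace)
                batch = label_segments_from_truth(batch, truth)
                deployed = clinician_update(
                    deployed, batch, day_block, cfg.finetune,
                    seed=(seed * 499 + k) % (2**31 - 1),
                )
                checkpoints.append((b, deployed))

    # ---- full-stay comparison: baseline vs prospective deployment ----
    baseline_full = evaluate_span(baseline, windows, truth, 0.0, stay_end, cfg.detector)
    pros_events: list[SeizureEvent] = []
    for i, (t_start, model) in enumerate(checkpoints):
        t_stop = checkpoints[i + 1][0] if i + 1 < len(checkpoints) else stay_end
        if t_stop <= t_start:
            continue
        seg, _ = _slice_windows(windows, t_start, t_stop)
        if seg.n_windows == 0:
            continue
        pros_events.extend(detect_events(predict_trace(model, seg), cfg.detector))
    prospective_full = score_events(
        canonicalize_events(pros_events),
        canonicalize_events(list(truth)),
        duration_h=stay_end / 3600.0,
    )

    deltas = {"false_alarms_per_hour": [], "event_sensitivity": []}
    for it in iterations:
        if "eval_finetuned" not in it:
            continue
        for m in deltas:
            vf, vb = it["eval_finetuned"][m], it["eval_baseline"][m]
            if vf is not None and vb is not None:
                deltas[m].append(vf - vb)
    median_deltas = {
        m: (float(np.median(v)) if v else None) for m, v in deltas.items()
    }

    return {
        "seed": seed,
        "n_sessions": n_sessions,
        "n_trained": sum(1 for it in iterations if it.get("status") == "trained"),
        "iterations": iterations,
        "baseline_full": baseline_full.to_dict(),
        "prospective_full": prospective_full.to_dict(),
        "median_deltas": median_deltas,
        "leakage_audit": audit,
    }


def make_baseline(
    n_channels: int = 4,
    window_samples: int = 320,
    fs_out: float = 32.0,
    seed: int = 0,
    n_per_class: int = 100,
    epochs: int = 20,
    lr: float = 1e-3,
    ictal_amplitude: float = 100.0,
    background_amplitude: float = 20.0,
    ictal_freq: float = 6.0,
) -> SurrogateClassifier:
    """Pretrain a surrogate baseline on labelled synthetic windows.

    The pretraining distribution contains only pink-noise background and
    ictal chirps — never the rhythmic background bursts a deployment stay
    can contain — so the deployed baseline systematically confuses such
    bursts with seizures.  That domain shift (a model meeting activity it
    was not trained on) is the regime the human-in-the-loop fine-tuning
    protocol is designed for.
    """
    model = make_surrogate_model(seed, n_channels, window_samples)
    x, y = surrogate_training_set(
        n_per_class, n_channels, window_samples, fs_out, seed=seed + 1,
        ictal_amplitude=ictal_amplitude, background_amplitude=background_amplitude,
        ictal_freq=ictal_freq,
    )
    pretrain(model, x, y, epochs=epochs, lr=lr, seed=seed + 2)
    return model


def emu_study_conditions() -> tuple[SimConfig, StayConfig]:
    """Canonical synthetic EMU-stay conditions for the fine-tuning replay.

    One 24-hour stay: twelve 3-minute seizures (one every two hours,
    6->3 Hz chirp at 180 uV RMS on half the channels) over pink-noise
    background with seven 9-Hz rhythmic background bursts per hour — the
    activity class the pretrained baseline has never seen, and therefore
    the source of its false alarms.  Patients answer 70% of alerts.  The
    session optimizer runs at a rate suited to the small surrogate with a
    fixed trainable subset (stem + head).
    """
    sim = SimConfig(
        n_channels=4,
        fs=64.0,
        duration=24 * 3600.0,
        seizure_times=[(7200.0 * h + 900.0, 7200.0 * h + 1080.0) for h in range(12)],
        seizure_channel_fraction=0.5,
        background_amplitude=20.0,
        ictal_amplitude=180.0,
        ictal_freq=6.0,
        burst_rate_per_h=7.0,
        burst_freq=9.0,
        burst_amplitude=50.0,
        burst_duration=60.0,
    )
    stay = StayConfig(
        stay_duration_h=24.0,
        response_model=ResponseModel(response_rate=0.7),
        finetune=FineTuneConfig(learning_rate=1e-4, unfreeze_order=()),
    )
    return sim, stay
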