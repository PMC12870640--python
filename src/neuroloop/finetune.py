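"""Patient-in-the-loop fine-tuning sessions.

Every three hours the deployed classifier is fine-tuned on weak labels
derived from patient annotations of its own detections.  A session consists
of: gating (skip when there is nothing to learn from or when validation
AUROC indicates near-perfect performance or unusable labels), a stratified
temporal 85:15 split, inverse-frequency weighted sampling over
TP/FP/FN/TN categories, optional left-right channel-flip augmentation,
a task loss (binary cross-entropy, with top-k pooling of per-channel
probabilities in the intracranial path, or a KL loss over a class
distribution in the multiclass path) plus a knowledge-distillation penalty
KL(reference || current) weighted by lambda = 0.5 that anchors the model to
its pre-session predictions, progressive layer unfreezing, checkpoint
selection, and early stopping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LabelSeries, ValidationError, WindowBatch
from .evaluate import sample_auc
from .model import AdamW, SurrogateClassifier

_EPS = 1e-12


@dataclass
class FineTuneConfig:
    split_ratio: float = 0.85
    skip_auroc_high: float = 0.98
    skip_auroc_low: float = 0.5
    learning_rate: float = 5e-6
    weight_decay: float = 1e-3
    distill_weight: float = 0.5
    topk_fraction: float = 0.10
    max_epochs: int = 20
    patience: int = 3  # scalp-style; the intracranial analogue uses 10
    unfreeze_patience: int = 2
    stop_metric_high: float = 0.98
    batch_size: int = 64
    min_delta: float = 1e-3  # smallest val-loss drop that counts as improvement
    channel_flip_augmentation: bool = True
    initial_trainable: tuple[str, ...] = ("stem", "head")
    unfreeze_order: tuple[str, ...] = ("block2", "block1")

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValidationError("split_ratio must be in (0, 1)")
        if self.distill_weight < 0:
            raise ValidationError("distill_weight must be >= 0")
        if not 0 < self.topk_fraction <= 1:
            raise ValidationError("topk_fraction must be in (0, 1]")


@dataclass
class SessionResult:
    status: str  # trained | skipped_no_events | skipped_no_labels | skipped_auroc_high | skipped_auroc_low
    best_checkpoint: SurrogateClassifier | None = None
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == "trained") != (self.best_checkpoint is not None):
            raise ValidationError("best_checkpoint present iff status == 'trained'")


# ------------------------------------------------------------------ split


def stratified_split(
    labels: LabelSeries, ratio: float = 0.85
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified temporal split of non-NaN samples.

    Within each class the chronologically first floor(ratio * n) samples go
    to training (at least one when the class is present), the rest to
    validation.  Returns (train_idx, val_idx) as indices into the full grid.
    """
    y = labels.labels
    valid = np.flatnonzero(~np.isnan(y))
    if valid.size == 0:
        raise ValidationError("no valid labels")
    train, val = [], []
    for cls in (0.0, 1.0):
        idx = valid[y[valid] == cls]
        if idx.size == 0:
            continue
        n_train = max(1, math.floor(ratio * idx.size)) if idx.size else 0
        train.extend(idx[:n_train])
        val.extend(idx[n_train:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(val, dtype=int))


def session_gate(
    n_events: int,
    labels: LabelSeries,
    val_auroc_baseline: float | None,
    cfg: FineTuneConfig,
) -> str:
    """Decide whether a 3-hour session should train.

    Returns 'proceed' or a skip reason.  Sessions with no detected events,
    or where every detected event lacks a usable annotation, are skipped;
    likewise when the deployed model's validation AUROC is already above
    skip_auroc_high (nothing to gain) or below skip_auroc_low (labels
    probably inconsistent).  An undefined AUROC (single-class validation
    split) does not block training.
    """
    if n_events == 0:
        return "skipped_no_events"
    if not np.any(~np.isnan(labels.labels)):
        return "skipped_no_labels"
    if val_auroc_baseline is not None:
        if val_auroc_baseline > cfg.skip_auroc_high:
            return "skipped_auroc_high"
        if val_auroc_baseline < cfg.skip_auroc_low:
            return "skipped_auroc_low"
    return "proceed"


# ------------------------------------------------------------------ pooling


def topk_pool(channel_probs: np.ndarray, fraction: float = 0.10) -> np.ndarray | float:
    """Mean of the k largest channel probabilities, k = max(1, ceil(f*C)).

    Accepts a (C,) vector or an (N, C) batch; gradient flows only to the
    selected channels (see ``topk_pool_vjp``).
    """
    p = np.asarray(channel_probs, dtype=np.float64)
    squeeze = p.ndim == 1
    if squeeze:
        p = p[None, :]
    if p.shape[1] == 0:
        raise ValidationError("topk_pool requires at least one channel")
    k = max(1, math.ceil(fraction * p.shape[1]))
    top = np.sort(p, axis=1)[:, -k:]
    pooled = top.mean(axis=1)
    return float(pooled[0]) if squeeze else pooled


def topk_pool_vjp(channel_probs: np.ndarray, fraction: float, gy: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of topk_pool: routes gy/k to the k selected
    channels of each row (ties broken toward lower channel index, matching
    a stable descending sort)."""
    p = np.asarray(channel_probs, dtype=np.float64)
    k = max(1, math.ceil(fraction * p.shape[1]))
    order = np.argsort(-p, axis=1, kind="stable")[:, :k]
    g = np.zeros_like(p)
    rows = np.repeat(np.arange(p.shape[0]), k)
    g[rows, order.ravel()] = np.repeat(np.asarray(gy) / k, k)
    return g


# ------------------------------------------------------------------- losses


def _bernoulli_kl(r: np.ndarray, q: np.ndarray) -> np.ndarray:
    r = np.clip(r, _EPS, 1 - _EPS)
    q = np.clip(q, _EPS, 1 - _EPS)
    return r * np.log(r / q) + (1 - r) * np.log((1 - r) / (1 - q))


def _bce(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    q = np.clip(q, _EPS, 1 - _EPS)
    return -(y * np.log(q) + (1 - y) * np.log(1 - q))


def session_loss(
    predictions: np.ndarray,
    labels: np.ndarray,
    reference_predictions: np.ndarray,
    mode: str = "binary_topk",
    distill_weight: float = 0.5,
    topk_fraction: float = 0.10,
    detection_class: int = 1,
    background_class: int = 0,
) -> float:
    """Batch-mean session loss: task loss + lambda * KL(reference || current).

    binary_topk: predictions are per-channel probabilities (N, C) — or
    already-pooled scalars (N,) — pooled by top-k; task = BCE(label, pooled).
    multiclass_kl: predictions are class distributions (N, K); the target is
    one-hot on the detection class for label 1 and on the background class
    for label 0; task = KL(target || predicted); distillation is the
    categorical KL of reference vs current distributions.
    """
    y = np.asarray(labels, dtype=np.float64)
    if np.isnan(y).any():
        raise ValidationError("NaN-labelled samples must not reach the loss")
    p = np.asarray(predictions, dtype=np.float64)
    r = np.asarray(reference_predictions, dtype=np.float64)
    if mode == "binary_topk":
        pooled = topk_pool(p, topk_fraction) if p.ndim == 2 else p
        pooled_ref = topk_pool(r, topk_fraction) if r.ndim == 2 else r
        task = _bce(y, np.asarray(pooled))
        distill = _bernoulli_kl(np.asarray(pooled_ref), np.asarray(pooled))
        return float(np.mean(task + distill_weight * distill))
    if mode == "multiclass_kl":
        if p.ndim != 2:
            raise ValidationError("multiclass mode needs (N, K) distributions")
        pc = np.clip(p, _EPS, 1.0)
        target_cls = np.where(y == 1.0, detection_class, background_class).astype(int)
        task = -np.log(pc[np.arange(len(y)), target_cls])  # KL(one-hot || p)
        rc = np.clip(r, _EPS, 1.0)
        distill = np.sum(rc * np.log(rc / pc), axis=1)
        return float(np.mean(task + distill_weight * distill))
    raise ValidationError(f"unknown loss mode {mode!r}")


# ----------------------------------------------------------------- training


def _categories(y: np.ndarray, baseline_p: np.ndarray, thresh: float = 0.5) -> np.ndarray:
    """TP/FP/FN/TN category of each sample w.r.t. baseline predictions."""
    pred = baseline_p >= thresh
    cat = np.empty(y.shape[0], dtype="<U2")
    cat[(y == 1) & pred] = "TP"
    cat[(y == 0) & pred] = "FP"
    cat[(y == 1) & ~pred] = "FN"
    cat[(y == 0) & ~pred] = "TN"
    return cat


def _sample_weights(cat: np.ndarray) -> np.ndarray:
    w = np.empty(cat.shape[0])
    for c in np.unique(cat):
        sel = cat == c
        w[sel] = 1.0 / sel.sum()
    return w / w.sum()


def _pooled_probs(model: SurrogateClassifier, x: np.ndarray, frac: float) -> np.ndarray:
    p = model.predict(x)
    return topk_pool(p, frac) if p.ndim == 2 else p


def _grad_step(
    model: SurrogateClassifier,
    opt: AdamW,
    xb: np.ndarray,
    yb: np.ndarray,
    rb: np.ndarray,
    lam: float,
    frac: float,
) -> None:
    """One optimizer step of BCE + lambda*KL(ref || cur) on a batch.

    Both terms have the same logit gradient form (q - target), so the
    backward pass uses dL/dz = [(q - y) + lambda (q - r)] / N; in
    per-channel mode the gradient is routed through the top-k pooling.
    """
    x = model._check_batch(xb)
    logits, cache = model.forward(x)
    n = yb.shape[0]
    if model.per_channel:
        q_ch = 1.0 / (1.0 + np.exp(-logits.reshape(n, -1)))
        pooled = np.asarray(topk_pool(q_ch, frac))
        pooled_c = np.clip(pooled, _EPS, 1 - _EPS)
        dpooled = ((pooled - yb) + lam * (pooled - rb)) / (pooled_c * (1 - pooled_c)) / n
        dq = topk_pool_vjp(q_ch, frac, dpooled)
        dz = (dq * q_ch * (1 - q_ch)).ravel()
    else:
        q = 1.0 / (1.0 + np.exp(-logits))
        dz = ((q - yb) + lam * (q - rb)) / n
    grads = model.backward(cache, dz)
    opt.step(grads)


def run_finetune_session(
    model: SurrogateClassifier,
    windows: WindowBatch,
    labels: LabelSeries,
    cfg: FineTuneConfig | None = None,
    seed: int = 0,
    reference: SurrogateClassifier | None = None,
) -> SessionResult:
    """Fine-tune ``model`` on one session's windows and weak labels.

    The caller is responsible for gating (``session_gate``); this routine
    splits, trains and selects the best checkpoint.  The input model is not
    mutated; the returned checkpoint is a fine-tuned clone.

    ``reference`` is the frozen model whose predictions anchor the
    distillation term.  It defaults to the pre-session model; in sequential
    deployment pass the original (never-fine-tuned) baseline instead, so
    that the anchor does not drift with each session — otherwise repeated
    negative-heavy sessions compound suppression geometrically.
    """
    cfg = cfg or FineTuneConfig()
    if windows.n_windows != labels.labels.shape[0]:
        raise ValidationError("windows and labels length mismatch")
    try:
        train_idx, val_idx = stratified_split(labels, cfg.split_ratio)
    except ValidationError:
        return SessionResult(status="skipped_no_labels")
    if val_idx.size == 0:
        return SessionResult(status="skipped_no_labels")

    rng = np.random.default_rng(seed)
    lam, frac = cfg.distill_weight, cfg.topk_fraction
    x_train = windows.windows[train_idx]
    y_train = labels.labels[train_idx]
    x_val = windows.windows[val_idx]
    y_val = labels.labels[val_idx]

    reference = reference.clone() if reference is not None else model.clone()
    ref_train = _pooled_probs(reference, x_train, frac)
    ref_val = _pooled_probs(reference, x_val, frac)

    cat = _categories(y_train, ref_train)
    if cfg.channel_flip_augmentation and not model.per_channel:
        x_train = np.concatenate([x_train, x_train[:, ::-1, :]])
        y_train = np.concatenate([y_train, y_train])
        ref_train = np.concatenate([ref_train, ref_train])
        cat = np.concatenate([cat, cat])
    weights = _sample_weights(cat)

    student = model.clone()
    student.set_trainable({g: (g in cfg.initial_trainable) for g in student.layer_groups})
    opt = AdamW(student, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    def val_metrics(m: SurrogateClassifier) -> tuple[float, float | None, float | None]:
        pv = _pooled_probs(m, x_val, frac)
        loss = float(np.mean(_bce(y_val, pv) + lam * _bernoulli_kl(ref_val, pv)))
        auroc, auprc = sample_auc(pv, y_val)
        return loss, auroc, auprc

    best_loss, best_auroc, best_auprc = val_metrics(student)
    best = student.clone()
    history = [
        {"epoch": 0, "val_loss": best_loss, "val_auroc": best_auroc, "val_auprc": best_auprc}
    ]
    epochs_since_ckpt = 0
    epochs_since_loss_improve = 0
    unfreeze_queue = list(cfg.unfreeze_order)

    n = x_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.choice(n, size=n, replace=True, p=weights)
        for b0 in range(0, n, cfg.batch_size):
            sel = order[b0 : b0 + cfg.batch_size]
            _grad_step(student, opt, x_train[sel], y_train[sel], ref_train[sel], lam, frac)

        loss, auroc, auprc = val_metrics(student)
        improved_loss = loss < best_loss - cfg.min_delta
        improved_both = (
            auroc is not None and best_auroc is not None and auprc is not None
            and best_auprc is not None and auroc > best_auroc and auprc > best_auprc
        )
        history.append(
            {"epoch": epoch, "val_loss": loss, "val_auroc": auroc, "val_auprc": auprc}
        )
        if improved_loss or improved_both:
            best = student.clone()
            best_loss = min(best_loss, loss)
            if auroc is not None:
                best_auroc = auroc if best_auroc is None else max(best_auroc, auroc)
            if auprc is not None:
                best_auprc = auprc if best_auprc is None else max(best_auprc, auprc)
            epochs_since_ckpt = 0
        else:
            epochs_since_ckpt += 1

        if improved_loss:
            epochs_since_loss_improve = 0
        else:
            epochs_since_loss_improve += 1
            if epochs_since_loss_improve >= cfg.unfreeze_patience and unfreeze_queue:
                student.unfreeze(unfreeze_queue.pop(0))
                epochs_since_loss_improve = 0

        if (auroc is not None and auroc > cfg.stop_metric_high) or (
            auprc is not None and auprc > cfg.stop_metric_high
        ):
            break
        if epochs_since_ckpt >= cfg.patience:
            break

    best.unfreeze()  # deployed models are returned with all groups trainable
    return SessionResult(status="trained", best_checkpoint=best, history=history)


def pretrain(
    model: SurrogateClassifier,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int = 10,
    lr: float = 1e-3,
    weight_decay: float = 0.0,
    batch_size: int = 32,
    seed: int = 0,
) -> list[float]:
    """Plain BCE training of the surrogate (all groups trainable).

    Used to build baseline models from synthetic labelled windows; returns
    the per-epoch mean training loss.
    """
    rng = np.random.default_rng(seed)
    opt = AdamW(model, lr=lr, weight_decay=weight_decay)
    model.unfreeze()
    n = x.shape[0]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, batch_size):
            sel = order[b0 : b0 + batch_size]
            _grad_step(model, opt, x[sel], y[sel], y[sel] * 0.0, 0.0, 1.0)
        p = _pooled_probs(model, x, 1.0)
        losses.append(float(np.mean(_bce(y, p))))
    return losses
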