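"""Small trainable 1-D convolutional seizure classifier.

This is a self-contained numpy implementation (forward + manual backprop +
AdamW) of a window classifier satisfying the ``ModelHandle`` contract used by
the fine-tuning machinery:

* ``predict`` maps a batch of EEG windows to seizure probabilities;
* parameters are organised into ordered named layer groups
  (``stem`` -> ``block1`` -> ``block2`` -> ``head``) that can be frozen and
  unfrozen independently, enabling the progressive-unfreezing schedule;
* ``clone`` yields an independent copy; ``save``/``load`` round-trip the
  weights exactly (JSON, shortest-round-trip float repr).

Architecture: three strided conv+ReLU stages, global average pooling, and a
two-layer dense head with sigmoid output.  In ``per_channel`` mode the same
single-channel network is applied to every channel of the input window,
returning a per-channel probability vector (the intracranial-EEG analogue,
whose outputs are aggregated by top-k pooling downstream).
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import ValidationError

LAYER_GROUPS = ("stem", "block1", "block2", "head")

# (kernel, stride) per conv stage; the long stem kernel gives ~2 Hz frequency
# resolution at a 32 Hz input rate, so rhythm bands are separated before any
# subsampling can alias them together
_CONV_SPECS = {"stem": (15, 4), "block1": (5, 4), "block2": (3, 2)}


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Valid strided 1-D convolution. x: (N,Ci,T), w: (Co,Ci,K) -> (N,Co,To)."""
    k = w.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride, :]
    return np.einsum("nitk,oik->not", cols, w, optimize=True) + b[None, :, None]


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, gy: np.ndarray, stride: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid strided conv. Returns (gx, gw, gb)."""
    k = w.shape[2]
    to = gy.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride, :]
    gw = np.einsum("not,nitk->oik", gy, cols, optimize=True)
    gb = gy.sum(axis=(0, 2))
    gx = np.zeros_like(x)
    git = np.einsum("not,oik->nitk", gy, w, optimize=True)
    for kk in range(k):
        gx[:, :, kk : kk + to * stride : stride] += git[:, :, :, kk]
    return gx, gw, gb


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SurrogateClassifier:
    """Trainable CNN window classifier (the ``ModelHandle`` implementation)."""

    def __init__(
        self,
        n_channels: int,
        window_samples: int,
        n_filters: int = 16,
        hidden: int = 32,
        seed: int = 0,
        per_channel: bool = False,
    ):
        if per_channel and n_channels != 1:
            raise ValidationError("per_channel mode requires a 1-channel network")
        k0 = _CONV_SPECS["stem"][0]
        min_t = k0 * 4 * 2 + k0  # receptive-path minimum after three strided convs
        if window_samples < min_t:
            raise ValidationError(f"window_samples must be >= {min_t}")
        self.n_channels = n_channels
        self.window_samples = window_samples
        self.n_filters = n_filters
        self.hidden = hidden
        self.per_channel = per_channel
        self.layer_groups: tuple[str, ...] = LAYER_GROUPS
        self.trainable: dict[str, bool] = {g: True for g in LAYER_GROUPS}
        rng = np.random.default_rng(seed)
        f = n_filters

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, dict[str, np.ndarray]] = {
            "stem": {"w": he((f, n_channels, k0), n_channels * k0), "b": np.zeros(f)},
            "block1": {"w": he((f, f, 5), f * 5), "b": np.zeros(f)},
            "block2": {"w": he((f, f, 3), f * 3), "b": np.zeros(f)},
            "head": {
                "w1": he((hidden, f), f),
                "b1": np.zeros(hidden),
                "w2": he((1, hidden), hidden),
                "b2": np.zeros(1),
            },
        }

    # ------------------------------------------------------------------ core

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValidationError("batch must be (n, channels, samples)")
        if self.per_channel:
            n, c, t = x.shape
            x = x.reshape(n * c, 1, t)
        if x.shape[1] != self.n_channels:
            raise ValidationError(
                f"expected {self.n_channels} channels, got {x.shape[1]}"
            )
        return x

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Forward pass on a prepared (N, C, T) batch; returns (logits, cache)."""
        p = self.params
        cache: dict[str, np.ndarray] = {}
        a = x
        for g in ("stem", "block1", "block2"):
            _, stride = _CONV_SPECS[g]
            cache[g + "_in"] = a
            z = _conv1d(a, p[g]["w"], p[g]["b"], stride)
            a = np.maximum(z, 0.0)
            cache[g + "_out"] = a
        gap = cache["block2_out"].mean(axis=2)  # (N, F)
        h_pre = gap @ p["head"]["w1"].T + p["head"]["b1"]
        h = np.maximum(h_pre, 0.0)
        logits = (h @ p["head"]["w2"].T + p["head"]["b2"]).ravel()
        cache.update(gap=gap, h=h)
        return logits, cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        """Backprop from d(loss)/d(logits); returns grads mirroring ``params``."""
        p = self.params
        g_head: dict[str, np.ndarray] = {}
        dl = np.asarray(dlogits, dtype=np.float64)[:, None]  # (N,1)
        g_head["w2"] = dl.T @ cache["h"]
        g_head["b2"] = dl.sum(axis=0)
        dh = dl @ p["head"]["w2"]
        dh_pre = dh * (cache["h"] > 0)
        g_head["w1"] = dh_pre.T @ cache["gap"]
        g_head["b1"] = dh_pre.sum(axis=0)
        dgap = dh_pre @ p["head"]["w1"]  # (N, F)
        t_out = cache["block2_out"].shape[2]
        da = np.repeat(dgap[:, :, None] / t_out, t_out, axis=2)
        grads: dict[str, dict[str, np.ndarray]] = {"head": g_head}
        for g in ("block2", "block1", "stem"):
            _, stride = _CONV_SPECS[g]
            dz = da * (cache[g + "_out"] > 0)
            da, gw, gb = _conv1d_backward(cache[g + "_in"], p[g]["w"], dz, stride)
            grads[g] = {"w": gw, "b": gb}
        return grads

    # --------------------------------------------------------------- contract

    def predict_logits(self, batch: np.ndarray) -> np.ndarray:
        x = self._check_batch(batch)
        logits, _ = self.forward(x)
        if self.per_channel:
            n_orig = np.asarray(batch).shape[0] if np.asarray(batch).ndim == 3 else 1
            logits = logits.reshape(n_orig, -1)
        return logits

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Seizure probability per window ((N,) scalar mode, (N,C) per-channel)."""
        return _sigmoid(self.predict_logits(batch))

    def freeze(self, group: str | None = None) -> None:
        for g in [group] if group else self.layer_groups:
            self.trainable[g] = False

    def unfreeze(self, group: str | None = None) -> None:
        for g in [group] if group else self.layer_groups:
            self.trainable[g] = True

    def set_trainable(self, groups: Mapping[str, bool]) -> None:
        for g, flag in groups.items():
            if g not in self.trainable:
                raise ValidationError(f"unknown layer group {g!r}")
            self.trainable[g] = bool(flag)

    def clone(self) -> "SurrogateClassifier":
        return copy.deepcopy(self)

    def n_parameters(self) -> int:
        return sum(a.size for g in self.params.values() for a in g.values())

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return {
            "format": "neuroloop-surrogate-v1",
            "n_channels": self.n_channels,
            "window_samples": self.window_samples,
            "n_filters": self.n_filters,
            "hidden": self.hidden,
            "per_channel": self.per_channel,
            "trainable": dict(self.trainable),
            "params": {
                g: {k: a.tolist() for k, a in d.items()} for g, d in self.params.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateClassifier":
        if d.get("format") != "neuroloop-surrogate-v1":
            raise ValidationError("not a surrogate checkpoint")
        m = cls(
            n_channels=d["n_channels"],
            window_samples=d["window_samples"],
            n_filters=d["n_filters"],
            hidden=d["hidden"],
            per_channel=d["per_channel"],
        )
        m.trainable = {g: bool(v) for g, v in d["trainable"].items()}
        for g, sub in d["params"].items():
            for k, v in sub.items():
                m.params[g][k] = np.asarray(v, dtype=np.float64)
        return m

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ModelHandle is the duck-typed contract; the surrogate is its one in-repo
# implementation, but fine-tuning only relies on the methods above.
ModelHandle = SurrogateClassifier


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimizer over a param dict.

    Updates only layer groups whose ``trainable`` flag is set at step time;
    frozen groups receive neither gradient steps nor weight decay.
    """

    def __init__(
        self,
        model: SurrogateClassifier,
        lr: float = 5e-6,
        weight_decay: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {
            g: {k: np.zeros_like(a) for k, a in d.items()}
            for g, d in model.params.items()
        }
        self.v = copy.deepcopy(self.m)

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for g, sub in self.model.params.items():
            if not self.model.trainable.get(g, False):
                continue
            for k, theta in sub.items():
                gk = grads[g][k]
                self.m[g][k] = b1 * self.m[g][k] + (1 - b1) * gk
                self.v[g][k] = b2 * self.v[g][k] + (1 - b2) * gk * gk
                mhat = self.m[g][k] / (1 - b1**self.t)
                vhat = self.v[g][k] / (1 - b2**self.t)
                theta -= self.lr * (
                    mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * theta
                )
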