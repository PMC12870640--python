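import math

import numpy as np
import pytest

from neuroloop.core import LabelSeries, ValidationError, WindowBatch
from neuroloop.finetune import (
    FineTuneConfig,
    pretrain,
    run_finetune_session,
    session_gate,
    session_loss,
    stratified_split,
    topk_pool,
    topk_pool_vjp,
)
from neuroloop.simulate import make_surrogate_model, surrogate_training_set


def label_series(values):
    values = np.asarray(values, dtype=float)
    return LabelSeries(labels=values, window_start_times=np.arange(len(values)) * 8.0)


class TestStratifiedSplit:
    def test_floor_arithmetic_20_80(self):
        y = np.concatenate([np.ones(20), np.zeros(80)])
        # interleave classes chronologically to exercise per-class ordering
        rng = np.random.default_rng(0)
        y = y[rng.permutation(100)]
        train, val = stratified_split(label_series(y), 0.85)
        yt, yv = y[train], y[val]
        assert (yt == 1).sum() == 17 and (yv == 1).sum() == 3
        assert (yt == 0).sum() == 68 and (yv == 0).sum() == 12

    def test_temporal_order_preserved(self):
        y = np.concatenate([np.zeros(50), np.ones(10), np.zeros(40)])
        train, val = stratified_split(label_series(y), 0.85)
        assert train.max() < 100 and np.all(np.diff(train) > 0)
        # validation samples of each class come after that class's training samples
        pos_train = [i for i in train if y[i] == 1]
        pos_val = [i for i in val if y[i] == 1]
        assert max(pos_train) < min(pos_val)

    def test_all_nan_labels_rejected(self):
        with pytest.raises(ValidationError, match="no valid labels"):
            stratified_split(label_series([np.nan] * 10), 0.85)

    def test_single_positive_goes_to_train(self):
        y = np.zeros(50)
        y[10] = 1.0
        train, _ = stratified_split(label_series(y), 0.85)
        assert 10 in train

    def test_stability_adding_future_samples(self):
        y = np.concatenate([np.zeros(40), np.ones(10)])
        train_a, _ = stratified_split(label_series(y), 0.85)
        y2 = np.concatenate([y, np.zeros(20), np.ones(5)])
        train_b, _ = stratified_split(label_series(y2), 0.85)
        assert set(train_a) <= set(train_b)


class TestSessionGate:
    cfg = FineTuneConfig()

    def test_no_events_skips(self):
        assert session_gate(0, label_series([0, 1]), 0.7, self.cfg) == "skipped_no_events"

    def test_all_nan_labels_skip(self):
        assert (
            session_gate(3, label_series([np.nan, np.nan]), None, self.cfg)
            == "skipped_no_labels"
        )

    def test_high_auroc_skips(self):
        assert session_gate(3, label_series([0, 1]), 0.99, self.cfg) == "skipped_auroc_high"

    def test_low_auroc_skips(self):
        assert session_gate(3, label_series([0, 1]), 0.45, self.cfg) == "skipped_auroc_low"

    def test_midrange_auroc_proceeds(self):
        assert session_gate(3, label_series([0, 1]), 0.8, self.cfg) == "proceed"


class TestTopkPool:
    def test_mean_of_two_largest(self):
        probs = np.full(20, 0.1)
        probs[3], probs[11] = 0.9, 0.7
        assert topk_pool(probs, 0.10) == pytest.approx(0.8)

    def test_identical_channels_identity(self):
        for frac in (0.05, 0.5, 1.0):
            assert topk_pool(np.full(7, 0.42), frac) == pytest.approx(0.42)

    def test_limit_cases_mean_and_max(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        assert topk_pool(p, 1.0) == pytest.approx(p.mean())
        assert topk_pool(p, 1e-9) == pytest.approx(p.max())

    def test_matches_sort_oracle_on_batches(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(200, 17))
        frac = 0.25
        k = max(1, math.ceil(frac * 17))
        expected = np.sort(p, axis=1)[:, -k:].mean(axis=1)
        np.testing.assert_allclose(topk_pool(p, frac), expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            topk_pool(np.empty((3, 0)), 0.1)

    def test_vjp_routes_gradient_to_selected_channels(self):
        p = np.array([[0.9, 0.1, 0.8, 0.2]])
        g = topk_pool_vjp(p, 0.5, np.array([1.0]))  # k = 2
        np.testing.assert_allclose(g, [[0.5, 0.0, 0.5, 0.0]])


class TestSessionLoss:
    def test_zero_distill_weight_equals_task_loss(self):
        preds = np.array([0.8, 0.3])
        labels = np.array([1.0, 0.0])
        ref = np.array([0.5, 0.5])
        with_d = session_loss(preds, labels, ref, "binary_topk", distill_weight=0.0)
        expected = np.mean([-np.log(0.8), -np.log(0.7)])
        assert with_d == pytest.approx(expected)

    def test_distillation_vanishes_when_current_equals_reference(self):
        preds = np.array([0.8, 0.3])
        labels = np.array([1.0, 0.0])
        loss_l0 = session_loss(preds, labels, preds, "binary_topk", distill_weight=0.0)
        loss_l5 = session_loss(preds, labels, preds, "binary_topk", distill_weight=5.0)
        assert loss_l0 == pytest.approx(loss_l5)

    def test_binary_closed_form(self):
        loss = session_loss(
            np.array([0.8]), np.array([1.0]), np.array([0.8]), "binary_topk",
        )
        assert loss == pytest.approx(-np.log(0.8), abs=1e-6)

    def test_channelwise_predictions_pooled_before_bce(self):
        probs = np.full((1, 20), 0.1)
        probs[0, 3], probs[0, 11] = 0.9, 0.7  # pooled = 0.8 at k=2
        loss = session_loss(probs, np.array([1.0]), probs, "binary_topk")
        assert loss == pytest.approx(-np.log(0.8), abs=1e-6)

    def test_multiclass_one_hot_target(self):
        pred = np.array([[0.1, 0.7, 0.2]])
        ref = pred.copy()
        loss = session_loss(pred, np.array([1.0]), ref, "multiclass_kl",
                            detection_class=1, background_class=0)
        assert loss == pytest.approx(-np.log(0.7), abs=1e-6)

    def test_nan_labels_rejected(self):
        with pytest.raises(ValidationError):
            session_loss(np.array([0.5]), np.array([np.nan]), np.array([0.5]))


class TestRunSession:
    def _session_data(self, n=120, seed=0):
        x, y = surrogate_training_set(n // 2, 4, 320, 32.0, seed=seed)
        batch = WindowBatch(
            windows=x, window_start_times=np.arange(n) * 8.0,
            window_length=10.0, stride=8.0, fs_out=32.0,
        )
        labels = LabelSeries(labels=y, window_start_times=batch.window_start_times)
        return batch, labels

    def test_all_frozen_returns_initial_model(self):
        model = make_surrogate_model(0, 4, 320)
        batch, labels = self._session_data()
        cfg = FineTuneConfig(initial_trainable=(), unfreeze_order=(), max_epochs=2)
        res = run_finetune_session(model, batch, labels, cfg, seed=1)
        assert res.status == "trained"
        x = batch.windows[:5]
        np.testing.assert_array_equal(res.best_checkpoint.predict(x), model.predict(x))

    def test_training_improves_validation_loss(self):
        model = make_surrogate_model(0, 4, 320)
        pre_x, pre_y = surrogate_training_set(30, 4, 320, 32.0, seed=5)
        pretrain(model, pre_x, pre_y, epochs=2, lr=1e-3, seed=5)  # weak baseline
        batch, labels = self._session_data(seed=6)
        cfg = FineTuneConfig(learning_rate=3e-4, max_epochs=10)
        for seed in (1, 2, 3):
            res = run_finetune_session(model, batch, labels, cfg, seed=seed)
            assert res.status == "trained"
            assert min(h["val_loss"] for h in res.history[1:]) < res.history[0]["val_loss"]

    def test_checkpoint_val_loss_not_above_all_epochs(self):
        model = make_surrogate_model(0, 4, 320)
        batch, labels = self._session_data(seed=7)
        res = run_finetune_session(
            model, batch, labels, FineTuneConfig(learning_rate=1e-4, max_epochs=6), seed=1
        )
        losses = [h["val_loss"] for h in res.history]
        # recompute the returned checkpoint's val loss via a fresh session history entry
        assert min(losses) <= losses[0]

    def test_empty_validation_split_skips(self):
        model = make_surrogate_model(0, 4, 320)
        x, _ = surrogate_training_set(2, 4, 320, 32.0, seed=0)
        batch = WindowBatch(
            windows=x[:2], window_start_times=np.array([0.0, 8.0]),
            window_length=10.0, stride=8.0, fs_out=32.0,
        )
        labels = LabelSeries(labels=np.array([np.nan, np.nan]),
                             window_start_times=batch.window_start_times)
        res = run_finetune_session(model, batch, labels, seed=0)
        assert res.status == "skipped_no_labels"
        assert res.best_checkpoint is None

    def test_distillation_weight_pins_predictions_monotonically(self):
        model = make_surrogate_model(0, 4, 320)
        pre_x, pre_y = surrogate_training_set(30, 4, 320, 32.0, seed=5)
        pretrain(model, pre_x, pre_y, epochs=3, lr=1e-3, seed=5)
        batch, labels = self._session_data(seed=8)
        # flip labels so the task loss actively pulls away from the reference
        flipped = LabelSeries(labels=1.0 - labels.labels,
                              window_start_times=labels.window_start_times)
        ref_probs = model.predict(batch.windows)
        drifts = []
        for lam in (0.0, 2.0, 50.0):
            cfg = FineTuneConfig(learning_rate=3e-4, max_epochs=5, distill_weight=lam,
                                 patience=10)
            res = run_finetune_session(model, batch, flipped, cfg, seed=3)
            drift = np.abs(res.best_checkpoint.predict(batch.windows) - ref_probs).max()
            drifts.append(drift)
        assert drifts[0] >= drifts[1] >= drifts[2]
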