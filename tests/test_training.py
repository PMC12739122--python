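"""Focal loss, LR schedule, Adam, and the training loop contracts."""

import numpy as np
import pytest

from beatfusion.model import BeatClassifierModel
from beatfusion.signal_io import split_dataset
from beatfusion.synthetic import generate_dataset
from beatfusion.training import (
    Adam,
    FocalLossSpec,
    ScheduleSpec,
    TrainingConfig,
    focal_loss,
    focal_loss_batch,
    lr_at_step,
    train,
)
from beatfusion._tensor import Tensor


def random_simplex(rng, n, k):
    p = rng.dirichlet(np.ones(k), size=n)
    return p


class TestFocalLoss:
    def test_certain_prediction_has_zero_loss(self):
        for gamma, alpha in [(0.0, None), (2.0, np.full(3, 0.3)), (5.0, None)]:
            spec = FocalLossSpec(gamma=gamma, alpha=alpha)
            assert focal_loss(np.array([0.0, 1.0, 0.0]), 1, spec) == 0.0

    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        spec = FocalLossSpec(gamma=0.0)
        assert focal_loss(np.array([0.5, 0.5]), 0, spec) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_evaluated_example(self):
        # gamma=2, alpha=0.25, p_t=0.9: 0.25 * 0.01 * (-ln 0.9) = 2.6341e-4
        spec = FocalLossSpec(gamma=2.0, alpha=np.array([0.25, 0.25]))
        assert focal_loss(np.array([0.9, 0.1]), 0, spec) == pytest.approx(2.6341e-4, rel=1e-4)

    def test_equals_cross_entropy_on_random_simplex_points(self, rng):
        spec = FocalLossSpec(gamma=0.0)
        P = random_simplex(rng, 1000, 4)
        y = rng.integers(0, 4, size=1000)
        for p, t in zip(P, y):
            assert focal_loss(p, int(t), spec) == pytest.approx(-np.log(p[t]), abs=1e-12)

    def test_nonincreasing_in_pt(self):
        spec = FocalLossSpec(gamma=2.0)
        grid = np.linspace(0.01, 0.99, 99)
        losses = [focal_loss(np.array([p, 1 - p]), 0, spec) for p in grid]
        assert all(a >= b - 1e-15 for a, b in zip(losses, losses[1:]))

    def test_zero_probability_clamped_not_infinite(self):
        loss = focal_loss(np.array([0.0, 1.0]), 0, FocalLossSpec(gamma=0.0))
        assert np.isfinite(loss)

    def test_batch_version_matches_per_sample_mean(self, rng):
        spec = FocalLossSpec(gamma=2.0, alpha=np.array([0.5, 1.5, 1.0]))
        P = random_simplex(rng, 20, 3)
        y = rng.integers(0, 3, size=20)
        batch = float(focal_loss_batch(Tensor(P), y, spec).data)
        assert batch == pytest.approx(np.mean([focal_loss(p, int(t), spec) for p, t in zip(P, y)]), abs=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FocalLossSpec(gamma=-1.0)
        with pytest.raises(ValueError):
            FocalLossSpec(alpha=np.array([0.5, 0.0]))


class TestSchedule:
    SPEC = ScheduleSpec(lr_max=1e-3, warmup_steps=100, total_steps=1000)

    def test_peak_at_warmup_boundary(self):
        assert lr_at_step(100, self.SPEC) == pytest.approx(1e-3)

    def test_half_peak_midway_through_warmup(self):
        assert lr_at_step(50, self.SPEC) == pytest.approx(5e-4)

    def test_half_peak_at_four_times_warmup(self):
        assert lr_at_step(400, self.SPEC) == pytest.approx(5e-4)

    def test_monotone_up_then_down(self):
        lrs = [lr_at_step(s, self.SPEC) for s in range(1, 1001)]
        assert all(a <= b + 1e-15 for a, b in zip(lrs[:99], lrs[1:100]))
        assert all(a >= b - 1e-15 for a, b in zip(lrs[99:-1], lrs[100:]))

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            lr_at_step(0, self.SPEC)

    def test_invalid_warmup_rejected(self):
        with pytest.raises(ValueError):
            ScheduleSpec(warmup_steps=0, total_steps=10)


def test_one_adam_step_decreases_batch_loss(rng):
    w = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
    X = rng.normal(size=(10, 6))
    y = rng.integers(0, 3, size=10)

    def loss_value():
        from beatfusion._tensor import softmax
        probs = softmax(Tensor(X) @ w, axis=-1)
        return focal_loss_batch(probs, y, FocalLossSpec(gamma=0.0))

    before = float(loss_value().data)
    loss = loss_value()
    loss.backward()
    Adam({"w": w}).step(lr=1e-4)
    after = float(loss_value().data)
    assert after < before


def _small_run(tiny_model_config, seed, max_epochs=3, **cfg_kwargs):
    counts = {"N": 60, "S": 20, "V": 20}
    ds = generate_dataset(counts, window_len=64, rng_seed=1)
    ds = split_dataset(ds, (0.7, 0.1, 0.2), rng_seed=1)
    model = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(seed))
    config = TrainingConfig(batch_size=16, max_epochs=max_epochs, patience=10, seed=seed, **cfg_kwargs)
    state = train(model, ds, config)
    return model, state


def test_same_seed_reproduces_validation_losses(tiny_model_config):
    _, a = _small_run(tiny_model_config, seed=7)
    _, b = _small_run(tiny_model_config, seed=7)
    assert [h["val_loss"] for h in a.history] == [h["val_loss"] for h in b.history]
    assert [h["train_loss"] for h in a.history] == [h["train_loss"] for h in b.history]


def test_early_stopping_halts_at_patience_exhaustion(tiny_model_config, tmp_path):
    """With a rigged strictly worsening metric, patience=2 stops after epoch 3
    and the epoch-1 checkpoint is the one left on disk."""
    counts = {"N": 40, "S": 12, "V": 12}
    ds = split_dataset(generate_dataset(counts, window_len=64, rng_seed=2), rng_seed=2)
    model = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(0))
    metric_values = iter([1.0, 0.9, 0.8, 0.7, 0.6])
    ckpt = tmp_path / "ckpt.npz"
    state = train(
        model,
        ds,
        TrainingConfig(batch_size=16, max_epochs=20, patience=2, seed=0),
        checkpoint_path=ckpt,
        val_metric_fn=lambda *a: next(metric_values),
    )
    assert state.epoch == 3
    assert state.best_val_metric == 1.0
    meta = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(0)).load(ckpt)
    assert int(meta["epoch"]) == 1


def test_checkpoint_roundtrip_preserves_predictions(tiny_model_config, tmp_path, rng):
    model, _ = _small_run(tiny_model_config, seed=3, max_epochs=1)
    X = rng.normal(size=(5, 64))
    before = model.predict(X)
    model.save(tmp_path / "m.npz")
    fresh = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(99))
    fresh.load(tmp_path / "m.npz")
    np.testing.assert_array_equal(fresh.predict(X), before)


def test_two_stage_mode_freezes_encoders(tiny_model_config):
    model, _ = _small_run(tiny_model_config, seed=4, max_epochs=1, two_stage=True)
    init = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(4))
    for name, p in model.cnn.parameters("cnn/").items():
        np.testing.assert_array_equal(p.data, init.cnn.parameters("cnn/")[name].data)
    # fusion parameters did move
    moved = any(
        not np.array_equal(p.data, init.fusion.parameters("f/")[n.replace("fusion/", "f/", 1)].data)
        for n, p in model.fusion.parameters("fusion/").items()
    )
    assert moved


def test_empty_split_rejected(tiny_model_config):
    ds = generate_dataset({"N": 10, "S": 5, "V": 5}, window_len=64, rng_seed=0)  # unsplit
    model = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        train(model, ds, TrainingConfig(max_epochs=1))


def test_full_model_gradient_reaches_every_parameter(tiny_model_config, rng):
    model = BeatClassifierModel(tiny_model_config, rng=np.random.default_rng(0))
    X = rng.normal(size=(4, 64))
    y = np.array([0, 1, 2, 0])
    probs = model.forward(X, rng, train_mode=False)
    focal_loss_batch(probs, y, FocalLossSpec(gamma=2.0)).backward()
    for name, p in model.parameters().items():
        assert p.grad is not None and np.abs(p.grad).max() > 0, f"dead parameter {name}"
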