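"""Supervised training: focal loss, warm-up/inverse-sqrt LR schedule, Adam,
early stopping and checkpointing.

Focal loss, FL(p_t) = −α_t (1 − p_t)^γ log p_t, down-weights easy examples
so the heavily imbalanced beat classes still contribute gradient; γ = 0 with
uniform α recovers plain cross-entropy.  The learning rate rises linearly to
lr_max over the warm-up steps and then decays as the inverse square root of
the step count:

    lr(step) = lr_max · min(step / warmup_steps, √(warmup_steps / step)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import save_checkpoint
from ._tensor import Tensor
from .evaluation import compute_metrics, confusion_matrix
from .model import BeatClassifierModel
from .signal_io import BeatSegment, LabeledDataset, augment_beat

logger = logging.getLogger(__name__)

__all__ = ["FocalLossSpec", "ScheduleSpec", "TrainingConfig", "TrainingState", "focal_loss", "lr_at_step", "Adam", "train"]

_EPS = 1e-12


@dataclass(frozen=True)
class FocalLossSpec:
    """γ is the focusing exponent; alpha an optional per-class weight vector."""

    gamma: float = 2.0
    alpha: np.ndarray | None = None  # None = uniform weights of 1

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None:
            object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=np.float64))
            if np.any(self.alpha <= 0):
                raise ValueError("alpha entries must be positive")

    def weight(self, class_index: int) -> float:
        return 1.0 if self.alpha is None else float(self.alpha[class_index])


def focal_loss(probabilities: np.ndarray, true_class: int, spec: FocalLossSpec) -> float:
    """FL(p_t) = −α_t (1 − p_t)^γ log(p_t) for one sample."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("probabilities must be a simplex point")
    p_t = p[true_class]
    if p_t < _EPS:
        logger.warning("focal_loss: clamping p_t=%g to %g", p_t, _EPS)
        p_t = _EPS
    return float(-spec.weight(true_class) * (1.0 - p_t) ** spec.gamma * np.log(p_t))


def focal_loss_batch(probs: Tensor, y: np.ndarray, spec: FocalLossSpec) -> Tensor:
    """Mean focal loss over a batch, differentiable through `probs`."""
    n, k = probs.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    p_t = (probs * Tensor(onehot)).sum(axis=1)
    if np.any(p_t.data < _EPS):
        logger.warning("focal_loss: clamping %d probabilities to %g", int((p_t.data < _EPS).sum()), _EPS)
    log_pt = p_t.clip_min(_EPS).log()
    alpha = np.ones(n) if spec.alpha is None else spec.alpha[y]
    nll = Tensor(-alpha) * log_pt
    if spec.gamma > 0:
        nll = nll * (1.0 - p_t) ** spec.gamma
    return nll.mean()


@dataclass(frozen=True)
class ScheduleSpec:
    lr_max: float = 1e-3
    warmup_steps: int = 100
    total_steps: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.warmup_steps <= self.total_steps:
            raise ValueError("need 1 <= warmup_steps <= total_steps")
        if self.lr_max <= 0:
            raise ValueError("lr_max must be positive")


def lr_at_step(step: int, spec: ScheduleSpec) -> float:
    """Warm-up then inverse-square-root decay; the schedule is 1-based."""
    if step < 1:
        raise ValueError("the schedule is 1-based: step must be >= 1")
    return spec.lr_max * min(step / spec.warmup_steps, np.sqrt(spec.warmup_steps / step))


class Adam:
    """Adam over a named parameter dict; lr supplied per step by the schedule."""

    def __init__(self, params: dict[str, Tensor], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.data -= lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


@dataclass
class TrainingConfig:
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    lr_max: float = 1e-3
    warmup_frac: float = 0.08  # inside the customary 5-10% band
    gamma: float = 2.0
    alpha: str | None = "inverse_frequency"  # or None for uniform
    seed: int = 0
    two_stage: bool = False  # freeze encoders, train fusion + head only
    augment_minority: bool = True
    stretch_range: tuple[float, float] = (0.9, 1.1)
    scale_range: tuple[float, float] = (0.8, 1.2)
    selection_metric: str = "macro_f1"


@dataclass
class TrainingState:
    epoch: int = 0
    step: int = 0
    best_val_metric: float = -np.inf
    epochs_since_improvement: int = 0
    rng_seed: int = 0
    checkpoint_path: str | None = None
    history: list[dict] = field(default_factory=list)


def _inverse_frequency_alpha(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class frequency, normalized to mean 1 over the present classes."""
    counts = np.bincount(y, minlength=n_classes).astype(np.float64)
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)
    present = inv > 0
    inv[present] *= present.sum() / inv[present].sum()
    inv[~present] = 1.0
    return inv


def _augment_batch(
    X: np.ndarray,
    y: np.ndarray,
    minority: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    out = X.copy()
    for i in range(len(X)):
        if minority[y[i]]:
            stretch = rng.uniform(*cfg.stretch_range)
            scale = rng.uniform(*cfg.scale_range)
            out[i] = augment_beat(BeatSegment(X[i], label="N"), stretch, scale).samples
    return out


def evaluate_split(model: BeatClassifierModel, X: np.ndarray, y: np.ndarray, vocab: list[str]):
    """Predict a split and compute its metrics report."""
    pred = model.predict(X)
    cm = confusion_matrix([vocab[i] for i in y], [vocab[i] for i in pred], vocab)
    return compute_metrics(cm)


def train(
    model: BeatClassifierModel,
    data: LabeledDataset,
    config: TrainingConfig,
    checkpoint_path=None,
    log_path=None,
    val_metric_fn=None,
) -> TrainingState:
    """Run the full supervised loop; the best-validation weights win.

    After every epoch the validation split is scored (macro-F1 by default —
    the minority classes are the point of the exercise, so plain accuracy
    would be a poor selection signal); the model checkpoint is saved iff the
    score improved, and training stops after `patience` epochs without
    improvement or at `max_epochs`.  A fixed seed makes the run bit-
    reproducible.  `val_metric_fn(model, X_val, y_val) -> float` may replace
    the selection metric.
    """
    vocab = data.class_vocabulary
    train_split, val_split = data.subset("train"), data.subset("val")
    if len(train_split) == 0 or len(val_split) == 0:
        raise ValueError("train and val splits must both be nonempty")
    X_tr, y_tr = train_split.to_arrays()
    X_va, y_va = val_split.to_arrays()

    rng = np.random.default_rng(config.seed)
    n_classes = len(vocab)
    alpha = _inverse_frequency_alpha(y_tr, n_classes) if config.alpha == "inverse_frequency" else None
    loss_spec = FocalLossSpec(gamma=config.gamma, alpha=alpha)
    # minority classes (everything but the most frequent) get augmentation
    counts = np.bincount(y_tr, minlength=n_classes)
    minority = counts < counts.max()

    steps_per_epoch = max(1, -(-len(X_tr) // config.batch_size))
    total_steps = steps_per_epoch * config.max_epochs
    schedule = ScheduleSpec(
        lr_max=config.lr_max,
        warmup_steps=max(1, int(round(config.warmup_frac * total_steps))),
        total_steps=total_steps,
    )
    params = model.fusion.parameters("fusion/") if config.two_stage else model.parameters()
    optimizer = Adam(params)
    state = TrainingState(rng_seed=config.seed, checkpoint_path=str(checkpoint_path) if checkpoint_path else None)
    best_weights: dict[str, np.ndarray] | None = None
    log_lines: list[str] = []

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            if config.augment_minority and minority.any():
                Xb = _augment_batch(Xb, yb, minority, config, rng)
            model.zero_grad()
            probs = model.forward(Xb, rng, train_mode=True, freeze_encoders=config.two_stage)
            loss = focal_loss_batch(probs, yb, loss_spec)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}, step {state.step + 1}")
            loss.backward()
            state.step += 1
            optimizer.step(lr_at_step(state.step, schedule))
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= len(X_tr)

        # validation
        val_probs = []
        for lo in range(0, len(X_va), 256):
            val_probs.append(model.forward(X_va[lo : lo + 256], rng, train_mode=False).data)
        val_probs = np.concatenate(val_probs)
        val_loss = float(
            np.mean(
                [focal_loss(val_probs[i], y_va[i], loss_spec) for i in range(len(y_va))]
            )
        )
        if val_metric_fn is not None:
            val_metric = float(val_metric_fn(model, X_va, y_va))
        else:
            pred = val_probs.argmax(axis=1)
            cm = confusion_matrix([vocab[i] for i in y_va], [vocab[i] for i in pred], vocab)
            report = compute_metrics(cm)
            val_metric = (
                report.aggregate["macro_f1"]
                if config.selection_metric == "macro_f1"
                else report.aggregate["overall_accuracy"]
            )
        state.epoch = epoch
        record = {
            "epoch": epoch,
            "step": state.step,
            "lr": lr_at_step(state.step, schedule),
            "train_loss": epoch_loss,
            "val_loss": val_loss,
            "val_metric": val_metric,
        }
        state.history.append(record)
        log_lines.append(
            "epoch={epoch} step={step} lr={lr:.3e} train_loss={train_loss:.6f} "
            "val_loss={val_loss:.6f} val_metric={val_metric:.6f}".format(**record)
        )
        logger.info(log_lines[-1])

        if val_metric > state.best_val_metric:
            state.best_val_metric = val_metric
            state.epochs_since_improvement = 0
            best_weights = {k: p.data.copy() for k, p in model.parameters().items()}
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, model.parameters(), meta={"epoch": epoch, "val_metric": val_metric})
        else:
            state.epochs_since_improvement += 1
            if state.epochs_since_improvement >= config.patience:
                break

    if best_weights is not None:  # restore the best-validation weights
        for k, p in model.parameters().items():
            p.data = best_weights[k]
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return state
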