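"""Training, fine-tuning and augmentation for the 3D CNN.

The optimizer is Adam on a binary cross-entropy loss plus an L2 penalty
``lambda * sum(W^2)`` over a configurable subset of the convolutional layers
(default: the third and fourth).  Early stopping watches the validation
cross-entropy and restores the checkpoint with the best validation loss.
The learning rate follows inverse-time decay ``lr_t = lr0 / (1 + decay*t)``
per optimizer step.

Augmentation mirrors along the sagittal axis (axis 0) with probability 0.5
and applies an integer translation drawn uniformly from {-2..2}^2 within the
axial plane (axes 0 and 1), zero padded.  A lesion mask co-augmented with
its volume receives the identical transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Network
from .phantoms import CohortManifest

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "finetune",
    "augment",
    "apply_augment",
    "draw_augment_params",
    "lr_schedule",
    "prepare_inputs",
    "bce_loss",
    "l2_penalty",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the fine-tuning regime (lr 5e-4 with 0.002 inverse-time
    decay, patience 15); pre-training uses lr 1e-3, no decay, patience 10.
    """

    learning_rate: float = 5e-4
    lr_decay: float = 0.002
    batch_size: int = 8
    max_epochs: int = 50
    early_stop_patience: int = 15
    l2_lambda: float = 0.01
    l2_conv_indices: tuple[int, ...] = (2, 3)  # 3rd and 4th conv layer
    augmentation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int
    stopped_epoch: int


def lr_schedule(lr0: float, decay: float, step: int) -> float:
    """Inverse-time decay: effective learning rate at optimizer step ``step``."""
    return lr0 / (1.0 + decay * step)


def bce_loss(score: float, label: int, eps: float = 1e-12) -> float:
    s = min(max(score, eps), 1.0 - eps)
    return -(label * np.log(s) + (1 - label) * np.log(1.0 - s))


def l2_penalty(net: Network, lam: float, conv_indices: tuple[int, ...]) -> float:
    """``lam * sum(W^2)`` over the selected conv layers (by conv order)."""
    convs = net.conv_layers()
    total = 0.0
    for i in conv_indices:
        if i < len(convs):
            total += float(np.sum(convs[i].W**2))
    return lam * total


def draw_augment_params(rng: np.random.Generator) -> tuple[bool, int, int]:
    """Draw (sagittal flip?, axis-0 shift, axis-1 shift) for one sample."""
    flip = bool(rng.random() < 0.5)
    t0, t1 = (int(v) for v in rng.integers(-2, 3, size=2))
    return flip, t0, t1


def _shift2(a: np.ndarray, t0: int, t1: int) -> np.ndarray:
    """Integer translation in axes (0,1) with zero padding."""
    out = np.zeros_like(a)

    def sl(t, n):
        if t >= 0:
            return slice(t, n), slice(0, n - t)
        return slice(0, n + t), slice(-t, n)

    d0, s0 = sl(t0, a.shape[0])
    d1, s1 = sl(t1, a.shape[1])
    out[d0, d1, :] = a[s0, s1, :]
    return out


def apply_augment(data: np.ndarray, flip: bool, t0: int, t1: int) -> np.ndarray:
    """Apply a fixed augmentation transform to one 3D array."""
    out = data[::-1, :, :] if flip else data
    if t0 or t1:
        out = _shift2(out, t0, t1)
    return np.ascontiguousarray(out)


def augment(
    data: np.ndarray,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
):
    """Randomly augment one volume (and, optionally, a co-aligned mask)."""
    flip, t0, t1 = draw_augment_params(rng)
    out = apply_augment(data, flip, t0, t1)
    if mask is None:
        return out
    return out, apply_augment(mask, flip, t0, t1)


def prepare_inputs(
    cohort: CohortManifest, dtype=np.float64
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Min-max standardize every volume and stack to (n, D, H, W) plus labels."""
    from .volume_io import minmax_scale

    X = np.stack([minmax_scale(r.volume).data for r in cohort.records]).astype(dtype)
    y = cohort.labels()
    return X, y, cohort.subject_ids()


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, net: Network, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(net.trainable()):
            for name, w, g in layer.params():
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(w)
                    self.v[key] = np.zeros_like(w)
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = self.m[key] / (1 - b1**self.t)
                vhat = self.v[key] / (1 - b2**self.t)
                w -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _epoch_loss(net: Network, X, y, idx) -> tuple[float, float]:
    """Mean BCE and balanced accuracy over ``idx`` in eval mode."""
    losses, preds, labels = [], [], []
    for i in idx:
        score, _, _ = net.forward(X[i], train=False)
        losses.append(bce_loss(score, int(y[i])))
        preds.append(score > 0.5)
        labels.append(int(y[i]))
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    accs = []
    for cls in (0, 1):
        sel = labels == cls
        if sel.any():
            accs.append(np.mean(preds[sel] == cls))
    return float(np.mean(losses)), float(np.mean(accs))


def train(
    net: Network,
    cohort: CohortManifest,
    split,
    cfg: TrainConfig,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> tuple[Network, TrainHistory]:
    """Train ``net`` in place and return it with the best-validation weights.

    ``split`` provides disjoint ``train_ids`` and ``val_ids`` (subject ids);
    holdout subjects are never touched here.  Precomputed standardized inputs
    may be passed via ``X``/``y`` to avoid rescaling per run.
    """
    if X is None or y is None:
        X, y, ids = prepare_inputs(cohort)
    else:
        ids = cohort.subject_ids()
    id_to_idx = {s: i for i, s in enumerate(ids)}
    train_idx = [id_to_idx[s] for s in split.train_ids]
    val_idx = [id_to_idx[s] for s in split.val_ids]
    if not train_idx or not val_idx:
        raise ValueError("empty train or validation split")
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation splits overlap")

    rng = np.random.default_rng(cfg.seed)
    adam = _Adam()
    step = 0
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    history = TrainHistory([], [], [], best_epoch=0, stopped_epoch=0)
    since_improve = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_idx[j] for j in order[start : start + cfg.batch_size]]
            net.zero_grad()
            batch_loss = 0.0
            for i in batch:
                xi = X[i]
                if cfg.augmentation:
                    xi = augment(xi, rng)
                score, logit, _ = net.forward(xi, train=True, rng=rng)
                batch_loss += bce_loss(score, int(y[i]))
                # d(BCE)/d(logit) = sigmoid(logit) - label
                net.backward_logit((score - int(y[i])) / len(batch))
            batch_loss /= len(batch)
            # L2 penalty lam*sum(W^2) on the configured conv layers
            if cfg.l2_lambda > 0:
                convs = net.conv_layers()
                for ci in cfg.l2_conv_indices:
                    if ci < len(convs):
                        convs[ci].gW += 2.0 * cfg.l2_lambda * convs[ci].W
                batch_loss += l2_penalty(net, cfg.l2_lambda, cfg.l2_conv_indices)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}"
                )
            adam.step(net, lr_schedule(cfg.learning_rate, cfg.lr_decay, step))
            step += 1
            epoch_losses.append(batch_loss)

        val_loss, val_acc = _epoch_loss(net, X, y, val_idx)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience:
                break

    net.set_weights(best_weights)
    history.best_epoch = best_epoch
    history.stopped_epoch = len(history.train_loss) - 1
    return net, history


def finetune(
    pretrained: Network,
    cohort: CohortManifest,
    split,
    cfg: TrainConfig,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> tuple[Network, TrainHistory]:
    """Fine-tune a copy of ``pretrained`` on a new task.

    All layers are trainable; the target cohort must match the pre-trained
    input shape and architecture.  With ``max_epochs=0`` the returned weights
    equal the pre-trained ones.
    """
    if cohort.records[0].volume.shape != pretrained.input_shape:
        raise ValueError(
            f"architecture mismatch: pre-trained input {pretrained.input_shape}, "
            f"cohort grid {cohort.records[0].volume.shape}"
        )
    net = pretrained.copy()
    if cfg.max_epochs == 0:
        return net, TrainHistory([], [], [], best_epoch=-1, stopped_epoch=-1)
    return train(net, cohort, split, cfg, X=X, y=y)
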