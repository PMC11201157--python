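"""SGDM/Adam training with a piecewise-constant learning-rate schedule.

Hyperparameter defaults follow the study regime: 30 epochs, mini-batch 8,
weight decay 5e-3, momentum 0.9 (SGDM) or beta1 = 0.9, beta2 = 0.999,
eps = 1e-8 (Adam); initial learning rate 1e-3 for SGDM and 1e-4 for Adam,
dropped by a factor of 0.3 every 10 epochs — the unique constant factor
connecting the stated initial rates to the stated final rates (9e-5 SGDM,
9e-6 Adam) over the two drops of a 30-epoch run.

Weight decay is coupled L2 (added to the gradient) for both optimizers;
decoupled decay is available via ``decoupled_decay=True``.  Training is
deterministic given the seed under single-threaded execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import LossConfig, loss_and_logit_grad, loss_value, softmax_probabilities
from .mask_io import DatasetManifest, read_image, read_index_mask, resize_pair
from .models import UNet

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "learning_rate_at",
    "sgdm_step",
    "adam_step",
    "load_arrays",
    "train",
    "train_arrays",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    mini_batch: int = 8
    optimizer: str = "Adam"
    ilr: float | None = None  # default depends on optimizer
    weight_decay: float = 5.0e-3
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    adam_epsilon: float = 1.0e-8
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.3
    decoupled_decay: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("SGDM", "Adam"):
            raise ValueError("optimizer must be SGDM or Adam")
        if self.ilr is None:
            self.ilr = 1.0e-3 if self.optimizer == "SGDM" else 1.0e-4
        if self.ilr <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must lie in (0, 1]")
        if self.epochs < 1 or self.lr_drop_period < 1:
            raise ValueError("epochs and lr_drop_period must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Piecewise-constant rate: ilr * factor^floor((epoch-1)/period)."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {config.epochs}]")
    drops = (epoch - 1) // config.lr_drop_period
    return config.ilr * config.lr_drop_factor**drops


def _check_finite(params: dict) -> None:
    for k, v in params.items():
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite parameter update in {k!r}")


def sgdm_step(
    params: dict,
    grads: dict,
    velocity: dict,
    lr: float,
    momentum: float = 0.9,
    weight_decay: float = 0.0,
    decoupled: bool = False,
) -> tuple[dict, dict]:
    """One SGD-with-momentum step, in place on the parameter arrays.

    v <- momentum*v - lr*(g + wd*theta); theta <- theta + v (coupled L2).
    """
    for k, theta in params.items():
        g = grads[k]
        if not decoupled:
            g = g + weight_decay * theta
        v = velocity.setdefault(k, np.zeros_like(theta))
        v *= momentum
        v -= lr * g
        theta += v
        if decoupled:
            theta -= lr * weight_decay * theta
    _check_finite(params)
    return params, velocity


def adam_step(
    params: dict,
    grads: dict,
    moments: tuple[dict, dict],
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1.0e-8,
    weight_decay: float = 0.0,
    t: int = 1,
    decoupled: bool = False,
) -> tuple[dict, tuple[dict, dict]]:
    """One bias-corrected Adam step (step counter t >= 1), in place."""
    if t < 1:
        raise ValueError("step counter t must be >= 1")
    m1, m2 = moments
    bc1 = 1.0 - beta1**t
    bc2 = 1.0 - beta2**t
    for k, theta in params.items():
        g = grads[k]
        if not decoupled:
            g = g + weight_decay * theta
        m = m1.setdefault(k, np.zeros_like(theta))
        v = m2.setdefault(k, np.zeros_like(theta))
        m *= beta1
        m += (1.0 - beta1) * g
        v *= beta2
        v += (1.0 - beta2) * g * g
        theta -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
        if decoupled:
            theta -= lr * weight_decay * theta
    _check_finite(params)
    return params, moments


@dataclass
class TrainingLog:
    """Per-iteration and per-epoch loss/accuracy/learning-rate records."""

    iterations: list[dict] = field(default_factory=list)
    epochs: list[dict] = field(default_factory=list)

    def iteration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)

    def epoch_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.iteration_frame().to_csv(out / "iterations.csv", index=False)
        self.epoch_frame().to_csv(out / "epochs.csv", index=False)

    def plot(self, path: str | Path) -> None:
        """Training-curve figure: accuracy and loss per epoch."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.epoch_frame()
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        for key, label in (("train_acc", "train"), ("val_acc", "validation")):
            if key in df:
                axes[0].plot(df["epoch"], df[key], label=label)
        axes[0].set_xlabel("epoch"), axes[0].set_ylabel("accuracy"), axes[0].legend()
        for key, label in (("train_loss", "train"), ("val_loss", "validation")):
            if key in df:
                axes[1].plot(df["epoch"], df[key], label=label)
        axes[1].set_xlabel("epoch"), axes[1].set_ylabel("loss"), axes[1].legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def load_arrays(
    manifest: DatasetManifest, input_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Load a manifest into (N,3,H,W) float32 images and (N,H,W) int masks."""
    xs, ys = [], []
    for r in manifest.records:
        img = read_image(r.image_path)
        mask = read_index_mask(r.mask_path)
        img, mask = resize_pair(img, mask, input_size)
        xs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(mask)
    return np.stack(xs), np.stack(ys)


def _batch_stats(logits_nchw, targets, loss_cfg):
    probs = softmax_probabilities(logits_nchw.transpose(0, 2, 3, 1))
    acc = float((probs.argmax(axis=-1) == targets).mean())
    return float(loss_value(probs, targets, loss_cfg)), acc


def train_arrays(
    model: UNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    loss_cfg: LossConfig,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[UNet, TrainingLog]:
    """Core training loop on in-memory arrays."""
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    log = TrainingLog()
    velocity: dict = {}
    moments: tuple[dict, dict] = ({}, {})
    t = 0
    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate_at(config, epoch)
        perm = rng.permutation(n)
        ep_loss, ep_acc, nb = 0.0, 0.0, 0
        for start in range(0, n, config.mini_batch):
            sel = perm[start : start + config.mini_batch]
            xb, yb = x_train[sel], y_train[sel]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            value, dl = loss_and_logit_grad(
                logits.transpose(0, 2, 3, 1).astype(np.float64), yb, loss_cfg
            )
            model.backward(
                np.ascontiguousarray(dl.transpose(0, 3, 1, 2)).astype(np.float32)
            )
            t += 1
            params, grads = model.parameters(), model.gradients()
            if config.optimizer == "SGDM":
                sgdm_step(
                    params, grads, velocity, lr, config.momentum,
                    config.weight_decay, config.decoupled_decay,
                )
            else:
                adam_step(
                    params, grads, moments, lr, config.beta1, config.beta2,
                    config.adam_epsilon, config.weight_decay, t,
                    config.decoupled_decay,
                )
            acc = float(
                (logits.argmax(axis=1) == yb).mean()
            )
            log.iterations.append(
                {"iteration": t, "epoch": epoch, "loss": value, "train_acc": acc,
                 "lr": lr}
            )
            ep_loss += value
            ep_acc += acc
            nb += 1
        record = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": ep_loss / nb,
            "train_acc": ep_acc / nb,
        }
        if x_val is not None and len(x_val):
            v_loss, v_acc, nv = 0.0, 0.0, 0
            for start in range(0, len(x_val), config.mini_batch):
                xb = x_val[start : start + config.mini_batch]
                yb = y_val[start : start + config.mini_batch]
                logits = model.forward(xb, train=False)
                loss_v, acc_v = _batch_stats(logits, yb, loss_cfg)
                v_loss += loss_v * len(xb)
                v_acc += acc_v * len(xb)
                nv += len(xb)
            record["val_loss"] = v_loss / nv
            record["val_acc"] = v_acc / nv
        log.epochs.append(record)
    return model, log


def train(
    model: UNet,
    manifest: DatasetManifest,
    loss_cfg: LossConfig,
    config: TrainConfig,
) -> tuple[UNet, TrainingLog]:
    """Train from a partitioned manifest (train + optional val records)."""
    tr = manifest.partition("train")
    if len(tr) == 0:
        raise ValueError("manifest has no train records")
    size = tuple(model.config.input_size)
    x_train, y_train = load_arrays(tr, size)
    va = manifest.partition("val")
    x_val, y_val = (None, None) if len(va) == 0 else load_arrays(va, size)
    return train_arrays(model, x_train, y_train, loss_cfg, config, x_val, y_val)
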