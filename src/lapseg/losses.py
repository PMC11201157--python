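"""Loss functions for imbalanced per-pixel classification.

Implements the loss-function zoo compared in the study: (class-weighted)
cross-entropy CE, focal loss FL, soft Tversky loss TL, Dice loss DiL
(Tversky with sigma = beta = 0.5), and the convex combinations
CEDL = delta*CE + (1-delta)*DiL and CETL = delta*CE + (1-delta)*TL.

All losses are evaluated on a per-pixel class-probability map (channel-last,
``(..., C)``, each pixel on the simplex) against an integer label mask, and
each has a companion analytic gradient with respect to the pre-softmax
logits so the NumPy training loop can backpropagate.  The Tversky sums use
the *soft* predicted probabilities (differentiable); hard counts belong to
the metrics module.

Default experiment parameters: alpha_t = 0.25, gamma = 2 (focal);
sigma = 0.3, beta = 0.7 (false positives weighted less than false
negatives); delta = 0.7 (cross-entropy dominant); epsilon = 1e-6 smoothing
on the Tversky ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = [
    "LossConfig",
    "softmax_probabilities",
    "cross_entropy",
    "focal_loss",
    "tversky_index",
    "tversky_loss",
    "dice_loss",
    "combined_loss",
    "loss_value",
    "loss_and_logit_grad",
]

LOSS_KINDS = ("CE", "FL", "DiL", "TL", "CEDL", "CETL")

#: clamp for log(p) in cross-entropy style terms; far below any probability
#: the float32 softmax can resolve, so it only guards against -inf.
LOG_CLAMP = 1.0e-12


@dataclass
class LossConfig:
    """Serializable description of one loss configuration."""

    kind: str = "CETL"
    alpha_t: Any = 0.25
    gamma: float = 2.0
    sigma: float = 0.3
    beta: float = 0.7
    delta: float = 0.7
    epsilon: float = 1.0e-6
    class_weights: Any = None  # None = uniform; else per-class array
    weight_tversky: bool = False
    per_image: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; expected {LOSS_KINDS}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.sigma < 0 or self.beta < 0:
            raise ValueError("sigma and beta must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "alpha_t": self.alpha_t,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "beta": self.beta,
            "delta": self.delta,
            "epsilon": self.epsilon,
            "weight_tversky": self.weight_tversky,
            "per_image": self.per_image,
        }
        if self.class_weights is not None:
            d["class_weights"] = np.asarray(_weights_array(self.class_weights)).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        d = dict(d)
        if d.get("class_weights") is not None:
            d["class_weights"] = np.asarray(d["class_weights"], dtype=float)
        return cls(**d)


def _weights_array(weights) -> np.ndarray | None:
    if weights is None:
        return None
    if hasattr(weights, "weights"):
        weights = weights.weights
    return np.asarray(weights, dtype=float)


def _flatten(probs: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    target = np.asarray(target)
    if probs.shape[:-1] != target.shape:
        raise ValueError(
            f"probability map shape {probs.shape} does not match target {target.shape}"
        )
    c = probs.shape[-1]
    if target.size and (target.min() < 0 or target.max() >= c):
        raise ValueError("target labels outside [0, C)")
    return probs.reshape(-1, c), target.reshape(-1).astype(np.intp)


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the last (class) axis, max-stabilized."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs, target, weights=None) -> float:
    """(Weighted) mean of -log p_true over pixels.

    With per-class weights w, the mean is normalized by the sum of the
    applied weights, so uniform weights reduce exactly to the plain mean.
    Zero probabilities are clamped, never infinite.
    """
    p, t = _flatten(probs, target)
    pt = np.clip(p[np.arange(t.size), t], LOG_CLAMP, 1.0)
    w = _weights_array(weights)
    if w is None:
        return float(-np.log(pt).mean())
    wp = w[t]
    return float(-(wp * np.log(pt)).sum() / wp.sum())


def focal_loss(probs, target, alpha_t=0.25, gamma=2.0) -> float:
    """Mean of alpha_t * (1 - p_t)^gamma * (-log p_t).

    The modulating factor (1-p_t)^gamma down-weights easy pixels; at
    gamma = 0, alpha_t = 1 this is exactly the unweighted cross-entropy.
    ``alpha_t`` may be a scalar or a length-C per-class vector.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, t = _flatten(probs, target)
    pt = np.clip(p[np.arange(t.size), t], LOG_CLAMP, 1.0)
    a = np.asarray(alpha_t, dtype=float)
    av = a[t] if a.ndim == 1 else a
    return float((av * (1.0 - pt) ** gamma * (-np.log(pt))).mean())


def _tversky_terms(probs, target, per_image: bool):
    """Per-class soft TP / FP / FN sums; rows are images if per_image."""
    p, t = _flatten(probs, target)
    c = p.shape[1]
    g = np.zeros_like(p)
    g[np.arange(t.size), t] = 1.0
    if per_image and np.asarray(probs).ndim == 4:
        n = np.asarray(probs).shape[0]
        p = p.reshape(n, -1, c)
        g = g.reshape(n, -1, c)
        tp = (p * g).sum(axis=1)
        fp = (p * (1 - g)).sum(axis=1)
        fn = ((1 - p) * g).sum(axis=1)
    else:
        tp = (p * g).sum(axis=0)[None]
        fp = (p * (1 - g)).sum(axis=0)[None]
        fn = ((1 - p) * g).sum(axis=0)[None]
    return tp, fp, fn


def tversky_index(probs, target, c: int, sigma=0.3, beta=0.7, epsilon=1.0e-6) -> float:
    """Soft Tversky index for class c over all pixels.

    TI_c = (sum J_c G_c + eps) / (sum J_c G_c + sigma*FP + beta*FN + eps)
    with J the predicted class-c probability channel and G the one-hot
    ground truth; sigma weighs false positives, beta false negatives.
    Equals the hard index when probs are one-hot; sigma = beta = 0.5 gives
    the Dice index.
    """
    if sigma < 0 or beta < 0:
        raise ValueError("sigma and beta must be >= 0")
    tp, fp, fn = _tversky_terms(probs, target, per_image=False)
    num = tp[0, c] + epsilon
    den = tp[0, c] + sigma * fp[0, c] + beta * fn[0, c] + epsilon
    return float(num / den)


def tversky_loss(probs, target, sigma=0.3, beta=0.7, epsilon=1.0e-6,
                 per_image=False, class_weights=None) -> float:
    """Sum over classes of (1 - TI_c); lies in [0, C].

    A class absent from both the prediction mass and the truth contributes
    ~0 through the epsilon-smoothed index.  By default the Tversky sums run
    over every pixel in the batch; ``per_image=True`` averages per-image
    losses instead.
    """
    tp, fp, fn = _tversky_terms(probs, target, per_image)
    ti = (tp + epsilon) / (tp + sigma * fp + beta * fn + epsilon)
    w = _weights_array(class_weights)
    terms = (1.0 - ti) if w is None else (1.0 - ti) * w
    return float(terms.sum(axis=1).mean())


def dice_loss(probs, target, epsilon=1.0e-6, per_image=False) -> float:
    """Tversky loss at sigma = beta = 0.5 (the Dice loss)."""
    return tversky_loss(probs, target, 0.5, 0.5, epsilon, per_image)


def combined_loss(kind: str, probs, target, config: LossConfig) -> float:
    """delta*CE + (1-delta)*X, X = Dice loss (CEDL) or Tversky loss (CETL).

    The cross-entropy term carries the class weights; the region term is
    unweighted unless ``config.weight_tversky``.
    """
    if kind not in ("CEDL", "CETL"):
        raise ValueError("combined loss kind must be CEDL or CETL")
    ce = cross_entropy(probs, target, config.class_weights)
    if kind == "CEDL":
        x = dice_loss(probs, target, config.epsilon, config.per_image)
    else:
        x = tversky_loss(
            probs, target, config.sigma, config.beta, config.epsilon,
            config.per_image,
            config.class_weights if config.weight_tversky else None,
        )
    return config.delta * ce + (1.0 - config.delta) * x


def loss_value(probs, target, config: LossConfig) -> float:
    """Evaluate the configured loss on a probability map."""
    k = config.kind
    if k == "CE":
        return cross_entropy(probs, target, config.class_weights)
    if k == "FL":
        return focal_loss(probs, target, config.alpha_t, config.gamma)
    if k == "DiL":
        return dice_loss(probs, target, config.epsilon, config.per_image)
    if k == "TL":
        return tversky_loss(
            probs, target, config.sigma, config.beta, config.epsilon,
            config.per_image,
            config.class_weights if config.weight_tversky else None,
        )
    return combined_loss(k, probs, target, config)


# ---------------------------------------------------------------------------
# analytic gradients w.r.t. logits (channel-last), used by the trainer
# ---------------------------------------------------------------------------


def _ce_grad(p, t, weights):
    m = t.size
    g = p.copy()
    g[np.arange(m), t] -= 1.0
    w = _weights_array(weights)
    if w is None:
        return g / m
    wp = w[t]
    return g * (wp / wp.sum())[:, None]


def _focal_grad(p, t, alpha_t, gamma):
    m = t.size
    pt = np.clip(p[np.arange(m), t], LOG_CLAMP, 1.0)
    a = np.asarray(alpha_t, dtype=float)
    av = a[t] if a.ndim == 1 else np.full(m, float(a))
    one_m = 1.0 - pt
    # d/dpt of alpha*(1-pt)^g*(-log pt)
    if gamma == 0:
        dldpt = -av / pt
    else:
        dldpt = av * (gamma * one_m ** (gamma - 1.0) * np.log(pt) - one_m**gamma / pt)
    dldpt /= m
    # dpt/dz_k = pt * (delta_{k,y} - p_k)
    g = -dldpt[:, None] * pt[:, None] * p
    g[np.arange(m), t] += dldpt * pt
    return g


def _tversky_grad(p, t, sigma, beta, epsilon, class_weights):
    m, c = p.shape
    g1 = np.zeros_like(p)
    g1[np.arange(m), t] = 1.0
    tp = (p * g1).sum(axis=0)
    fp = (p * (1 - g1)).sum(axis=0)
    fn = ((1 - p) * g1).sum(axis=0)
    num = tp + epsilon
    den = tp + sigma * fp + beta * fn + epsilon
    w = _weights_array(class_weights)
    wc = np.ones(c) if w is None else w
    # dTI_c/dJ_cm = (G*den - num*(G + sigma*(1-G) - beta*G)) / den^2
    dden = g1 + sigma * (1 - g1) - beta * g1
    dti = (g1 * den - num[None, :] * dden) / (den**2)[None, :]
    dl_dj = -dti * wc[None, :]  # loss term is wc*(1 - TI_c)
    # back through softmax: dz_k = p_k * (dl_dj_k - sum_c dl_dj_c p_c)
    inner = (dl_dj * p).sum(axis=1, keepdims=True)
    return p * (dl_dj - inner)


def loss_and_logit_grad(logits, target, config: LossConfig):
    """Loss value and its gradient with respect to the logits.

    ``logits`` is channel-last ``(..., C)``; the returned gradient has the
    same shape.  Used by the training loop; cross-checked against central
    finite differences in the test suite.
    """
    probs = softmax_probabilities(logits)
    k = config.kind
    if config.per_image and np.asarray(logits).ndim == 4 and k not in ("CE", "FL"):
        # region terms averaged per image: gradient is the per-image stack / N
        n = np.asarray(logits).shape[0]
        vals, grads = zip(
            *(loss_and_logit_grad(np.asarray(logits)[i], target[i], config)
              for i in range(n))
        )
        return float(np.mean(vals)), np.stack(grads) / n
    p, t = _flatten(probs, target)
    if k == "CE":
        g = _ce_grad(p, t, config.class_weights)
    elif k == "FL":
        g = _focal_grad(p, t, config.alpha_t, config.gamma)
    elif k in ("DiL", "TL"):
        sigma, beta = (0.5, 0.5) if k == "DiL" else (config.sigma, config.beta)
        cw = config.class_weights if (k == "TL" and config.weight_tversky) else None
        g = _tversky_grad(p, t, sigma, beta, config.epsilon, cw)
    else:  # CEDL / CETL
        sigma, beta = (0.5, 0.5) if k == "CEDL" else (config.sigma, config.beta)
        cw = config.class_weights if (k == "CETL" and config.weight_tversky) else None
        g = config.delta * _ce_grad(p, t, config.class_weights) + (
            1.0 - config.delta
        ) * _tversky_grad(p, t, sigma, beta, config.epsilon, cw)
    value = loss_value(probs, target, config)
    return value, g.reshape(np.asarray(logits).shape)
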