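"""Nonlinear activation functions and their derivatives.

Three activations are supported in the hidden layers of the segmentation
networks: the rectified linear unit, the Gaussian error linear unit
(exact erf form, ``x/2 * (1 + erf(x/sqrt(2)))``), and Swish in its
sigmoid-weighted (SiLU) configuration ``x * sigmoid(x)``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import erf, expit

__all__ = ["relu", "gelu", "swish", "activation_fn", "activation_grad", "ACTIVATIONS"]

ACTIVATIONS = ("relu", "gelu", "swish")


def relu(x):
    """max(x, 0): thresholds negative inputs to zero."""
    return np.maximum(x, 0.0)


def gelu(x):
    """Gaussian error linear unit: x weighted by the standard-normal CDF."""
    x = np.asarray(x, dtype=float)
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def swish(x):
    """Swish in the SiLU configuration, x * sigmoid(x)."""
    x = np.asarray(x, dtype=float)
    return x * expit(x)


def _relu_grad(x):
    return (np.asarray(x) > 0).astype(float)


def _gelu_grad(x):
    x = np.asarray(x, dtype=float)
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return cdf + x * pdf


def _swish_grad(x):
    x = np.asarray(x, dtype=float)
    s = expit(x)
    return s * (1.0 + x * (1.0 - s))


_FNS: dict[str, Callable] = {"relu": relu, "gelu": gelu, "swish": swish}
_GRADS: dict[str, Callable] = {"relu": _relu_grad, "gelu": _gelu_grad, "swish": _swish_grad}


def _canon(kind: str) -> str:
    k = kind.lower()
    if k not in _FNS:
        raise ValueError(f"unknown activation {kind!r}; expected one of {ACTIVATIONS}")
    return k


def activation_fn(kind: str) -> Callable:
    return _FNS[_canon(kind)]


def activation_grad(kind: str) -> Callable:
    return _GRADS[_canon(kind)]
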