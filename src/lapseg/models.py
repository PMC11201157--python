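"""Depth-configurable encoder-decoder (U-Net) segmentation network.

The reference configuration of the study is a five-stage encoder-decoder
("U-Net5ed"); here the number of stages is a parameter so desk-scale
experiments can run shallower networks on small images.  Each encoder stage
applies two (conv 3x3 -> batch norm -> activation) blocks and a 2x2 max
pool, doubling the channel width; the decoder mirrors it with 2x2 stride-2
transposed convolutions and skip concatenations; a final 1x1 convolution
produces per-class logits with no activation.

The hidden-layer activation (ReLU / GELU / Swish) is pluggable and
orthogonal to the architecture: swapping it changes no tensor shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activations import ACTIVATIONS, activation_fn, activation_grad, gelu, relu, swish

__all__ = [
    "relu",
    "gelu",
    "swish",
    "UNetConfig",
    "SegmentationModel",
    "UNet",
    "build_unet",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of encoder (and decoder) stages; input height and
    width must be divisible by ``2**depth`` so the pooling pyramid closes.
    ``base_channels`` is the width of the first stage (64 for paper-scale
    runs, 8 for desk-scale tests); widths double per stage.
    """

    depth: int = 5
    base_channels: int = 64
    n_classes: int = 13
    activation: str = "relu"
    input_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.activation.lower() not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.activation = self.activation.lower()
        h, w = self.input_size
        d = 2**self.depth
        if h % d or w % d:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2**depth = {d}"
            )

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "n_classes": self.n_classes,
            "activation": self.activation,
            "input_size": list(self.input_size),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        return cls(**d)


class SegmentationModel:
    """Interface: maps an RGB image batch to per-pixel class logits."""

    config: UNetConfig

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def gradients(self) -> dict[str, np.ndarray]:
        raise NotImplementedError


def _double_conv(c_in, c_out, act, rng):
    from . import nn

    return nn.Sequential(
        nn.Conv2d(c_in, c_out, 3, rng),
        nn.BatchNorm2d(c_out),
        nn.Activation(act),
        nn.Conv2d(c_out, c_out, 3, rng),
        nn.BatchNorm2d(c_out),
        nn.Activation(act),
    )


class UNet(SegmentationModel):
    def __init__(self, config: UNetConfig):
        from . import nn

        self.config = config
        rng = np.random.default_rng(config.seed)
        act = config.activation
        ch = [config.base_channels * 2**s for s in range(config.depth + 1)]

        self.enc = []
        c_prev = 3
        for s in range(config.depth):
            self.enc.append(_double_conv(c_prev, ch[s], act, rng))
            c_prev = ch[s]
        self.pool = [nn.MaxPool2d() for _ in range(config.depth)]
        self.bottleneck = _double_conv(ch[config.depth - 1], ch[config.depth], act, rng)
        self.up = []
        self.dec = []
        for s in reversed(range(config.depth)):
            self.up.append(nn.ConvTranspose2d(ch[s + 1], ch[s], rng))
            self.dec.append(_double_conv(2 * ch[s], ch[s], act, rng))
        self.head = nn.Conv2d(ch[0], config.n_classes, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        for i, m in enumerate(self.enc):
            yield f"enc{i}", m
        yield "bottleneck", self.bottleneck
        for i, (u, d) in enumerate(zip(self.up, self.dec)):
            yield f"up{i}", u
            yield f"dec{i}", d
        yield "head", self.head

    def _leaves(self):
        from . import nn

        for name, m in self._modules():
            if isinstance(m, nn.Sequential):
                for j, lay in enumerate(m.layers):
                    yield f"{name}.{j}", lay
            else:
                yield name, m

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, lay in self._leaves()
            for p, arr in lay.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, lay in self._leaves()
            for p, arr in lay.grads.items()
        }

    def zero_grad(self) -> None:
        for _, lay in self._leaves():
            lay.zero_grad()

    # -- computation ------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 3, H, W) float32 in [0, 1] -> logits (N, C, H, W)."""
        skips = []
        for enc, pool in zip(self.enc, self.pool):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, dec in zip(self.up, self.dec):
            x = up.forward(x, train)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.up), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = dec.backward(dx)
            dskips.append(d[:, :c_skip])
            dx = up.backward(d[:, c_skip:])
        dx = self.bottleneck.backward(dx)
        # dskips was collected shallowest-first; encoders run deepest-first
        for enc, pool, dskip in zip(
            reversed(self.enc), reversed(self.pool), reversed(dskips)
        ):
            dx = pool.backward(dx)
            dx = enc.backward(dx + dskip)

    def batchnorm_state(self) -> dict[str, np.ndarray]:
        from . import nn

        out = {}
        for name, lay in self._leaves():
            if isinstance(lay, nn.BatchNorm2d):
                out[f"{name}.running_mean"] = lay.running_mean
                out[f"{name}.running_var"] = lay.running_var
        return out


def build_unet(config: UNetConfig) -> UNet:
    """Construct the encoder-decoder network for a valid configuration."""
    return UNet(config)


def predict_mask(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Segment one RGB image: argmax over softmax channels, lowest id on ties.

    ``image`` is (H, W, 3) uint8 or float in [0, 1]; returns (H, W) int class
    labels.
    """
    h, w = image.shape[:2]
    if (h, w) != tuple(model.config.input_size):
        raise ValueError(
            f"image size {(h, w)} does not match model input {model.config.input_size}"
        )
    x = np.asarray(image, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    x = x.transpose(2, 0, 1)[None]
    logits = model.forward(x, train=False)[0]
    # argmax of logits == argmax of softmax; np.argmax takes the lowest index on ties
    return logits.argmax(axis=0).astype(np.int64)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Save weights (npz) plus a JSON config sidecar for reconstruction."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(model.parameters())
    arrays.update({f"_bn_{k}": v for k, v in model.batchnorm_state().items()})
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    config = UNetConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = UNet(config)
    with np.load(path) as data:
        params = model.parameters()
        bn = model.batchnorm_state()
        for k in data.files:
            if k.startswith("_bn_"):
                bn[k[4:]][...] = data[k]
            else:
                params[k][...] = data[k]
    return model
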