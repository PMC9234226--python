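"""The 2D U-net, the focal loss, and self-sufficient model checkpoints.

The network is a conventional fully-convolutional encoder-decoder with skip
connections: two 3x3 SeLU convolutions per level, 2x2 max-pooling down, 2x2
transposed-convolution up, alpha dropout at the deepest level only, and a
1x1 convolution + softmax producing four per-pixel class probabilities
(background, CTV, bladder, rectum).  Any input whose side is divisible by
``2^depth`` works, so the net trains on small patches and infers on full
slices without tiling.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io import N_CLASSES
from .nn import (Adam, AlphaDropout, Conv2D, ConvTranspose2D, MaxPool2x2,
                 SeLU, softmax_channels)
from .preprocess import CropRegion, NormStats


@dataclass
class UNetSpec:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling steps (encoder levels); filters start
    at ``base_filters`` and double per level.
    """

    depth: int = 4
    base_filters: int = 32
    bottom_dropout_rate: float = 0.4
    n_classes: int = N_CLASSES
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if not 0 <= self.bottom_dropout_rate < 1:
            raise ValueError("bottom_dropout_rate must be in [0, 1)")

    def to_json(self) -> dict:
        return {"depth": self.depth, "base_filters": self.base_filters,
                "bottom_dropout_rate": self.bottom_dropout_rate,
                "n_classes": self.n_classes, "kernel": self.kernel}

    @classmethod
    def from_json(cls, d: dict) -> "UNetSpec":
        return cls(**d)


class UNet:
    """Trainable U-net instance.  Use :func:`build_model` to construct."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        f, d, k = spec.base_filters, spec.depth, spec.kernel
        self.enc: list[list] = []
        c_in = 1
        for lvl in range(d):
            c = f * 2 ** lvl
            self.enc.append([Conv2D(c_in, c, k, rng), SeLU(),
                             Conv2D(c, c, k, rng), SeLU()])
            c_in = c
        self.pools = [MaxPool2x2() for _ in range(d)]
        cb = f * 2 ** d
        self.bottom = [Conv2D(c_in, cb, k, rng), SeLU(),
                       Conv2D(cb, cb, k, rng), SeLU(),
                       AlphaDropout(spec.bottom_dropout_rate, rng)]
        self.ups: list[ConvTranspose2D] = []
        self.dec: list[list] = []
        c_in = cb
        for lvl in reversed(range(d)):
            c = f * 2 ** lvl
            self.ups.append(ConvTranspose2D(c_in, c, rng))
            self.dec.append([Conv2D(2 * c, c, k, rng), SeLU(),
                             Conv2D(c, c, k, rng), SeLU()])
            c_in = c
        self.head = Conv2D(c_in, spec.n_classes, 1, rng)
        self._skip_channels: list[int] | None = None

    def layers(self) -> list:
        out = []
        for blk in self.enc:
            out += blk
        out += self.pools + self.bottom + self.ups
        for blk in self.dec:
            out += blk
        out.append(self.head)
        return out

    def _check_input(self, x: np.ndarray) -> None:
        div = 2 ** self.spec.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input spatial size {x.shape[1:3]} must be divisible by "
                f"2^depth = {div}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, H, W, 1) float32 -> (B, H, W, n_classes) probabilities."""
        self._check_input(x)
        skips = []
        h = x if x.dtype in (np.float32, np.float64) else x.astype(np.float32)
        for blk, pool in zip(self.enc, self.pools):
            for layer in blk:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottom:
            h = layer.forward(h, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=-1)
            for layer in blk:
                h = layer.forward(h, train)
        logits = self.head.forward(h, train)
        return softmax_channels(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-softmax logits."""
        dh = self.head.backward(dlogits)
        dskips = []
        for up, blk, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                   self._skip_channels):
            for layer in reversed(blk):
                dh = layer.backward(dh)
            dskips.append(dh[..., :c_skip])
            dh = up.backward(dh[..., c_skip:])
        # reversed decoder walk visits level 0 first -> dskips is in level order
        for layer in reversed(self.bottom):
            dh = layer.backward(dh)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dh = pool.backward(dh)
            dh = dh + dskip
            for layer in reversed(blk):
                dh = layer.backward(dh)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers() for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers() for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.layers(), lr)


def build_model(spec: UNetSpec, rng: np.random.Generator | int) -> UNet:
    """Construct a U-net with LeCun-normal initial weights."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return UNet(spec, rng)


def focal_loss(prob: np.ndarray, target_onehot: np.ndarray, gamma: float = 2.0,
               return_dlogits: bool = False, class_axis: int = -1):
    """Mean focal loss  -(1 - p_t)^gamma * log(p_t)  over pixels.

    ``p_t`` is the predicted probability of the true class; ``gamma = 0``
    reduces to categorical cross-entropy.  With ``return_dlogits`` the fused
    gradient with respect to the pre-softmax logits is returned as well
    (valid when ``prob`` came from a softmax).
    """
    if prob.shape != target_onehot.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target_onehot.shape}")
    p_t = np.clip((prob * target_onehot).sum(axis=class_axis), 1e-12, 1.0)
    one_m = 1.0 - p_t
    loss = float(np.mean(one_m ** gamma * (-np.log(p_t))))
    if not return_dlogits:
        return loss
    n_pix = p_t.size
    if gamma == 0:
        dldu = -1.0 / p_t
    else:
        dldu = gamma * one_m ** (gamma - 1) * np.log(p_t) - one_m ** gamma / p_t
    dldu = dldu / n_pix
    u = np.expand_dims(p_t, class_axis)
    dlogits = np.expand_dims(dldu, class_axis) * u * (target_onehot - prob)
    return loss, dlogits.astype(prob.dtype)


def pad_to_multiple(img: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple]:
    """Reflect-pad a 2D array so both sides divide ``multiple``."""
    h, w = img.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return img, (0, 0, 0, 0)
    pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    out = np.pad(img, ((pads[0], pads[1]), (pads[2], pads[3])), mode="reflect")
    return out, pads


def forward_slice(model: UNet, slice_2d: np.ndarray) -> np.ndarray:
    """Inference on one transversal slice -> (n_classes, H, W) probabilities.

    Sides not divisible by 2^depth are reflect-padded and the output is
    cropped back; dropout is inactive, so repeated calls are identical.
    """
    mult = 2 ** model.spec.depth
    padded, pads = pad_to_multiple(np.asarray(slice_2d, dtype=np.float32), mult)
    prob = model.forward(padded[None, :, :, None], train=False)[0]
    t, b, l, r = pads
    h, w = padded.shape
    return np.moveaxis(prob[t:h - b, l:w - r, :], -1, 0)


@dataclass
class ModelCheckpoint:
    """A self-sufficient inference bundle: weights + the training-time crop
    and intensity window, so a test volume can be segmented from this object
    alone."""

    epoch: int
    weights: list[np.ndarray]
    spec: UNetSpec
    crop: CropRegion
    norm_stats: NormStats
    train_config_hash: str = ""

    def build(self) -> UNet:
        model = build_model(self.spec, np.random.default_rng(0))
        model.set_weights(self.weights)
        return model

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"),
                 **{f"w{i}": w for i, w in enumerate(self.weights)})
        meta = {"format_version": 1, "epoch": self.epoch,
                "spec": self.spec.to_json(), "crop": self.crop.to_json(),
                "norm_stats": self.norm_stats.to_json(),
                "train_config_hash": self.train_config_hash,
                "n_weights": len(self.weights)}
        with open(os.path.join(directory, "checkpoint.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ModelCheckpoint":
        with open(os.path.join(directory, "checkpoint.json")) as fh:
            meta = json.load(fh)
        with np.load(os.path.join(directory, "weights.npz")) as npz:
            weights = [npz[f"w{i}"] for i in range(meta["n_weights"])]
        return cls(epoch=meta["epoch"], weights=weights,
                   spec=UNetSpec.from_json(meta["spec"]),
                   crop=CropRegion.from_json(meta["crop"]),
                   norm_stats=NormStats.from_json(meta["norm_stats"]),
                   train_config_hash=meta.get("train_config_hash", ""))


def config_hash(*objs) -> str:
    blob = json.dumps([getattr(o, "__dict__", o) for o in objs],
                      default=str, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_bundle(checkpoints: list[ModelCheckpoint], directory) -> None:
    """Write an ordered checkpoint bundle: ``ckpt_epoch{NNNN}/`` per member."""
    os.makedirs(directory, exist_ok=True)
    for ck in checkpoints:
        ck.save(os.path.join(directory, f"ckpt_epoch{ck.epoch:04d}"))


def load_bundle(directory) -> list[ModelCheckpoint]:
    names = sorted(n for n in os.listdir(directory) if n.startswith("ckpt_epoch"))
    if not names:
        raise FileNotFoundError(f"no checkpoints under {directory}")
    return [ModelCheckpoint.load(os.path.join(directory, n)) for n in names]
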