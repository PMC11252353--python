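"""Encoder-decoder semantic segmentation of polarized cell images.

A standard U-Net: an encoder of ``levels`` resolution levels (two 3x3
convolutions + ReLU per level, 2x2 max-pooling between levels, feature
width doubling each level), a mirrored decoder with 2x2 transposed-
convolution upsampling and skip concatenation, and a 1x1 convolution onto
three classes (background / ambiguous cell signal / high-quality cells)
with a softmax head. The two input channels are the co- and
cross-polarized emission images scaled to [0, 1].

The network, backpropagation, and the Adam optimizer are implemented
directly on NumPy (im2col convolutions backed by BLAS matmul), which is
fast enough for the desk-scale images this package trains on and keeps
the whole pipeline dependency-light. Training uses per-pixel
cross-entropy with equal class weights, batch size four by default, and
online augmentations (rotation, flips, scaling, shearing, optional
elastic deformation, random cropping) drawn fresh each epoch from a
seeded generator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import PolarizedImagePair, TriMask

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class NetConfig:
    """Architecture parameters.

    ``levels`` resolution levels with ``base_channels`` features at the
    finest level, doubling per level. Inputs are the two polarization
    channels; outputs the three annotation classes.
    """

    levels: int = 5
    base_channels: int = 16
    in_channels: int = 2
    out_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("a U-Net needs at least 2 resolution levels")
        if self.in_channels != 2:
            raise ValueError("the network takes exactly 2 input channels (co, cross)")
        if self.out_classes != 3:
            raise ValueError("the network predicts exactly 3 classes")


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation ranges (applied independently per sample).

    Elastic deformation is implemented but off by default; it is not
    clearly class-preserving for this imagery. Label masks are always
    resampled with nearest-neighbour interpolation.
    """

    flips: bool = True
    rotation_deg: float = 180.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    shear_deg: float = 10.0
    elastic: bool = False
    elastic_alpha: float = 10.0
    elastic_sigma: float = 4.0
    random_crop: bool = True


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-3
    epochs: int = 20
    crop_size: int | None = None
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass(frozen=True)
class ProbabilityMaps:
    """Per-pixel class probabilities, shape (3, H, W), summing to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float32)
        if p.ndim != 3 or p.shape[0] != 3:
            raise ValueError("expected (3, H, W) probability maps")
        object.__setattr__(self, "probs", p)

    @property
    def background(self) -> np.ndarray:
        return self.probs[0]

    @property
    def ambiguous(self) -> np.ndarray:
        return self.probs[1]

    @property
    def high_quality(self) -> np.ndarray:
        return self.probs[2]

    def class_map(self) -> np.ndarray:
        return np.argmax(self.probs, axis=0)


# ---------------------------------------------------------------------------
# primitive layers (im2col convolutions with manual backprop)
# ---------------------------------------------------------------------------


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return (
        win.reshape(n, c, h, w, 9).transpose(0, 1, 4, 2, 3).reshape(n, c * 9, h * w)
    )


def _col2im3(dcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`: scatter-add patches back to the grid."""
    n = dcols.shape[0]
    d = dcols.reshape(n, c, 9, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, k]
            k += 1
    return dxp[:, :, 1 : h + 1, 1 : w + 1]


def _conv3_forward(x, W, b):
    n, c, h, w = x.shape
    cols = _im2col3(x)
    y = (W @ cols) + b[:, None]
    return y.reshape(n, W.shape[0], h, w)


def _conv3_backward(dy, x, W):
    n, c, h, w = x.shape
    o = W.shape[0]
    dyr = dy.reshape(n, o, h * w)
    cols = _im2col3(x)
    dW = np.einsum("noh,nch->oc", dyr, cols, optimize=True)
    db = dyr.sum(axis=(0, 2))
    dcols = np.matmul(W.T[None], dyr)
    dx = _col2im3(dcols, c, h, w)
    return dx, dW, db


def _maxpool_forward(x):
    n, c, h, w = x.shape
    xr = (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = np.argmax(xr, axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy, idx, h, w):
    n, c, hh, ww = dy.shape
    dxr = np.zeros((n, c, hh, ww, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return (
        dxr.reshape(n, c, hh, ww, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _upconv_forward(x, W, b):
    # W: (C_in, C_out*4); each input pixel expands to a 2x2 output block
    n, c, h, w = x.shape
    co4 = W.shape[1]
    co = co4 // 4
    xr = x.reshape(n, c, h * w)
    y4 = np.matmul(W.T[None], xr)  # (n, C_out*4, h*w)
    y = (
        y4.reshape(n, co, 2, 2, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, co, 2 * h, 2 * w)
    )
    return y + b[None, :, None, None]


def _upconv_backward(dy, x, W):
    n, c, h, w = x.shape
    co = W.shape[1] // 4
    dy4 = (
        dy.reshape(n, co, h, 2, w, 2)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, co * 4, h * w)
    )
    xr = x.reshape(n, c, h * w)
    dW = np.einsum("noh,nch->co", dy4, xr, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.matmul(W[None], dy4).reshape(n, c, h, w)
    return dx, dW, db


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class UNet:
    """Encoder-decoder network with skip connections; see module docstring."""

    #: working precision; float32 keeps BLAS matmuls fast
    dtype = np.float32

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        rng = np.random.default_rng(cfg.seed)
        chans = [cfg.base_channels * 2**i for i in range(cfg.levels)]
        self.channels = chans

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        prev = cfg.in_channels
        for i, c in enumerate(chans):
            self.params[f"enc{i}_c1_W"] = he((c, prev * 9), prev * 9)
            self.params[f"enc{i}_c1_b"] = np.zeros(c, dtype=np.float32)
            self.params[f"enc{i}_c2_W"] = he((c, c * 9), c * 9)
            self.params[f"enc{i}_c2_b"] = np.zeros(c, dtype=np.float32)
            prev = c
        for i in range(cfg.levels - 2, -1, -1):
            c, cb = chans[i], chans[i + 1]
            self.params[f"up{i}_W"] = he((cb, c * 4), cb)
            self.params[f"up{i}_b"] = np.zeros(c, dtype=np.float32)
            self.params[f"dec{i}_c1_W"] = he((c, 2 * c * 9), 2 * c * 9)
            self.params[f"dec{i}_c1_b"] = np.zeros(c, dtype=np.float32)
            self.params[f"dec{i}_c2_W"] = he((c, c * 9), c * 9)
            self.params[f"dec{i}_c2_b"] = np.zeros(c, dtype=np.float32)
        self.params["out_W"] = he((cfg.out_classes, chans[0]), chans[0])
        self.params["out_b"] = np.zeros(cfg.out_classes, dtype=np.float32)

    # -- shape checks ------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        div = 2 ** (self.cfg.levels - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input spatial dimensions {x.shape[2:]} must be divisible by "
                f"{div} (= 2^(levels-1)); pad or crop the image accordingly"
            )

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.params
        L = self.cfg.levels
        cache: dict = {"inputs": {}, "relu": {}, "pool_idx": {}, "pool_shape": {}}
        skips = {}
        h = x
        for i in range(L):
            for j in (1, 2):
                key = f"enc{i}_c{j}"
                cache["inputs"][key] = h
                h = _conv3_forward(h, p[f"{key}_W"], p[f"{key}_b"])
                np.maximum(h, 0.0, out=h)
                cache["relu"][key] = h
            skips[i] = h
            if i < L - 1:
                cache["pool_shape"][i] = h.shape[2:]
                h, idx = _maxpool_forward(h)
                cache["pool_idx"][i] = idx
        for i in range(L - 2, -1, -1):
            key = f"up{i}"
            cache["inputs"][key] = h
            up = _upconv_forward(h, p[f"{key}_W"], p[f"{key}_b"])
            h = np.concatenate([skips[i], up], axis=1)
            for j in (1, 2):
                key = f"dec{i}_c{j}"
                cache["inputs"][key] = h
                h = _conv3_forward(h, p[f"{key}_W"], p[f"{key}_b"])
                np.maximum(h, 0.0, out=h)
                cache["relu"][key] = h
        cache["inputs"]["out"] = h
        n, c, hh, ww = h.shape
        logits = (
            p["out_W"] @ h.reshape(n, c, hh * ww) + p["out_b"][:, None]
        ).reshape(n, self.cfg.out_classes, hh, ww)
        if want_cache:
            return logits, cache
        return logits

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        """Mean per-pixel cross-entropy and parameter gradients.

        ``labels``: (N, H, W) integer class map.
        """
        logits, cache = self.forward(x, want_cache=True)
        n, k, hh, ww = logits.shape
        probs = _softmax(logits)
        flat = probs.reshape(n, k, -1)
        lab = labels.reshape(n, -1)
        picked = np.take_along_axis(flat, lab[:, None, :], axis=1)[:, 0, :]
        loss = float(-np.mean(np.log(np.maximum(picked, 1e-12))))

        dlogits = probs.copy()
        np.put_along_axis(
            dlogits.reshape(n, k, -1), lab[:, None, :],
            np.take_along_axis(dlogits.reshape(n, k, -1), lab[:, None, :], axis=1) - 1.0,
            axis=1,
        )
        dlogits /= n * hh * ww

        p = self.params
        grads = {name: None for name in p}
        L = self.cfg.levels

        # output 1x1 conv
        h_out = cache["inputs"]["out"]
        nn_, c0, _, _ = h_out.shape
        dyr = dlogits.reshape(nn_, k, hh * ww)
        hr = h_out.reshape(nn_, c0, hh * ww)
        grads["out_W"] = np.einsum("nkh,nch->kc", dyr, hr, optimize=True)
        grads["out_b"] = dyr.sum(axis=(0, 2))
        dh = np.matmul(p["out_W"].T[None], dyr).reshape(nn_, c0, hh, ww)

        # decoder backward: the forward ran levels L-2 .. 0, so walk 0 .. L-2,
        # carrying dh from each level's up-conv input into the next level's
        # decoder output (the bottleneck for the deepest one)
        dskips = {}
        for i in range(0, L - 1):
            for j in (2, 1):
                key = f"dec{i}_c{j}"
                dh = dh * (cache["relu"][key] > 0)
                dx_, dW_, db_ = _conv3_backward(dh, cache["inputs"][key], p[f"{key}_W"])
                grads[f"{key}_W"], grads[f"{key}_b"] = dW_, db_
                dh = dx_
            c = self.channels[i]
            dskips[i], dup = dh[:, :c], dh[:, c:]
            key = f"up{i}"
            dh, dW_, db_ = _upconv_backward(dup, cache["inputs"][key], p[f"{key}_W"])
            grads[f"{key}_W"], grads[f"{key}_b"] = dW_, db_
        # encoder backward: bottleneck first, then up with pool scatter + skips
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                h0, w0 = cache["pool_shape"][i]
                dh = _maxpool_backward(dh, cache["pool_idx"][i], h0, w0)
                dh = dh + dskips[i]
            for j in (2, 1):
                key = f"enc{i}_c{j}"
                dh = dh * (cache["relu"][key] > 0)
                dx_, dW_, db_ = _conv3_backward(dh, cache["inputs"][key], p[f"{key}_W"])
                grads[f"{key}_W"], grads[f"{key}_b"] = dW_, db_
                dh = dx_
        return loss, grads

    # -- optimizer ---------------------------------------------------------

    def adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            if g is None:
                continue
            g = g.astype(np.float32)
            m = self._adam_m.get(name)
            if m is None:
                m = np.zeros_like(g)
                self._adam_v[name] = np.zeros_like(g)
            v = self._adam_v[name]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam_m[name], self._adam_v[name] = m, v
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = json.dumps(dataclasses.asdict(self.cfg))
        np.savez(Path(path), __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            net = cls(NetConfig(**meta))
            for name in net.params:
                net.params[name] = data[name].astype(np.float32)
        return net


def build_network(cfg: NetConfig | None = None) -> UNet:
    """Construct a seeded U-Net from an architecture config."""
    return UNet(cfg or NetConfig())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _affine_matrix(rot_deg, scale, shear_deg, center):
    th = np.deg2rad(rot_deg)
    sh = np.deg2rad(shear_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
    mat = (rot @ shear) / scale
    offset = np.asarray(center) - mat @ np.asarray(center)
    return mat, offset


def augment_sample(
    image: np.ndarray,
    labels: np.ndarray,
    acfg: AugmentConfig,
    rng: np.random.Generator,
    crop_size: int | None = None,
):
    """Apply one random draw of the augmentation chain to (C,H,W) + (H,W)."""
    img = image
    lab = labels
    if acfg.flips:
        if rng.random() < 0.5:
            img, lab = img[:, :, ::-1], lab[:, ::-1]
        if rng.random() < 0.5:
            img, lab = img[:, ::-1, :], lab[::-1, :]
    rot = rng.uniform(-acfg.rotation_deg, acfg.rotation_deg) if acfg.rotation_deg else 0.0
    scale = rng.uniform(*acfg.scale_range) if acfg.scale_range else 1.0
    shear = rng.uniform(-acfg.shear_deg, acfg.shear_deg) if acfg.shear_deg else 0.0
    if rot or shear or scale != 1.0:
        center = ((img.shape[1] - 1) / 2.0, (img.shape[2] - 1) / 2.0)
        mat, offset = _affine_matrix(rot, scale, shear, center)
        img = np.stack(
            [
                ndimage.affine_transform(ch, mat, offset=offset, order=1, mode="nearest")
                for ch in img
            ]
        )
        lab = ndimage.affine_transform(
            lab.astype(np.float64), mat, offset=offset, order=0, mode="nearest"
        ).astype(labels.dtype)
    if acfg.elastic:
        h, w = lab.shape
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), acfg.elastic_sigma) * acfg.elastic_alpha
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), acfg.elastic_sigma) * acfg.elastic_alpha
        yy, xx = np.mgrid[0:h, 0:w]
        coords = [yy + dy, xx + dx]
        img = np.stack(
            [ndimage.map_coordinates(ch, coords, order=1, mode="nearest") for ch in img]
        )
        lab = ndimage.map_coordinates(
            lab.astype(np.float64), coords, order=0, mode="nearest"
        ).astype(labels.dtype)
    if crop_size is not None and acfg.random_crop:
        h, w = lab.shape
        if crop_size > h or crop_size > w:
            raise ValueError("crop_size exceeds the image size")
        r0 = int(rng.integers(0, h - crop_size + 1))
        c0 = int(rng.integers(0, w - crop_size + 1))
        img = img[:, r0 : r0 + crop_size, c0 : c0 + crop_size]
        lab = lab[r0 : r0 + crop_size, c0 : c0 + crop_size]
    return np.ascontiguousarray(img, dtype=np.float32), np.ascontiguousarray(lab)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------


def _to_input(pair: PolarizedImagePair) -> np.ndarray:
    """Stack the two channels and scale counts to [0, 1]."""
    return np.stack([pair.co, pair.cross]).astype(np.float32) / 255.0


def train(
    net: UNet,
    samples: Sequence[tuple[PolarizedImagePair, TriMask]],
    cfg: TrainConfig,
) -> list[float]:
    """Supervised training; returns the per-epoch mean loss history."""
    if len(samples) == 0:
        raise ValueError("training requires at least one sample")
    xs, ys = [], []
    for pair, masks in samples:
        if pair.shape != masks.shape:
            raise ValueError("mask/image dimension mismatch in training sample")
        xs.append(_to_input(pair))
        ys.append(masks.class_map())
    rng = np.random.default_rng(cfg.seed)
    n = len(xs)
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [
                augment_sample(xs[i], ys[i], cfg.augment, rng, cfg.crop_size)
                for i in idx
            ]
            xb = np.stack([b[0] for b in batch])
            yb = np.stack([b[1] for b in batch])
            loss, grads = net.loss_and_grads(xb, yb)
            net.adam_step(grads, lr=cfg.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(net: UNet, pair: PolarizedImagePair) -> ProbabilityMaps:
    """Per-pixel class probabilities for one image pair (deterministic)."""
    x = _to_input(pair)[None]
    logits = net.forward(x)
    return ProbabilityMaps(probs=_softmax(logits)[0])


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)
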