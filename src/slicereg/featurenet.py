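"""Kidney feature networks: a 5-level residual U-Net with local binary
convolution (LBC) skip layers, for CT volumes and 5-frame US windows.

The network maps an image patch to a same-shape kidney probability map
(sigmoid output).  Residual blocks replace plain convolutions; each skip
connection passes through an LBC layer — a fixed bank of sparse random
ternary {-1, 0, +1} filters followed by a ReLU and a trainable 1x1x1
combination — injecting handcrafted texture features that narrow the
semantic gap between modalities.  US windows are never downsampled along
the time axis.

Training minimises the negative soft set-Dice coefficient with Adam at
learning rate 1e-4 and batch size 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .engine import Adam, Tensor, conv3d, upsample_nearest3d

__all__ = [
    "FeatureMap",
    "ULBNetConfig",
    "LBCLayer",
    "ULBNet",
    "build_ulbnet",
    "train_featurenet",
    "predict_featuremap",
    "seg_metrics",
    "ct_config",
    "us_config",
    "desk_ct_config",
    "desk_us_config",
]

DTYPE = np.float32


@dataclass
class FeatureMap:
    """Per-voxel kidney probability on the source grid."""

    values: np.ndarray
    modality: str = "CT"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("feature map values must lie in [0, 1]")
        if self.modality not in ("CT", "US"):
            raise ValueError("modality must be CT or US")


@dataclass
class ULBNetConfig:
    levels: int = 5
    encoder_filters: tuple = (16, 32, 64, 128, 256)
    decoder_filters: tuple = (256, 128, 64, 32, 16)
    dropout: float = 0.2
    lbc_filters: int = 8
    lbc_sparsity: float = 0.5
    time_axis: int | None = None  # axis that is never down/upsampled (US: 0)
    patch_shape: tuple = (160, 160, 80)
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if len(self.encoder_filters) != self.levels or len(self.decoder_filters) != self.levels:
            raise ValueError("encoder and decoder filter lists must have length = levels")
        factor = 2 ** (self.levels - 1)
        for ax, n in enumerate(self.patch_shape):
            if ax == self.time_axis:
                continue
            if n % factor != 0:
                raise ValueError(
                    f"patch axis {ax} (size {n}) must be divisible by {factor} "
                    f"for a {self.levels}-level network")

    def level_stride(self) -> tuple:
        return tuple(1 if ax == self.time_axis else 2 for ax in range(3))


def ct_config(**kw) -> ULBNetConfig:
    return ULBNetConfig(**kw)


def us_config(**kw) -> ULBNetConfig:
    kw.setdefault("patch_shape", (5, 192, 256))
    kw.setdefault("time_axis", 0)
    return ULBNetConfig(**kw)


def desk_ct_config(**kw) -> ULBNetConfig:
    kw.setdefault("encoder_filters", (4, 8, 16, 32, 64))
    kw.setdefault("decoder_filters", (64, 32, 16, 8, 4))
    kw.setdefault("patch_shape", (64, 64, 16))
    kw.setdefault("learning_rate", 1e-3)
    return ULBNetConfig(**kw)


def desk_us_config(**kw) -> ULBNetConfig:
    kw.setdefault("encoder_filters", (4, 8, 16, 32, 64))
    kw.setdefault("decoder_filters", (64, 32, 16, 8, 4))
    kw.setdefault("patch_shape", (5, 48, 64))
    kw.setdefault("time_axis", 0)
    kw.setdefault("learning_rate", 1e-3)
    return ULBNetConfig(**kw)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _he_init(rng, cout, cin, k=3) -> np.ndarray:
    fan_in = cin * k**3
    return (rng.standard_normal((cout, cin, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv:
    def __init__(self, rng, cin, cout, k=3, stride=(1, 1, 1), name=""):
        self.w = Tensor(_he_init(rng, cout, cin, k), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)
        self.stride = stride
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride)

    def params(self):
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}


class InstanceNorm:
    def __init__(self, channels, name=""):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
        xn = xc / (var + 1e-5).sqrt()
        return xn * self.gamma.reshape(-1, 1, 1, 1) + self.beta.reshape(-1, 1, 1, 1)

    def params(self):
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}


class ResidualBlock:
    """conv-norm-ReLU-conv-norm on a residual branch added to the input
    (1x1x1 projection when channel counts differ).  With all branch
    parameters zeroed the block is the identity."""

    def __init__(self, rng, cin, cout, name=""):
        self.c1 = Conv(rng, cin, cout, name=f"{name}.c1")
        self.n1 = InstanceNorm(cout, name=f"{name}.n1")
        self.c2 = Conv(rng, cout, cout, name=f"{name}.c2")
        self.n2 = InstanceNorm(cout, name=f"{name}.n2")
        self.proj = None if cin == cout else Conv(rng, cin, cout, k=1, name=f"{name}.proj")

    def __call__(self, x: Tensor) -> Tensor:
        h = self.n2(self.c2(self.n1(self.c1(x)).relu()))
        skip = x if self.proj is None else self.proj(x)
        return skip + h

    def params(self):
        out = {}
        for layer in (self.c1, self.n1, self.c2, self.n2, self.proj):
            if layer is not None:
                out.update(layer.params())
        return out


class LBCLayer:
    """Fixed sparse ternary filter bank + ReLU + trainable 1x1x1 combination.

    The fixed filters are drawn once from ``seed`` (each tap is nonzero
    with probability ``sparsity``, sign +-1 equiprobable), carry no bias,
    and are serialised with the model.  Zero input maps to zero output.
    """

    def __init__(self, cin, cout, n_filters=8, sparsity=0.5, seed=0, name=""):
        rng = np.random.default_rng(seed)
        mask = rng.random((n_filters, cin, 3, 3, 3)) < sparsity
        signs = rng.choice([-1.0, 1.0], size=mask.shape)
        self.fixed = Tensor((mask * signs).astype(DTYPE))  # non-trainable
        crng = np.random.default_rng(seed + 1)
        self.combine = Conv(crng, n_filters, cout, k=1, name=f"{name}.combine")
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return self.combine(conv3d(x, self.fixed).relu())

    def params(self):
        return self.combine.params()

    def fixed_filters(self) -> np.ndarray:
        return self.fixed.data


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ULBNet:
    """5-level residual U-Net with LBC skip layers and sigmoid output."""

    def __init__(self, cfg: ULBNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L = cfg.levels
        enc, dec = cfg.encoder_filters, cfg.decoder_filters
        stride = cfg.level_stride()

        self.enc_blocks = [ResidualBlock(rng, 1, enc[0], name="enc0")]
        self.down = []
        for l in range(1, L):
            self.down.append(Conv(rng, enc[l - 1], enc[l], stride=stride, name=f"down{l}"))
            self.enc_blocks.append(ResidualBlock(rng, enc[l], enc[l], name=f"enc{l}"))

        self.lbc = [LBCLayer(enc[l], enc[l], cfg.lbc_filters, cfg.lbc_sparsity,
                             seed=cfg.seed + 100 + l, name=f"lbc{l}") for l in range(L - 1)]
        self.up_conv = []
        self.dec_blocks = []
        for i, l in enumerate(range(L - 2, -1, -1)):
            cin = enc[L - 1] if i == 0 else dec[i]
            self.up_conv.append(Conv(rng, cin, dec[i + 1], name=f"up{l}"))
            self.dec_blocks.append(ResidualBlock(rng, dec[i + 1] + enc[l], dec[i + 1],
                                                 name=f"dec{l}"))
        self.head = Conv(rng, dec[-1], 1, k=1, name="head")
        self._stride = stride

    # -- parameter bookkeeping --------------------------------------------
    def params(self) -> dict:
        out = {}
        for block in (*self.enc_blocks, *self.down, *self.lbc, *self.up_conv,
                      *self.dec_blocks, self.head):
            out.update(block.params())
        return out

    def param_list(self):
        return list(self.params().values())

    # -- forward ------------------------------------------------------------
    def forward(self, patch: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = Tensor(np.asarray(patch, dtype=DTYPE)[None])
        skips = []
        for l in range(self.cfg.levels):
            if l > 0:
                x = self.down[l - 1](x).relu()
            x = self.enc_blocks[l](x).relu()
            if l < self.cfg.levels - 1:
                skips.append(x)
        if train and self.cfg.dropout > 0:
            x = x.dropout(self.cfg.dropout, rng)
        for i, l in enumerate(range(self.cfg.levels - 2, -1, -1)):
            x = upsample_nearest3d(x, self._stride)
            x = self.up_conv[i](x).relu()
            x = engine.concat([x, self.lbc[l](skips[l])], axis=0)
            x = self.dec_blocks[i](x).relu()
            if train and self.cfg.dropout > 0:
                x = x.dropout(self.cfg.dropout, rng)
        return self.head(x).sigmoid()[0]

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        arrays = {k: v.data for k, v in self.params().items()}
        for l, lbc in enumerate(self.lbc):
            arrays[f"lbc{l}.fixed"] = lbc.fixed_filters()
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.cfg.__dict__.items()}
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "ULBNet":
        data = np.load(path, allow_pickle=False)
        cfg_dict = json.loads(str(data["__config__"]))
        for k in ("encoder_filters", "decoder_filters", "patch_shape"):
            cfg_dict[k] = tuple(cfg_dict[k])
        model = cls(ULBNetConfig(**cfg_dict))
        params = model.params()
        for k, v in params.items():
            v.data = data[k]
        for l, lbc in enumerate(model.lbc):
            lbc.fixed.data = data[f"lbc{l}.fixed"]
        return model


def build_ulbnet(cfg: ULBNetConfig) -> ULBNet:
    return ULBNet(cfg)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def _soft_dice(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    t = Tensor(np.asarray(target, dtype=DTYPE))
    inter = (pred * t).sum()
    return (inter * 2.0 + eps) / (pred.sum() + t.sum() + eps)


def train_featurenet(model: ULBNet, images, masks, epochs: int, seed: int = 0,
                     lr: float | None = None):
    """Optimise the negative set-Dice with Adam (batch size 1).

    Returns ``(model, history)`` where ``history[e]`` is the mean training
    loss of epoch ``e``.
    """
    images = list(images)
    masks = list(masks)
    if not images or len(images) != len(masks):
        raise ValueError("need a non-empty, paired training set")
    for m in masks:
        if np.asarray(m).sum() == 0:
            raise ValueError("degenerate training mask (all zero)")
    rng = np.random.default_rng(seed)
    opt = Adam(model.param_list(), lr=lr if lr is not None else model.cfg.learning_rate)
    history = []
    order = np.arange(len(images))
    for _ in range(int(epochs)):
        rng.shuffle(order)
        losses = []
        for i in order:
            opt.zero_grad()
            pred = model.forward(images[i], train=True, rng=rng)
            loss = -_soft_dice(pred, masks[i])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return model, history


def _tile_starts(full: int, patch: int) -> list:
    if full <= patch:
        return [0]
    step = max(1, patch // 2)
    starts = list(range(0, full - patch, step))
    starts.append(full - patch)
    return starts


def predict_featuremap(model: ULBNet, vol, modality: str = "CT") -> FeatureMap:
    """Tile the volume into patches (50% overlap, tapered blending) and
    assemble a probability map on the full grid."""
    values = np.asarray(vol.voxels if hasattr(vol, "voxels") else vol, dtype=DTYPE)
    patch = model.cfg.patch_shape
    pad = [(0, max(0, p - s)) for p, s in zip(patch, values.shape)]
    padded = np.pad(values, pad)
    out = np.zeros(padded.shape, dtype=np.float64)
    wsum = np.zeros(padded.shape, dtype=np.float64)

    def taper(n):
        x = np.linspace(-1.0, 1.0, n)
        return 0.1 + 0.9 * (1.0 - np.abs(x))

    w = taper(patch[0])[:, None, None] * taper(patch[1])[None, :, None] * taper(patch[2])[None, None, :]
    for s0 in _tile_starts(padded.shape[0], patch[0]):
        for s1 in _tile_starts(padded.shape[1], patch[1]):
            for s2 in _tile_starts(padded.shape[2], patch[2]):
                sl = (slice(s0, s0 + patch[0]), slice(s1, s1 + patch[1]), slice(s2, s2 + patch[2]))
                pred = model.forward(padded[sl]).data
                out[sl] += w * pred
                wsum[sl] += w
    blended = (out / wsum)[: values.shape[0], : values.shape[1], : values.shape[2]]
    return FeatureMap(np.clip(blended, 0.0, 1.0), modality)


def seg_metrics(pred_mask, gt_mask) -> tuple:
    """(Dice, sensitivity, specificity) of binary masks, as defined on the
    overlap |Y ∩ Y*| with Y the ground truth and Y* the prediction:
    Dice = 2|∩|/(|Y|+|Y*|), sensitivity = |∩|/|Y|, specificity = |∩|/|Y*|.

    Returns NaNs when both masks are empty.
    """
    p = np.asarray(pred_mask) > 0.5
    g = np.asarray(gt_mask) > 0.5
    if p.shape != g.shape:
        raise ValueError("masks must share a shape")
    inter = float(np.logical_and(p, g).sum())
    np_, ng = float(p.sum()), float(g.sum())
    if np_ == 0 and ng == 0:
        return (float("nan"),) * 3
    dice = 2.0 * inter / (np_ + ng) if (np_ + ng) else float("nan")
    sens = inter / ng if ng else float("nan")
    spec = inter / np_ if np_ else float("nan")
    return dice, sens, spec
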