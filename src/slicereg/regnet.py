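"""Hierarchical 3D-2D rigid registration network.

The network consumes the concatenated CT and US feature volumes on the
canonical paired grid, encodes them with stride-2 convolutions (8, 16, 16
feature maps in the full profile), and decodes with nearest-neighbour
upsampling (16, 16, 16, 16, 8, 8 feature maps).  Four decoder scales —
1/8, 1/4, 1/2 and full resolution — each emit a set of ``6 * Nw`` rigid
transform parameters through a zero-initialised dense head with tanh
activation, so the untrained network performs an exact identity warp.

The per-scale predictions are merged by the hierarchical combination rule:
rotations are scale invariant and averaged; translations are predicted in
the emitting scale's voxel units and summed with weights
{8, 4, 2, 1}/4 = {2, 1, 0.5, 0.25} (coarsest to finest), yielding a
full-resolution-voxel translation that is converted to mm via the grid
spacing.

The decoder has six convolution stages but only four printed combination
weights; here the four transform-emitting scales are 1/8 ... 1/1 and the
two extra decoder stages act as refinement convolutions at the finest
scale before its head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine, geometry
from .engine import Tensor, conv3d, upsample_nearest3d
from .geometry import RigidTransform, Volume3D, WindowTransformSet

__all__ = [
    "RegNetConfig",
    "ScaleTransformStack",
    "RegNet",
    "build_regnet",
    "combine_hierarchical",
    "register_window",
    "desk_regnet_config",
]

DTYPE = np.float32


@dataclass
class RegNetConfig:
    encoder_filters: tuple = (8, 16, 16)
    decoder_filters: tuple = (16, 16, 16, 16, 8, 8)
    n_scales: int = 4
    scale_factors: tuple = (0.125, 0.25, 0.5, 1.0)
    translation_weights: tuple = (2.0, 1.0, 0.5, 0.25)
    emit_scales: tuple = (0, 1, 2, 3)  # indices into scale_factors, coarsest first
    window_size: int = 5
    max_rotation_rad: float = float(np.radians(30.0))
    max_translation_vox: float = 16.0  # at the emitting scale
    learning_rate: float = 3e-4
    head: str = "pool"  # 'pool' (global average) or 'flatten'
    input_shape: tuple | None = None  # required for head='flatten'
    seed: int = 0

    def __post_init__(self):
        if len(self.translation_weights) != self.n_scales:
            raise ValueError("one translation weight per emitting scale is required")
        expected = tuple((1.0 / f) / 4.0 for f in self.scale_factors)
        if not np.allclose(self.translation_weights, expected):
            raise ValueError("translation weights must equal reciprocal scale factors / 4")
        if self.head not in ("pool", "flatten"):
            raise ValueError("head must be 'pool' or 'flatten'")
        if self.head == "flatten" and self.input_shape is None:
            raise ValueError("head='flatten' requires input_shape")
        if self.window_size % 2 != 1:
            raise ValueError("window size must be odd")


def desk_regnet_config(**kw) -> RegNetConfig:
    """Desk-profile network: filter counts scaled down with the grid, with
    a lean finest-resolution tail (the full-resolution convolutions
    dominate CPU cost)."""
    kw.setdefault("encoder_filters", (4, 8, 8))
    kw.setdefault("decoder_filters", (8, 8, 8, 4, 2, 2))
    return RegNetConfig(**kw)


@dataclass
class ScaleTransformStack:
    """Per-scale window transforms, coarsest first; translations are in the
    emitting scale's voxel units."""

    sets: list

    def __post_init__(self):
        sizes = {len(s) for s in self.sets}
        if len(sizes) != 1:
            raise ValueError("all scales must share the window size")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _Head:
    """Spatial pooling (or flatten) + zero-initialised dense + tanh."""

    def __init__(self, cin, cfg: RegNetConfig, spatial=None, name=""):
        self.cfg = cfg
        n_out = 6 * cfg.window_size
        n_in = cin if cfg.head == "pool" else cin * int(np.prod(spatial))
        self.w = Tensor(np.zeros((n_in, n_out), dtype=DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        if self.cfg.head == "pool":
            feat = x.mean(axis=(1, 2, 3)).reshape(1, -1)
        else:
            feat = x.reshape(1, -1)
        return self.from_features(feat)

    def from_features(self, feat: Tensor) -> Tensor:
        raw = (feat @ self.w + self.b.reshape(1, -1)).tanh().reshape(self.cfg.window_size, 6)
        scale = np.concatenate([
            np.full(3, self.cfg.max_rotation_rad, dtype=DTYPE),
            np.full(3, self.cfg.max_translation_vox, dtype=DTYPE),
        ])
        return raw * Tensor(scale.reshape(1, 6))

    def params(self):
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}


class RegNet:
    def __init__(self, cfg: RegNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)

        def he(cout, cin, k=3):
            fan = cin * k**3
            return Tensor((rng.standard_normal((cout, cin, k, k, k))
                           * np.sqrt(2.0 / fan)).astype(DTYPE), requires_grad=True)

        enc, dec = cfg.encoder_filters, cfg.decoder_filters
        self.enc_w = []
        self.enc_b = []
        cin = 2
        for f in enc:
            self.enc_w.append(he(f, cin))
            self.enc_b.append(Tensor(np.zeros(f, dtype=DTYPE), requires_grad=True))
            cin = f
        self.dec_w = []
        self.dec_b = []
        for f in dec:
            self.dec_w.append(he(f, cin))
            self.dec_b.append(Tensor(np.zeros(f, dtype=DTYPE), requires_grad=True))
            cin = f
        # decoder stage index at which each emitting scale's head sits:
        # stages 0,1,2 handle scales 1/8,1/4,1/2; stages 3..5 refine at 1/1
        self._head_stage = {0: 0, 1: 1, 2: 2, 3: len(dec) - 1}
        spatial_div = {0: 8, 1: 4, 2: 2, 3: 1}
        self.heads = []
        for s in cfg.emit_scales:
            stage = self._head_stage[s]
            spatial = None
            if cfg.head == "flatten":
                spatial = tuple(int(n // spatial_div[s]) for n in cfg.input_shape)
            self.heads.append(_Head(dec[stage], cfg, spatial=spatial, name=f"head{s}"))

    def params(self) -> dict:
        out = {}
        for i, (w, b) in enumerate(zip(self.enc_w, self.enc_b)):
            out[f"enc{i}.w"] = w
            out[f"enc{i}.b"] = b
        for i, (w, b) in enumerate(zip(self.dec_w, self.dec_b)):
            out[f"dec{i}.w"] = w
            out[f"dec{i}.b"] = b
        for h in self.heads:
            out.update(h.params())
        return out

    def param_list(self):
        return list(self.params().values())

    def forward(self, ct_feat: np.ndarray, us_feat: np.ndarray) -> list:
        """Per-scale (Nw, 6) parameter Tensors, coarsest first: rotations in
        radians, translations in the emitting scale's voxel units."""
        if ct_feat.shape != us_feat.shape:
            raise ValueError("paired volumes must share a shape")
        for n in ct_feat.shape:
            if n % 8 != 0:
                raise ValueError("paired dims must be divisible by 8 "
                                 f"(got {ct_feat.shape})")
        x = Tensor(np.stack([np.asarray(ct_feat, dtype=DTYPE),
                             np.asarray(us_feat, dtype=DTYPE)]))
        for w, b in zip(self.enc_w, self.enc_b):
            x = conv3d(x, w, b, stride=(2, 2, 2)).relu()
        outputs = {}
        emit_set = {self._head_stage[s]: i for i, s in enumerate(self.cfg.emit_scales)}
        for stage, (w, b) in enumerate(zip(self.dec_w, self.dec_b)):
            if stage in (1, 2, 3):  # upsample before stages at 1/4, 1/2, 1/1
                x = upsample_nearest3d(x, (2, 2, 2))
            x = conv3d(x, w, b).relu()
            if stage in emit_set:
                outputs[emit_set[stage]] = self.heads[emit_set[stage]](x)
        return [outputs[i] for i in range(len(self.cfg.emit_scales))]

    def head_features(self, ct_feat: np.ndarray, us_feat: np.ndarray) -> list:
        """The per-scale head input vectors (pooled or flattened decoder
        features) as plain arrays.  With the convolutional trunk frozen
        these are constant per input pair and can be cached, making
        head-only adaptation steps cheap."""
        x = Tensor(np.stack([np.asarray(ct_feat, dtype=DTYPE),
                             np.asarray(us_feat, dtype=DTYPE)]))
        for w, b in zip(self.enc_w, self.enc_b):
            x = conv3d(x, Tensor(w.data), Tensor(b.data), stride=(2, 2, 2)).relu()
        feats = {}
        emit_set = {self._head_stage[s]: i for i, s in enumerate(self.cfg.emit_scales)}
        for stage, (w, b) in enumerate(zip(self.dec_w, self.dec_b)):
            if stage in (1, 2, 3):
                x = upsample_nearest3d(x, (2, 2, 2))
            x = conv3d(x, Tensor(w.data), Tensor(b.data)).relu()
            if stage in emit_set:
                if self.cfg.head == "pool":
                    feats[emit_set[stage]] = x.data.mean(axis=(1, 2, 3)).reshape(1, -1)
                else:
                    feats[emit_set[stage]] = x.data.reshape(1, -1)
        return [feats[i] for i in range(len(self.cfg.emit_scales))]

    def params_from_head_features(self, feats, spacing) -> Tensor:
        """Combined (Nw, 6) parameters from cached head features;
        differentiable in the head weights and biases."""
        outs = [h.from_features(Tensor(f)) for h, f in zip(self.heads, feats)]
        return combine_params_t(outs, self.cfg, spacing)

    def combined_params(self, ct_feat, us_feat, spacing) -> Tensor:
        """(Nw, 6) Tensor of combined rotations (rad) and translations (mm),
        differentiable end to end."""
        return combine_params_t(self.forward(ct_feat, us_feat), self.cfg, spacing)

    # -- persistence -------------------------------------------------------
    def save(self, path):
        import json

        arrays = {k: v.data for k, v in self.params().items()}
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.cfg.__dict__.items()}
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "RegNet":
        import json

        data = np.load(path, allow_pickle=False)
        cfg_dict = json.loads(str(data["__config__"]))
        for k in ("encoder_filters", "decoder_filters", "scale_factors",
                  "translation_weights", "emit_scales"):
            cfg_dict[k] = tuple(cfg_dict[k])
        if cfg_dict.get("input_shape") is not None:
            cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        model = cls(RegNetConfig(**cfg_dict))
        for k, v in model.params().items():
            v.data = data[k]
        return model

    def copy(self) -> "RegNet":
        clone = RegNet(self.cfg)
        for (_, a), (_, b) in zip(sorted(clone.params().items()), sorted(self.params().items())):
            a.data = b.data.copy()
        return clone


def build_regnet(cfg: RegNetConfig) -> RegNet:
    return RegNet(cfg)


# ---------------------------------------------------------------------------
# Hierarchical combination
# ---------------------------------------------------------------------------

def combine_params_t(scale_params: list, cfg: RegNetConfig, spacing) -> Tensor:
    """Merge per-scale (Nw, 6) Tensors: mean rotation, weighted-sum
    translation in full-resolution voxels, converted to mm."""
    if len(scale_params) != len(cfg.emit_scales):
        raise ValueError("one parameter set per emitting scale is required")
    spacing = np.asarray(spacing, dtype=float)
    weights = [cfg.translation_weights[s] for s in cfg.emit_scales]
    rot = None
    trans = None
    for p, w in zip(scale_params, weights):
        r = p[:, 0:3]
        t = p[:, 3:6] * w
        rot = r if rot is None else rot + r
        trans = t if trans is None else trans + t
    rot = rot * (1.0 / len(scale_params))
    trans = trans * Tensor(spacing.reshape(1, 3))
    return engine.concat([rot, trans], axis=1)


def combine_hierarchical(stack: ScaleTransformStack, cfg: RegNetConfig,
                         spacing=(1.0, 1.0, 1.0)) -> WindowTransformSet:
    """Numpy-level view of the combination rule for explicit transform
    stacks (translations in per-scale voxel units)."""
    arrays = [Tensor(np.stack([t.parameters for t in s])) for s in stack]
    combined = combine_params_t(arrays, cfg, spacing).data
    return WindowTransformSet([RigidTransform(row[:3], row[3:]) for row in combined])


def register_window(model: RegNet, ct_feat, us_feat, spacing=None):
    """Forward pass + hierarchical combination + per-frame warps.

    Returns ``(WindowTransformSet, warped CT feature volumes)``; transforms
    are relative to the pre-aligned pose (centroid alignment happens
    upstream) with rotations about the grid centre.
    """
    ct_vals = np.asarray(ct_feat.voxels if hasattr(ct_feat, "voxels") else ct_feat)
    us_vals = np.asarray(us_feat.voxels if hasattr(us_feat, "voxels") else us_feat)
    if spacing is None:
        spacing = ct_feat.spacing if hasattr(ct_feat, "spacing") else np.ones(3)
    params = model.combined_params(ct_vals, us_vals, spacing).data
    transforms = WindowTransformSet([RigidTransform(row[:3], row[3:]) for row in params])
    vol = Volume3D(ct_vals, np.asarray(spacing, dtype=float))
    warped = [geometry.resample_rigid(vol, t) for t in transforms]
    return transforms, warped
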