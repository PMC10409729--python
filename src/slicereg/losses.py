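"""The feature-image-motion (FIM) registration objective.

The objective that drives the 3D-2D registration network combines three
terms evaluated on one ultrasound time window of ``Nw`` frames with
per-frame rigid transforms ``D_i``:

* **feature loss** — negative windowed elementwise Dice between the fixed
  US kidney probability maps and the middle RL slice of the CT probability
  map warped by each frame's transform;
* **image loss** — mean absolute difference of MIND descriptors between
  the fixed US window volume and the warped, kidney-masked CT volume,
  restricted to the middle RL slice;
* **motion loss** — a weighted sum of the mean Frobenius deviation of the
  per-frame transform matrices from identity and the mean second difference
  of consecutive transforms (breathing-smoothness regulariser).

Total: ``L = L_f + lambda1 * L_i + lambda2 * L_d`` with the empirical
weights ``lambda1 = 0.01`` and ``lambda2 = 0.001``.

MIND (modality-independent neighbourhood descriptor) encodes per-voxel
self-similarity: for each of the six face-neighbour displacements ``r`` the
channel value is ``exp(-D_p(x, r) / V(x))`` where ``D_p`` is the mean
squared difference between the 3x3x3 patch at ``x`` and at ``x + r`` and
``V(x)`` is the mean of the six patch distances (floored to stay positive).
Channels are normalised so the per-voxel maximum is exactly one.  Because
of the per-voxel variance normalisation the descriptor is invariant to
affine intensity remaps, which is what makes the CT-US comparison
meaningful.

All operations here run on :class:`slicereg.engine.Tensor` and are
differentiable with respect to the transform parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine, geometry
from .engine import Tensor

__all__ = [
    "FimWeights",
    "FimBreakdown",
    "WindowWarper",
    "mind_descriptor",
    "elementwise_dice",
    "feature_loss",
    "image_loss",
    "transform_loss",
    "fim_loss",
]

DISPLACEMENTS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass
class FimWeights:
    """Loss mixing weights (the full-profile defaults)."""

    lambda1: float = 0.01
    lambda2: float = 0.001
    transform_mix: tuple = (0.01, 0.99)

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or min(self.transform_mix) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class FimBreakdown:
    total: Tensor
    feature: Tensor
    image: Tensor
    motion: Tensor

    def as_dict(self) -> dict:
        return {
            "total": self.total.item(),
            "feature": self.feature.item(),
            "image": self.image.item(),
            "motion": self.motion.item(),
        }


# ---------------------------------------------------------------------------
# MIND descriptor
# ---------------------------------------------------------------------------

def _shift3(x: Tensor, r) -> Tensor:
    """Edge-replicated shift: out(y) = x(clip(y + r)).

    Replication (rather than zero fill) keeps patch differences zero on
    constant images, so boundary voxels behave like interior ones.
    """
    idx = tuple(np.clip(np.arange(n) + d, 0, n - 1) for n, d in zip(x.shape, r))
    return x[np.ix_(*idx)]


def _box3(x: Tensor) -> Tensor:
    """3x3x3 edge-replicated box mean (separable)."""
    for axis in range(3):
        r_plus = [0, 0, 0]
        r_minus = [0, 0, 0]
        r_plus[axis] = 1
        r_minus[axis] = -1
        x = (x + _shift3(x, tuple(r_plus)) + _shift3(x, tuple(r_minus))) * (1.0 / 3.0)
    return x


def _floor_at(x: Tensor, eps: float) -> Tensor:
    return (x - eps).relu() + eps


def mind_descriptor(vol, eps_scale: float = 1e-6, eps: float | None = None) -> Tensor:
    """Six-channel MIND descriptor of a (D, H, W) volume.

    Returns a (6, D, H, W) tensor with all values in (0, 1] and per-voxel
    channel maximum exactly 1.  Boundary samples are edge-replicated so a
    constant image yields a unit descriptor everywhere.  The variance floor
    is ``eps_scale`` times the squared dynamic range, or the explicit
    ``eps`` when given (callers inside the training graph pass a floor
    derived from the *unwarped* image so the floor does not move with the
    transform parameters).
    """
    vol = engine.tensor(vol)
    if eps is None:
        rng2 = float(np.ptp(vol.data) ** 2)
        eps = eps_scale * max(rng2, 1e-30)
    dists = []
    for r in DISPLACEMENTS:
        diff = vol - _shift3(vol, r)
        dists.append(_box3(diff * diff))
    dp = engine.stack(dists, axis=0)  # (6, D, H, W)
    v = _floor_at(dp.mean(axis=0, keepdims=True), eps)
    c = (-(dp / v)).exp()
    return c / c.max(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Elementwise Dice (used only inside the feature loss)
# ---------------------------------------------------------------------------

def elementwise_dice(x, y, eps: float = 1e-6) -> Tensor:
    """Mean over elements of 2xy / (x + y + eps); inputs in [0, 1]."""
    x, y = engine.tensor(x), engine.tensor(y)
    return ((x * y * 2.0) / (x + y + eps)).mean()


# ---------------------------------------------------------------------------
# Warping helper for the canonical paired grid
# ---------------------------------------------------------------------------

@dataclass
class WindowWarper:
    """Samples warped CT slices/slabs on the canonical paired grid.

    The US window occupies RL indices centred at ``shape[0] // 2``; frame
    ``i`` of an ``Nw`` window lives at RL index ``mid - (Nw-1)/2 + i``.
    """

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray = None
    window_size: int = 5

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        self.mid = self.shape[0] // 2
        self.centre = self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing
        self._plane_cache = {}

    def frame_rl_index(self, i: int) -> int:
        return self.mid - (self.window_size - 1) // 2 + i

    def _plane_pts(self, rl_indices) -> np.ndarray:
        key = tuple(rl_indices)
        if key not in self._plane_cache:
            _, H, W = self.shape
            jj, kk = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            pts = []
            for rl in rl_indices:
                idx = np.stack([np.full(jj.size, float(rl)), jj.ravel(), kk.ravel()])
                pts.append(idx)
            idx = np.concatenate(pts, axis=1)
            self._plane_cache[key] = self.origin[:, None] + idx * self.spacing[:, None]
        return self._plane_cache[key]

    def warp_planes(self, vol_t: Tensor, params: Tensor, rl_indices) -> Tensor:
        """Warp ``vol_t`` by the rigid ``params`` (6,) and extract the given
        constant-RL planes; returns (len(rl_indices), H, W)."""
        pts = self._plane_pts(rl_indices)
        coords = geometry.warp_source_coords_t(params, pts, self.centre,
                                               self.origin, self.spacing)
        vals = engine.trilinear_sample(vol_t, coords)
        return vals.reshape(len(rl_indices), self.shape[1], self.shape[2])

    def warp_middle_slice(self, vol_t: Tensor, params: Tensor) -> Tensor:
        return self.warp_planes(vol_t, params, [self.mid])[0]

    def warp_middle_slab(self, vol_t: Tensor, params: Tensor, half: int = 2) -> Tensor:
        return self.warp_planes(vol_t, params, list(range(self.mid - half, self.mid + half + 1)))


def _params_tensor(w) -> Tensor:
    """Accept a (Nw, 6) Tensor/array or a WindowTransformSet."""
    if isinstance(w, Tensor):
        return w
    if isinstance(w, geometry.WindowTransformSet):
        return Tensor(np.stack([t.parameters for t in w]))
    return Tensor(np.asarray(w, dtype=float))


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def feature_loss(m_fix_vol, m_mov_vol, w, warper: WindowWarper, eps: float = 1e-6,
                 dice: str = "elementwise") -> Tensor:
    """Negative mean windowed Dice between warped CT and US feature maps.

    ``m_fix_vol`` is the embedded US feature window volume, ``m_mov_vol``
    the CT feature map on the same grid; frame ``i`` of the window is
    compared against the middle RL slice of the CT map warped by ``D_i``.

    ``dice`` selects the per-slice similarity: ``"elementwise"`` is the
    mean of 2xy/(x+y) over pixels; ``"set"`` is the soft set Dice
    2·sum(xy)/(sum(x)+sum(y)).  The elementwise form is monotonically
    increasing in the warped map wherever the fixed map is positive, so
    it rewards *covering* the fixed kidney rather than matching it and
    its optimum need not be the true pose; the set form penalises excess
    mass through its denominator and is the recommended training
    objective (see the methods note).
    """
    params = _params_tensor(w)
    nw = params.shape[0]
    if nw != warper.window_size:
        raise ValueError("window size mismatch between transforms and warper")
    if dice not in ("elementwise", "set"):
        raise ValueError("dice must be 'elementwise' or 'set'")
    m_fix = np.asarray(m_fix_vol.voxels if hasattr(m_fix_vol, "voxels") else m_fix_vol)
    mov_t = engine.tensor(m_mov_vol.voxels if hasattr(m_mov_vol, "voxels") else m_mov_vol)
    total = None
    for i in range(nw):
        warped_slice = warper.warp_middle_slice(mov_t, params[i])
        fix_slice = Tensor(m_fix[warper.frame_rl_index(i)])
        if dice == "elementwise":
            d = elementwise_dice(fix_slice, warped_slice, eps)
        else:
            d = ((fix_slice * warped_slice).sum() * 2.0 + eps) / \
                (fix_slice.sum() + warped_slice.sum() + eps)
        total = d if total is None else total + d
    return -(total * (1.0 / nw))


def image_loss(i_fix_vol, i_mov_vol, m_mov_vol, w, warper: WindowWarper,
               mind_fix: Tensor | None = None, slab_half: int = 2) -> Tensor:
    """Mean absolute MIND difference on the middle RL slice.

    The CT volume is masked by its feature map (elementwise product) before
    warping by the middle frame's transform; descriptors are computed on a
    thin slab so the middle slice sees full 3D neighbourhoods.
    """
    params = _params_tensor(w)
    mid_params = params[warper.window_size // 2]
    i_mov = np.asarray(i_mov_vol.voxels if hasattr(i_mov_vol, "voxels") else i_mov_vol)
    m_mov = np.asarray(m_mov_vol.voxels if hasattr(m_mov_vol, "voxels") else m_mov_vol)
    masked_arr = i_mov * m_mov
    masked = engine.tensor(masked_arr)
    eps = 1e-6 * max(float(np.ptp(masked_arr) ** 2), 1e-30)
    warped_slab = warper.warp_middle_slab(masked, mid_params, half=slab_half)
    mind_mov = mind_descriptor(warped_slab, eps=eps)
    if mind_fix is None:
        mind_fix = fixed_mind_slab(i_fix_vol, warper, slab_half)
    diff = (mind_mov[:, slab_half] - mind_fix[:, slab_half]).abs()
    return diff.mean()


def fixed_mind_slab(i_fix_vol, warper: WindowWarper, slab_half: int = 2) -> Tensor:
    """MIND of the fixed US window volume on the middle RL slab (cacheable)."""
    i_fix = np.asarray(i_fix_vol.voxels if hasattr(i_fix_vol, "voxels") else i_fix_vol)
    slab = i_fix[warper.mid - slab_half : warper.mid + slab_half + 1]
    return mind_descriptor(Tensor(slab)).detach()


def transform_loss(w, translation_scale: float = 1.0,
                   mix: tuple = (0.01, 0.99)) -> Tensor:
    """Motion regulariser: mix[0] * mean deviation-from-identity of the
    transform matrices + mix[1] * mean second-difference norm (gradD).

    Requires ``Nw >= 3`` (the second difference is undefined otherwise).
    Translations are divided by ``translation_scale`` inside the matrices
    so rotation and translation entries are commensurate.
    """
    params = _params_tensor(w)
    nw = params.shape[0]
    if nw < 3:
        raise ValueError("transform_loss requires a window of at least 3 frames")
    eye = Tensor(np.eye(4))
    mats = [geometry.matrix_t(params[i], translation_scale) for i in range(nw)]

    def fro(m: Tensor) -> Tensor:
        return (m * m).sum().sqrt(eps=1e-24)

    dist = None
    for m in mats:
        d = fro(m - eye)
        dist = d if dist is None else dist + d
    dist = dist * (1.0 / nw)

    grad_d = None
    for i in range(1, nw - 1):
        g = fro(mats[i + 1] + mats[i - 1] - mats[i] * 2.0)
        grad_d = g if grad_d is None else grad_d + g
    grad_d = grad_d * (1.0 / (nw - 2))
    return dist * mix[0] + grad_d * mix[1]


def fim_loss(i_fix, i_mov, m_fix, m_mov, w, warper: WindowWarper,
             weights: FimWeights | None = None,
             translation_scale: float | None = None,
             mind_fix: Tensor | None = None,
             feature_dice: str = "elementwise") -> FimBreakdown:
    """Assemble the full FIM objective; returns the total and the terms."""
    if weights is None:
        weights = FimWeights()
    if translation_scale is None:
        translation_scale = float(warper.spacing[0])
    params = _params_tensor(w)
    lf = feature_loss(m_fix, m_mov, params, warper, dice=feature_dice)
    li = image_loss(i_fix, i_mov, m_mov, params, warper, mind_fix=mind_fix)
    ld = transform_loss(params, translation_scale, weights.transform_mix)
    total = lf + li * weights.lambda1 + ld * weights.lambda2
    return FimBreakdown(total=total, feature=lf, image=li, motion=ld)
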