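"""Rigid-transform algebra and rigid resampling on regular voxel grids.

Conventions used throughout the package:

* Axis order is (RL, AP, IS) — right-left, anterior-posterior,
  inferior-superior ("RAI" orientation).  Sagittal planes are constant-RL
  slices.
* A :class:`RigidTransform` holds three Euler angles (radians) applied as
  intrinsic rotations in axis order RL -> AP -> IS about a centre point
  (defaulting to the grid centre), plus a translation in mm.
* Grid points are voxel centres; ``world = origin + index * spacing`` with
  0-based indices.
* ``resample_rigid(vol, T)`` moves the *content* of ``vol`` by ``T``:
  ``out(x) = vol(T^{-1} x)`` (pull-back sampling), with zero fill outside
  the volume.

The Euler convention is a package choice — any fixed convention works as
long as simulation, training and evaluation share it — and is isolated in
:func:`euler_to_matrix` / :func:`matrix_to_euler`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .engine import Tensor

__all__ = [
    "RigidTransform",
    "WindowTransformSet",
    "Volume3D",
    "euler_to_matrix",
    "matrix_to_euler",
    "to_matrix",
    "from_matrix",
    "compose",
    "invert",
    "resample_rigid",
    "transform_distance",
    "poses_to_table",
    "table_to_poses",
    "matrix_to_text",
    "matrix_from_text",
]


# ---------------------------------------------------------------------------
# Euler <-> matrix
# ---------------------------------------------------------------------------

def _rot_axis(angle: float, axis: int) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s if axis != 1 else s
    m[j, i] = s if axis != 1 else -s
    return m


def euler_to_matrix(angles) -> np.ndarray:
    """Intrinsic rotations about RL, AP, IS in that order: R = R0·R1·R2."""
    a, b, c = angles
    return _rot_axis(a, 0) @ _rot_axis(b, 1) @ _rot_axis(c, 2)


def matrix_to_euler(r: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix` (angles in (-pi, pi])."""
    b = np.arcsin(np.clip(r[0, 2], -1.0, 1.0))
    if abs(np.cos(b)) > 1e-8:
        a = np.arctan2(-r[1, 2], r[2, 2])
        c = np.arctan2(-r[0, 1], r[0, 0])
    else:  # gimbal lock: fold everything into the first angle
        a = np.arctan2(r[2, 1], r[1, 1])
        c = 0.0
    return np.array([a, b, c])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """A 6-parameter rigid pose: rotation (rad), translation (mm), centre (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    centre: np.ndarray | None = None

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.centre is not None:
            self.centre = np.asarray(self.centre, dtype=float)

    @classmethod
    def identity(cls, centre=None) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), centre)

    @property
    def parameters(self) -> np.ndarray:
        """(6,) vector: 3 rotations (rad), 3 translations (mm)."""
        return np.concatenate([self.rotation, self.translation])

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.parameters) <= tol))


@dataclass
class WindowTransformSet:
    """Per-frame rigid poses for one US time window (odd length)."""

    transforms: list
    window_size: int = 0

    def __post_init__(self):
        self.transforms = list(self.transforms)
        if self.window_size == 0:
            self.window_size = len(self.transforms)
        if len(self.transforms) != self.window_size:
            raise ValueError("length of transforms must equal window_size")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")

    def __len__(self):
        return self.window_size

    def __iter__(self):
        return iter(self.transforms)

    def __getitem__(self, i):
        return self.transforms[i]

    @property
    def middle_index(self) -> int:
        return (self.window_size - 1) // 2

    @property
    def middle(self) -> RigidTransform:
        return self.transforms[self.middle_index]


@dataclass
class Volume3D:
    """A scalar voxel grid in RAI orientation with physical spacing (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.array([0.8, 0.8, 0.8]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: str = "RAI"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.orientation != "RAI":
            raise ValueError("only RAI orientation is supported")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def centre_mm(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin[:, None] + np.asarray(idx, dtype=float) * self.spacing[:, None]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin[:, None]) / self.spacing[:, None]

    def like(self, voxels: np.ndarray) -> "Volume3D":
        return Volume3D(voxels, self.spacing.copy(), self.origin.copy())

    # -- NIfTI IO ----------------------------------------------------------
    def to_nifti(self, path):
        import nibabel as nib

        affine = np.diag(np.concatenate([self.spacing, [1.0]]))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume3D":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)


# ---------------------------------------------------------------------------
# Transform algebra
# ---------------------------------------------------------------------------

def to_matrix(t: RigidTransform, translation_scale: float = 1.0) -> np.ndarray:
    """4x4 homogeneous matrix view of a rigid transform.

    ``translation_scale`` divides the translation column so rotation and
    translation entries are commensurate in norms (used by the transform
    loss); the default leaves translations in mm.
    """
    r = euler_to_matrix(t.rotation)
    c = np.zeros(3) if t.centre is None else t.centre
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = (t.translation + c - r @ c) / translation_scale
    return m


def from_matrix(m: np.ndarray, centre=None) -> RigidTransform:
    """Recover a RigidTransform (with the given centre convention) from a matrix."""
    r = m[:3, :3]
    rot = matrix_to_euler(r)
    c = np.zeros(3) if centre is None else np.asarray(centre, dtype=float)
    trans = m[:3, 3] - c + r @ c
    return RigidTransform(rot, trans, None if centre is None else c)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``b`` first, then ``a`` (matrix product A·B)."""
    ca = np.zeros(3) if a.centre is None else a.centre
    cb = np.zeros(3) if b.centre is None else b.centre
    if not np.allclose(ca, cb):
        raise ValueError("compose requires a shared centre convention")
    m = to_matrix(a) @ to_matrix(b)
    return from_matrix(m, centre=a.centre if a.centre is not None else b.centre)


def invert(t: RigidTransform) -> RigidTransform:
    r = euler_to_matrix(t.rotation)
    rot = matrix_to_euler(r.T)
    return RigidTransform(rot, -(r.T @ t.translation), t.centre)


def transform_distance(w: WindowTransformSet, translation_scale: float = 1.0) -> float:
    """Mean Frobenius deviation from identity, (1/Nw)·sum_i ||M(D_i) − I||_F."""
    total = 0.0
    for t in w:
        total += np.linalg.norm(to_matrix(t, translation_scale) - np.eye(4))
    return total / len(w)


# ---------------------------------------------------------------------------
# Rigid resampling (the STN contract)
# ---------------------------------------------------------------------------

def _sample_points(vol: Volume3D, pts_world: np.ndarray, interpolation: str) -> np.ndarray:
    idx = vol.world_to_index(pts_world)
    v = np.asarray(vol.voxels, dtype=float)
    D, H, W = v.shape
    if interpolation == "nearest":
        ii = np.round(idx).astype(np.int64)
        valid = np.all((ii >= 0) & (ii < np.array([[D], [H], [W]])), axis=0)
        ii = np.clip(ii, 0, np.array([[D - 1], [H - 1], [W - 1]]))
        out = np.where(valid, v[ii[0], ii[1], ii[2]], 0.0)
        return out
    if interpolation == "linear":
        return engine.trilinear_sample(Tensor(v), Tensor(idx)).data
    raise ValueError(f"unknown interpolation {interpolation!r}")


def resample_rigid(vol: Volume3D, t: RigidTransform, interpolation: str = "linear") -> Volume3D:
    """Warp the content of ``vol`` by ``t`` onto the same grid, zero-filled."""
    if not np.all(np.isfinite(vol.voxels)):
        raise ValueError("volume contains non-finite voxels")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    centre = t.centre if t.centre is not None else vol.centre_mm
    tc = RigidTransform(t.rotation, t.translation, centre)
    minv = to_matrix(invert(tc))
    idx = np.indices(vol.shape, dtype=float).reshape(3, -1)
    pts = vol.index_to_world(idx)
    src = minv[:3, :3] @ pts + minv[:3, 3:4]
    out = _sample_points(vol, src, interpolation)
    return vol.like(out.reshape(vol.shape))


# ---------------------------------------------------------------------------
# Differentiable transform pieces (used inside the training graph)
# ---------------------------------------------------------------------------

def rotation_matrix_t(angles: Tensor) -> Tensor:
    """(3,) Euler-angle Tensor -> (3, 3) rotation matrix Tensor (same convention)."""
    rows = []
    a, b, c = angles[0], angles[1], angles[2]
    ca, sa = a.cos(), a.sin()
    cb, sb = b.cos(), b.sin()
    cc, sc = c.cos(), c.sin()
    # R = R0(a)·R1(b)·R2(c), expanded to avoid building tiny matmul chains
    rows.append(engine.stack([cb * cc, -(cb * sc), sb]))
    rows.append(engine.stack([ca * sc + sa * sb * cc, ca * cc - sa * sb * sc, -(sa * cb)]))
    rows.append(engine.stack([sa * sc - ca * sb * cc, sa * cc + ca * sb * sc, ca * cb]))
    return engine.stack(rows, axis=0)


def warp_source_coords_t(params: Tensor, pts_world: np.ndarray, centre: np.ndarray,
                         origin: np.ndarray, spacing: np.ndarray) -> Tensor:
    """Fractional voxel coordinates at which a volume warped by ``params``
    is sampled for output points ``pts_world`` (pull-back: applies the
    inverse transform), differentiable in the 6 rigid ``params``.
    """
    rot = rotation_matrix_t(params[0:3])
    rinv = rot.transpose()
    trans = params[3:6]
    centre_t = Tensor(np.asarray(centre, dtype=float))
    pts = Tensor(np.asarray(pts_world, dtype=float))
    # T^{-1} x = R^T (x - c - t) + c
    shifted = pts - (centre_t + trans).reshape(3, 1)
    src = rinv @ shifted + centre_t.reshape(3, 1)
    return (src - Tensor(np.asarray(origin, dtype=float)).reshape(3, 1)) \
        * Tensor(1.0 / np.asarray(spacing, dtype=float)).reshape(3, 1)


def matrix_t(params: Tensor, translation_scale: float = 1.0) -> Tensor:
    """Differentiable 4x4 matrix view of a (6,) parameter Tensor (centre 0)."""
    rot = rotation_matrix_t(params[0:3])
    trans = (params[3:6] * (1.0 / translation_scale)).reshape(3, 1)
    top = engine.concat([rot, trans], axis=1)
    bottom = Tensor(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return engine.concat([top, bottom], axis=0)


# ---------------------------------------------------------------------------
# Plain-text serialisation
# ---------------------------------------------------------------------------

def poses_to_table(poses, frames=None) -> pd.DataFrame:
    """One row per frame: rotations in degrees, translations in mm."""
    if frames is None:
        frames = list(range(len(poses)))
    rows = []
    for f, t in zip(frames, poses):
        rot = np.degrees(t.rotation)
        rows.append({
            "frame": int(f),
            "rot_rl_deg": rot[0], "rot_ap_deg": rot[1], "rot_is_deg": rot[2],
            "trans_rl_mm": t.translation[0], "trans_ap_mm": t.translation[1],
            "trans_is_mm": t.translation[2],
        })
    return pd.DataFrame(rows)


def matrix_to_text(t: RigidTransform, path, translation_scale: float = 1.0):
    """Write the 4x4 homogeneous matrix view as a plain-text table."""
    np.savetxt(path, to_matrix(t, translation_scale), fmt="%.10g")


def matrix_from_text(path, centre=None) -> RigidTransform:
    return from_matrix(np.loadtxt(path), centre=centre)


def table_to_poses(df: pd.DataFrame, centre=None):
    poses = []
    for _, row in df.iterrows():
        rot = np.radians([row.rot_rl_deg, row.rot_ap_deg, row.rot_is_deg])
        trans = np.array([row.trans_rl_mm, row.trans_ap_mm, row.trans_is_mm])
        poses.append(RigidTransform(rot, trans, centre))
    return poses
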