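"""Synthetic breathing-kidney phantoms with known ground-truth poses.

Clinical 3D CT / 2D US kidney pairs are not publicly available, so the
pipeline is exercised on phantoms: an ellipsoidal "kidney" with smooth
internal texture inside a darker background volume, and an ultrasound-like
sagittal slice sequence of that kidney under periodic rigid breathing
motion.

The breathing model is a per-axis sinusoid in translation plus small
sinusoidal rotations — the simplest periodic model reproducing the two
motion components visible in free-breathing kidney scans (a dominant
inferior-superior excursion and a smaller anterior-posterior "back and
forth").  US appearance is emulated with a gamma intensity remap (so CT
and US intensities are *not* linearly related and the multimodal machinery
has real work to do), a mild Gaussian blur, and multiplicative log-normal
speckle.  Acoustic effects (shadowing, rib occlusion) and organ
deformation are out of scope.

Every frame's rigid pose is recorded exactly, which gives the registration
benchmark its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RigidTransform, Volume3D, resample_rigid

__all__ = [
    "PhantomSpec",
    "RespirationModel",
    "PhantomSample",
    "make_ct_phantom",
    "simulate_us_sequence",
    "save_sample",
    "desk_spec",
]

#: desk-profile grid: the full clinical-scale 128 x 224 x 288 at 0.8 mm divided by 4
DESK_SHAPE = (32, 56, 72)
DESK_SPACING = 3.2
FULL_SHAPE = (128, 224, 288)
FULL_SPACING = 0.8


@dataclass
class Lesion:
    centre_offset_mm: np.ndarray  # relative to kidney centre
    radius_mm: float
    intensity_offset: float


@dataclass
class PhantomSpec:
    """Geometry and appearance of one synthetic CT kidney volume."""

    shape: tuple = DESK_SHAPE
    spacing: float = DESK_SPACING
    semi_axes_mm: np.ndarray = field(default_factory=lambda: np.array([20.0, 25.0, 45.0]))
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    texture_amplitude: float = 0.2
    background_intensity: float = 0.2
    kidney_intensity: float = 1.0
    lesion: Lesion | None = None
    #: relative size of an off-axis protrusion merged with the ellipsoid
    #: (0 = exact ellipsoid).  A pure ellipsoid leaves the *sign* of
    #: out-of-plane tilts unobservable from one sagittal cross-section
    #: (mirror symmetry); real kidneys are bean-shaped, and the bump makes
    #: the full rigid pose identifiable from the slice.
    asymmetry: float = 0.0

    @property
    def spacing_vec(self) -> np.ndarray:
        return np.full(3, float(self.spacing))


@dataclass
class RespirationModel:
    """Periodic rigid breathing motion: per-axis sinusoids.

    Amplitudes are half peak-to-peak excursions.  Defaults emulate quiet
    free breathing: a dominant inferior-superior translation of a few mm,
    a smaller anterior-posterior component, and degree-scale rotations.
    """

    period: int = 10
    translation_amplitude_mm: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.5, 5.0]))
    rotation_amplitude_deg: np.ndarray = field(default_factory=lambda: np.array([2.0, 0.5, 0.5]))
    phase: float = 0.0

    def __post_init__(self):
        self.translation_amplitude_mm = np.asarray(self.translation_amplitude_mm, dtype=float)
        self.rotation_amplitude_deg = np.asarray(self.rotation_amplitude_deg, dtype=float)
        if self.period < 4:
            raise ValueError("breathing period must be at least 4 frames")
        if np.any(self.translation_amplitude_mm < 0) or np.any(self.rotation_amplitude_deg < 0):
            raise ValueError("amplitudes must be non-negative")

    def pose_at(self, frame: int, centre: np.ndarray | None = None) -> RigidTransform:
        s = np.sin(2.0 * np.pi * frame / self.period + self.phase)
        return RigidTransform(
            rotation=np.radians(self.rotation_amplitude_deg) * s,
            translation=self.translation_amplitude_mm * s,
            centre=centre,
        )


@dataclass
class PhantomSample:
    """One synthetic patient: CT volume + mask, US frames + masks, true poses."""

    ct: Volume3D
    ct_mask: Volume3D
    us_frames: list
    us_masks: list
    gt_poses: list
    resp: RespirationModel
    slice_plane_rl: int

    def __post_init__(self):
        if not (len(self.us_frames) == len(self.us_masks) == len(self.gt_poses)):
            raise ValueError("frames, masks and poses must align")

    @property
    def n_frames(self) -> int:
        return len(self.us_frames)


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

def make_ct_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[Volume3D, Volume3D]:
    """Textured ellipsoid CT volume and its exact binary mask.

    Deterministic given ``seed``.  Raises if the posed ellipsoid does not
    fit strictly inside the grid.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)
    spacing = spec.spacing_vec
    idx = np.indices(shape, dtype=float)
    world = idx * spacing[:, None, None, None]
    vol_centre = (np.array(shape) - 1) / 2.0 * spacing

    # kidney frame: apply the inverse pose to world coordinates
    pose = RigidTransform(spec.pose.rotation, spec.pose.translation, centre=vol_centre)
    from .geometry import invert, to_matrix

    minv = to_matrix(invert(pose))
    pts = world.reshape(3, -1)
    local = (minv[:3, :3] @ pts + minv[:3, 3:4]) - vol_centre[:, None]
    q = ((local / spec.semi_axes_mm[:, None]) ** 2).sum(axis=0).reshape(shape)
    mask = (q <= 1.0).astype(float)
    if spec.asymmetry > 0:
        a = spec.asymmetry
        bump_centre = spec.semi_axes_mm * np.array([0.55, 0.35, 0.3])
        bump_axes = spec.semi_axes_mm * np.array([0.7, 0.6, 0.45]) * a
        qb = (((local - bump_centre[:, None]) / bump_axes[:, None]) ** 2).sum(axis=0)
        mask = np.maximum(mask, (qb.reshape(shape) <= 1.0).astype(float))
    if mask.sum() == 0:
        raise ValueError("kidney ellipsoid produced an empty mask")
    boundary = np.concatenate([
        mask[0].ravel(), mask[-1].ravel(),
        mask[:, 0].ravel(), mask[:, -1].ravel(),
        mask[:, :, 0].ravel(), mask[:, :, -1].ravel(),
    ])
    if boundary.any():
        raise ValueError("kidney ellipsoid exceeds the volume grid")

    texture = np.zeros(shape)
    if spec.texture_amplitude > 0:
        texture = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        texture /= max(np.abs(texture).max(), 1e-12)
    vox = spec.background_intensity * (1.0 - mask) + mask * spec.kidney_intensity * (
        1.0 + spec.texture_amplitude * texture
    )
    if spec.lesion is not None:
        lc = vol_centre + np.asarray(spec.lesion.centre_offset_mm, dtype=float)
        d2 = (((pts - lc[:, None]) / spec.lesion.radius_mm) ** 2).sum(axis=0).reshape(shape)
        vox = vox + (d2 <= 1.0) * spec.lesion.intensity_offset
    spacing_arr = spec.spacing_vec
    return Volume3D(vox, spacing_arr), Volume3D(mask, spacing_arr.copy())


# ---------------------------------------------------------------------------
# US sequence
# ---------------------------------------------------------------------------

def simulate_us_sequence(
    ct: Volume3D,
    mask: Volume3D,
    resp: RespirationModel,
    n_frames: int,
    slice_plane_rl: int | None = None,
    noise: dict | None = None,
    seed: int = 0,
    gamma: float = 0.7,
    base_pose: RigidTransform | None = None,
) -> PhantomSample:
    """US-like sagittal frame sequence of the breathing phantom.

    Frame ``t`` is the constant-RL slice of the CT content moved by the
    breathing pose at ``t``, remapped by ``I^gamma``, blurred, and
    multiplied by log-normal speckle.  Masks are sliced from the warped
    exact mask without noise; poses are recorded exactly.

    ``base_pose`` composes a constant misalignment under the breathing
    motion (pose_t = breathing_t . base), emulating a CT whose initial
    position differs from the scanned kidney by a fixed rigid offset.
    """
    if n_frames < resp.period:
        raise ValueError("need at least one full breathing cycle of frames")
    if slice_plane_rl is None:
        slice_plane_rl = ct.shape[0] // 2
    if not (0 <= slice_plane_rl < ct.shape[0]):
        raise ValueError("slice plane outside the volume grid")
    noise = dict(noise or {})
    speckle_sigma = float(noise.get("speckle_sigma", 0.15))
    blur_sigma = float(noise.get("blur_sigma", 0.6))

    rng = np.random.default_rng(seed)
    lo, hi = float(ct.voxels.min()), float(ct.voxels.max())
    frames, masks, poses = [], [], []
    for t in range(n_frames):
        pose = resp.pose_at(t, centre=ct.centre_mm)
        if base_pose is not None:
            from .geometry import compose

            base = RigidTransform(base_pose.rotation, base_pose.translation, ct.centre_mm)
            pose = compose(pose, base)
            pose.centre = ct.centre_mm
        moving = (pose.rotation.any() or pose.translation.any())
        warped_ct = resample_rigid(ct, pose).voxels if moving else ct.voxels
        warped_mask = resample_rigid(mask, pose).voxels if moving else mask.voxels
        sl = np.asarray(warped_ct[slice_plane_rl], dtype=float)
        sl = np.clip((sl - lo) / max(hi - lo, 1e-12), 0.0, 1.0) ** gamma
        if blur_sigma > 0:
            sl = gaussian_filter(sl, blur_sigma)
        if speckle_sigma > 0:
            sl = sl * rng.lognormal(mean=-0.5 * speckle_sigma**2, sigma=speckle_sigma, size=sl.shape)
        frames.append(sl)
        masks.append(np.asarray(warped_mask[slice_plane_rl], dtype=float))
        poses.append(pose)
    return PhantomSample(ct=ct, ct_mask=mask, us_frames=frames, us_masks=masks,
                         gt_poses=poses, resp=resp, slice_plane_rl=slice_plane_rl)


# ---------------------------------------------------------------------------
# Convenience constructors and IO
# ---------------------------------------------------------------------------

def desk_spec(seed: int = 0, vary: float = 0.1) -> PhantomSpec:
    """A desk-profile spec with mildly varied kidney shape (one 'patient').

    Uses a bean-like asymmetric kidney so the rigid pose is identifiable
    from a single sagittal cross-section.
    """
    rng = np.random.default_rng(seed)
    base = np.array([20.0, 25.0, 45.0])
    semi = base * (1.0 + vary * rng.uniform(-1.0, 1.0, size=3))
    return PhantomSpec(semi_axes_mm=semi, asymmetry=1.0)


def save_sample(sample: PhantomSample, outdir) -> None:
    """Write CT/mask as NIfTI, US frames as a 3D NIfTI stack (frame axis =
    RL), the pose table as CSV and a YAML manifest."""
    import pathlib

    import yaml

    from .geometry import poses_to_table

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample.ct.to_nifti(outdir / "ct.nii.gz")
    sample.ct_mask.to_nifti(outdir / "ct_mask.nii.gz")
    in_plane = sample.ct.spacing[1:]
    stack = Volume3D(np.stack(sample.us_frames), np.array([1.0, *in_plane]))
    stack.to_nifti(outdir / "us_frames.nii.gz")
    Volume3D(np.stack(sample.us_masks), np.array([1.0, *in_plane])).to_nifti(
        outdir / "us_masks.nii.gz")
    poses_to_table(sample.gt_poses).to_csv(outdir / "gt_poses.csv", index=False)
    manifest = {
        "n_frames": sample.n_frames,
        "slice_plane_rl": int(sample.slice_plane_rl),
        "breathing_period": int(sample.resp.period),
        "translation_amplitude_mm": [float(x) for x in sample.resp.translation_amplitude_mm],
        "rotation_amplitude_deg": [float(x) for x in sample.resp.rotation_amplitude_deg],
        "ct_shape": [int(s) for s in sample.ct.shape],
        "spacing_mm": [float(s) for s in sample.ct.spacing],
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
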