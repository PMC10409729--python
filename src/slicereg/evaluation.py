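"""Contour-based alignment metrics and experiment drivers.

Alignment quality is measured between kidney outlines: the Hausdorff
distance (symmetric max of min point-to-contour distances) and the mean
contour distance (MCD, symmetric mean), both in mm and computed via
Euclidean distance transforms of the contours.  Two comparisons are
reported per registered frame: CT-US (estimated CT cutting-plane contour
vs the US frame's contour — a 2D view that overlooks out-of-plane error)
and CT-CT (estimated vs ground-truth-pose cutting plane, which sees the
full 3D error).

The desk-scale synthetic-patient benchmark driver built on these metrics
lives in :mod:`slicereg.benchmark`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .geometry import RigidTransform, Volume3D, resample_rigid
from .phantom import PhantomSample

__all__ = [
    "Contour2D",
    "extract_contour",
    "hausdorff",
    "mcd",
    "pose_error",
    "evaluate_sequence",
    "summarise",
]


@dataclass
class Contour2D:
    """Boundary pixels of a binary mask slice, with physical spacing."""

    pixels: np.ndarray  # (N, 2) integer pixel coordinates
    spacing: np.ndarray  # (2,) mm
    shape: tuple

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def is_empty(self) -> bool:
        return self.pixels.shape[0] == 0

    @property
    def points_mm(self) -> np.ndarray:
        return self.pixels * self.spacing[None, :]


def extract_contour(mask_slice, threshold: float = 0.5, spacing=(1.0, 1.0)) -> Contour2D:
    """Boundary pixels: foreground pixels with at least one background
    4-neighbour (image border counts as background)."""
    m = np.asarray(mask_slice, dtype=float) > threshold
    if m.ndim != 2:
        raise ValueError("expected a 2D mask slice")
    padded = np.pad(m, 1)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    pix = np.argwhere(boundary)
    return Contour2D(pix, np.asarray(spacing, dtype=float), m.shape)


def _distance_map(contour: Contour2D) -> np.ndarray:
    grid = np.ones(contour.shape, dtype=bool)
    grid[contour.pixels[:, 0], contour.pixels[:, 1]] = False
    return distance_transform_edt(grid, sampling=contour.spacing)


def _directed_distances(src: Contour2D, dst: Contour2D) -> np.ndarray:
    dmap = _distance_map(dst)
    return dmap[src.pixels[:, 0], src.pixels[:, 1]]


def _check_pair(u: Contour2D, c: Contour2D):
    if u.is_empty or c.is_empty:
        raise ValueError("contour distance undefined for empty contours")
    if u.shape != c.shape or not np.allclose(u.spacing, c.spacing):
        raise ValueError("contours must share grid shape and spacing")


def hausdorff(u: Contour2D, c: Contour2D) -> float:
    """Symmetric Hausdorff distance in mm (distance-transform based)."""
    _check_pair(u, c)
    return float(max(_directed_distances(u, c).max(), _directed_distances(c, u).max()))


def mcd(u: Contour2D, c: Contour2D) -> float:
    """Mean contour distance in mm: mean of point-to-other-contour
    distances pooled over both contours.  Always <= hausdorff."""
    _check_pair(u, c)
    d = np.concatenate([_directed_distances(u, c), _directed_distances(c, u)])
    return float(d.mean())


def pose_error(estimated: RigidTransform, truth: RigidTransform) -> tuple:
    """(rotation error deg, translation error mm): L2 norms of the
    component-wise parameter differences."""
    dr = np.degrees(estimated.rotation - truth.rotation)
    dt = estimated.translation - truth.translation
    return float(np.linalg.norm(dr)), float(np.linalg.norm(dt))


# ---------------------------------------------------------------------------
# Sequence evaluation
# ---------------------------------------------------------------------------

def evaluate_sequence(sample: PhantomSample, poses: dict,
                      threshold: float = 0.5) -> pd.DataFrame:
    """Per-frame contour metrics for estimated poses.

    ``poses`` maps frame index to an estimated RigidTransform (CT -> frame
    alignment).  For each frame the estimated CT cutting-plane mask contour
    is compared against the US frame's mask contour (CT-US) and against
    the ground-truth-pose cutting-plane contour (CT-CT).
    """
    if not poses:
        raise ValueError("need at least one posed frame")
    mask = sample.ct_mask
    spacing2d = mask.spacing[1:]
    rl = sample.slice_plane_rl
    rows = []
    for frame, est in sorted(poses.items()):
        if frame >= sample.n_frames:
            continue
        est_plane = resample_rigid(mask, est).voxels[rl]
        gt_plane = resample_rigid(mask, sample.gt_poses[frame]).voxels[rl]
        c_est = extract_contour(est_plane, threshold, spacing2d)
        c_gt = extract_contour(gt_plane, threshold, spacing2d)
        c_us = extract_contour(sample.us_masks[frame], threshold, spacing2d)
        row = {"frame": frame}
        if c_est.is_empty or c_us.is_empty or c_gt.is_empty:
            row.update({"hd_ct_us": np.nan, "mcd_ct_us": np.nan,
                        "hd_ct_ct": np.nan, "mcd_ct_ct": np.nan})
        else:
            row.update({
                "hd_ct_us": hausdorff(c_est, c_us), "mcd_ct_us": mcd(c_est, c_us),
                "hd_ct_ct": hausdorff(c_est, c_gt), "mcd_ct_ct": mcd(c_est, c_gt),
            })
        rot_err, trans_err = pose_error(est, sample.gt_poses[frame])
        row["rot_err_deg"] = rot_err
        row["trans_err_mm"] = trans_err
        rows.append(row)
    return pd.DataFrame(rows)


def summarise(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd per metric, mirroring the usual reporting shape."""
    metrics = [c for c in report.columns if c != "frame"]
    return pd.DataFrame({
        "metric": metrics,
        "mean": [report[m].mean() for m in metrics],
        "sd": [report[m].std() for m in metrics],
    })
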