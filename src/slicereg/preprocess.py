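"""Canonicalisation of CT volumes and US frame sequences into the fixed-size
paired volumes the registration network consumes.

Full-profile geometry: CT resampled to 0.8 mm isotropic, cropped to
128 x 224 x 288 about the kidney-feature centroid; US frames resampled to
0.8 mm in-plane, cropped to 224 x 288, windowed in groups of Nw = 5
consecutive frames and embedded at the centre of a zero 128 x 224 x 288
volume along the RL (time) axis.  The desk profile divides every dimension
by 4 (32 x 56 x 72 at 3.2 mm) and shares all code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import RigidTransform, Volume3D

__all__ = [
    "USWindow",
    "resample_isotropic",
    "crop_about_centroid",
    "window_us",
    "embed_us_window",
    "centroid_align",
    "windows_to_manifest",
]


@dataclass
class USWindow:
    """Nw consecutive US frames (and optional matching feature frames)."""

    frames: list
    spacing: np.ndarray = field(default_factory=lambda: np.array([0.8, 0.8]))
    source_indices: list | None = None
    feature_frames: list | None = None

    def __post_init__(self):
        self.frames = [np.asarray(f) for f in self.frames]
        if len(self.frames) % 2 != 1:
            raise ValueError("window size must be odd")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("all frames in a window must share one shape")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.source_indices is None:
            self.source_indices = list(range(len(self.frames)))

    @property
    def window_size(self) -> int:
        return len(self.frames)

    @property
    def middle_index(self) -> int:
        return (len(self.frames) - 1) // 2

    @property
    def middle_source_index(self) -> int:
        return self.source_indices[self.middle_index]


def resample_isotropic(vol: Volume3D, target_spacing: float = 0.8) -> Volume3D:
    """Resample to isotropic voxels by linear interpolation, preserving the
    world extent to within one voxel."""
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(vol.spacing, target_spacing):
        return Volume3D(vol.voxels.copy(), np.full(3, float(target_spacing)), vol.origin.copy())
    factors = vol.spacing / target_spacing
    new_shape = np.maximum(1, np.round(np.array(vol.shape) * factors)).astype(int)
    idx = np.indices(new_shape, dtype=float)
    old_idx = [idx[a] * (target_spacing / vol.spacing[a]) for a in range(3)]
    out = map_coordinates(np.asarray(vol.voxels, dtype=float), old_idx, order=1, mode="nearest")
    return Volume3D(out, np.full(3, float(target_spacing)), vol.origin.copy())


def _feature_centroid_vox(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise ValueError("feature map is empty")
    grids = np.indices(values.shape, dtype=float)
    return np.array([(g * values).sum() / total for g in grids])


def crop_about_centroid(vol: Volume3D, fmap, dims: tuple) -> Volume3D:
    """Crop (and zero-pad where needed) to ``dims`` so that the feature-map
    centroid lands on the output centre within one voxel."""
    values = np.asarray(fmap.voxels if hasattr(fmap, "voxels") else fmap, dtype=float)
    if values.shape != vol.shape:
        raise ValueError("feature map must live on the volume grid")
    centroid = np.round(_feature_centroid_vox(values)).astype(int)
    dims = tuple(int(d) for d in dims)
    out = np.zeros(dims, dtype=float)
    start = centroid - np.array(dims) // 2
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.array(dims), np.array(vol.shape))
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        raise ValueError("crop does not intersect the volume")
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        vol.voxels[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    new_origin = vol.origin + start * vol.spacing
    return Volume3D(out, vol.spacing.copy(), new_origin)


def window_us(frames, nw: int = 5, stride: int = 1, spacing=(0.8, 0.8),
              feature_frames=None) -> list:
    """Sliding windows of ``nw`` consecutive frames; window ``k``'s middle
    frame is source frame ``k + (nw - 1) // 2``."""
    frames = [np.asarray(f) for f in frames]
    if len(frames) < nw:
        raise ValueError(f"need at least {nw} frames, got {len(frames)}")
    windows = []
    for k in range(0, len(frames) - nw + 1, stride):
        idx = list(range(k, k + nw))
        windows.append(USWindow(
            frames=[frames[i] for i in idx],
            spacing=np.asarray(spacing, dtype=float),
            source_indices=idx,
            feature_frames=None if feature_frames is None else [feature_frames[i] for i in idx],
        ))
    return windows


def _embed_frames(frames, dims, centre_in_plane=None) -> np.ndarray:
    nw = len(frames)
    fh, fw = frames[0].shape
    if fh > dims[1] or fw > dims[2]:
        raise ValueError("frame larger than the target plane")
    out = np.zeros(dims, dtype=float)
    if centre_in_plane is None:
        centre_in_plane = np.array([(fh - 1) / 2.0, (fw - 1) / 2.0])
    start_rl = dims[0] // 2 - (nw - 1) // 2
    a0 = dims[1] // 2 - int(round(centre_in_plane[0]))
    b0 = dims[2] // 2 - int(round(centre_in_plane[1]))
    for i, f in enumerate(frames):
        src_lo = np.maximum([-a0, -b0], 0)
        dst_lo = np.maximum([a0, b0], 0)
        src_hi = np.minimum([dims[1] - a0, dims[2] - b0], [fh, fw])
        if np.any(src_hi <= src_lo):
            raise ValueError("frame placement does not intersect the plane")
        out[start_rl + i,
            dst_lo[0]:dst_lo[0] + (src_hi[0] - src_lo[0]),
            dst_lo[1]:dst_lo[1] + (src_hi[1] - src_lo[1])] = \
            f[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1]]
    return out


def embed_us_window(w: USWindow, dims: tuple, centre_in_plane=None) -> Volume3D:
    """Zero-pad the window's Nw frames into a ``dims`` volume, stacked along
    the RL axis and centred at RL index ``dims[0] // 2``.

    ``centre_in_plane`` (AP, IS frame coordinates) anchors the in-plane
    placement; by default the frame centre.  Pass the US kidney-feature
    centroid to centre the kidney instead.
    """
    dims = tuple(int(d) for d in dims)
    vox = _embed_frames(w.frames, dims, centre_in_plane)
    # the RL (time) spacing of the embedded stack equals the in-plane
    # spacing so the paired grid is isotropic
    ap, is_ = float(w.spacing[-2]), float(w.spacing[-1])
    return Volume3D(vox, np.array([is_, ap, is_]))


def windows_to_manifest(windows) -> "pd.DataFrame":
    """Window bookkeeping table: window id, frame ids, middle frame id."""
    import pandas as pd

    rows = []
    for k, w in enumerate(windows):
        rows.append({"window": k,
                     "frame_ids": " ".join(str(i) for i in w.source_indices),
                     "middle_frame": w.middle_source_index})
    return pd.DataFrame(rows)


def centroid_align(ct_fmap, us_fmap_vol) -> RigidTransform:
    """Pure translation moving the CT kidney centroid onto the US kidney
    centroid (both computed from feature maps on their grids, in mm)."""

    def centroid_mm(obj):
        values = np.asarray(obj.voxels if hasattr(obj, "voxels") else obj, dtype=float)
        spacing = obj.spacing if hasattr(obj, "spacing") else np.ones(3)
        origin = obj.origin if hasattr(obj, "origin") else np.zeros(3)
        return origin + _feature_centroid_vox(values) * spacing

    delta = centroid_mm(us_fmap_vol) - centroid_mm(ct_fmap)
    return RigidTransform(np.zeros(3), delta)
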