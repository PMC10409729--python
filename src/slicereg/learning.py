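"""Training strategy: 2-sigma Gaussian transform sampling, unsupervised
pretraining, and one-cycle transfer learning.

Clinically verified CT-US alignments are scarce, so training pairs are
*generated*: the six rigid parameters of the transforms that produce
verified alignments are modelled parameter-by-parameter as Gaussians
truncated at two standard deviations; sampled transforms are inverted and
applied to a reference (aligned) CT volume, giving many misaligned
moving-CT / fixed-US pairs whose restoring transform is known (recorded
for diagnostics only — the training objective never sees it).

Learning is two-step: the registration network is pretrained on the
generated pairs by minimising the FIM loss (Adam, learning rate 3e-4),
then adapted to one specific sequence by continuing the same unsupervised
optimisation on the windows of the sequence's *first breathing cycle* for
exactly two epochs ("one-cycle transfer learning") before inference on
the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, Volume3D, invert, resample_rigid
from .losses import FimWeights, WindowWarper, fim_loss, fixed_mind_slab
from .phantom import PhantomSample
from .regnet import RegNet

__all__ = [
    "TransformDistribution",
    "WindowBundle",
    "TrainingPair",
    "fit_transform_distribution",
    "sample_transforms",
    "group_a_distribution",
    "group_b_distribution",
    "make_window_bundles",
    "generate_training_pairs",
    "pretrain",
    "one_cycle_transfer",
    "first_cycle_frames",
    "infer_sequence",
]


# ---------------------------------------------------------------------------
# Transform distribution
# ---------------------------------------------------------------------------

@dataclass
class TransformDistribution:
    """Per-parameter Gaussians for the 6 rigid parameters, truncated at
    2 sigma.  Order: 3 rotations (degrees), 3 translations (mm)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (6,) or self.std.shape != (6,):
            raise ValueError("mean and std must be 6-vectors")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


def fit_transform_distribution(transforms) -> TransformDistribution:
    """Per-parameter sample mean and sample standard deviation (ddof = 1)."""
    transforms = list(transforms)
    if len(transforms) < 2:
        raise ValueError("need at least two reference transforms")
    rows = np.stack([
        np.concatenate([np.degrees(t.rotation), t.translation]) for t in transforms
    ])
    return TransformDistribution(rows.mean(axis=0), rows.std(axis=0, ddof=1))


def sample_transforms(dist: TransformDistribution, nt: int, seed: int = 0) -> list:
    """``nt`` independent draws, each parameter redrawn (rejection) until it
    falls inside its 2-sigma band; deterministic given ``seed``."""
    if nt < 1:
        raise ValueError("nt must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(nt):
        params = np.empty(6)
        for j in range(6):
            while True:
                v = rng.normal(dist.mean[j], dist.std[j]) if dist.std[j] > 0 else dist.mean[j]
                if abs(v - dist.mean[j]) <= 2.0 * dist.std[j]:
                    params[j] = v
                    break
        out.append(RigidTransform(np.radians(params[:3]), params[3:]))
    return out


#: mean chi-3 factor relating a per-axis sigma to the expected L2 norm of a
#: zero-mean isotropic 3-vector (E||x|| = sigma * sqrt(2) * Gamma(2)/Gamma(1.5))
_CHI3_MEAN = float(np.sqrt(2.0) * 1.0 / (np.sqrt(np.pi) / 2.0))


def group_a_distribution() -> TransformDistribution:
    """Small-transformation group: per-axis sigmas chosen so the expected
    L2 norms match rotations of ~10.4 degrees and translations of ~3.7 mm."""
    sr = 10.37 / _CHI3_MEAN
    st = 3.69 / _CHI3_MEAN
    return TransformDistribution(np.zeros(6), np.array([sr, sr, sr, st, st, st]))


def group_b_distribution() -> TransformDistribution:
    """Large-transformation group (~24.7 degrees, ~5.0 mm L2)."""
    sr = 24.72 / _CHI3_MEAN
    st = 5.04 / _CHI3_MEAN
    return TransformDistribution(np.zeros(6), np.array([sr, sr, sr, st, st, st]))


# ---------------------------------------------------------------------------
# Window bundles and training pairs
# ---------------------------------------------------------------------------

@dataclass
class WindowBundle:
    """One embedded US window on the canonical paired grid."""

    us_img: Volume3D
    us_feat: Volume3D
    frame_indices: list
    mid_pose: RigidTransform | None = None

    @property
    def middle_frame(self) -> int:
        return self.frame_indices[(len(self.frame_indices) - 1) // 2]


@dataclass
class TrainingPair:
    """Moving CT (at a sampled initial pose) against a fixed US window.

    ``gt_transform`` restores the moving volume to the reference alignment;
    it is recorded for diagnostics only and never enters the loss.
    """

    ct: Volume3D
    ct_feat: Volume3D
    window: WindowBundle
    gt_transform: RigidTransform


def _smooth_feature(mask: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(mask, dtype=float)
    from scipy.ndimage import gaussian_filter

    return np.clip(gaussian_filter(np.asarray(mask, dtype=float), sigma), 0.0, 1.0)


def bundles_from_frames(ct: Volume3D, us_frames, us_feat_frames, nw: int = 5,
                        mid_poses=None) -> list:
    """Embed sliding US windows (image + feature frames) on the CT grid.

    Frames must match the CT's in-plane (AP, IS) shape; windows are stacked
    along RL at the canonical centre ``shape[0] // 2``.
    """
    shape = ct.shape
    mid = shape[0] // 2
    half = (nw - 1) // 2
    n = len(us_frames)
    if n < nw:
        raise ValueError("sequence shorter than the window size")
    bundles = []
    for k in range(n - nw + 1):
        idx = list(range(k, k + nw))
        img = np.zeros(shape)
        feat = np.zeros(shape)
        for i, t in enumerate(idx):
            img[mid - half + i] = us_frames[t]
            feat[mid - half + i] = us_feat_frames[t]
        bundles.append(WindowBundle(
            us_img=Volume3D(img, ct.spacing.copy(), ct.origin.copy()),
            us_feat=Volume3D(feat, ct.spacing.copy(), ct.origin.copy()),
            frame_indices=idx,
            mid_pose=None if mid_poses is None else mid_poses[idx[half]],
        ))
    return bundles


def make_window_bundles(sample: PhantomSample, nw: int = 5,
                        feature_sigma: float = 1.0) -> tuple:
    """Assemble (ct_feature_volume, window bundles) for one phantom patient.

    Feature maps are the exact phantom masks softened by a small Gaussian,
    standing in for feature-network probability maps; US windows are
    embedded at the canonical RL centre of the CT grid.
    """
    ct = sample.ct
    ct_feat = Volume3D(_smooth_feature(sample.ct_mask.voxels, feature_sigma),
                       ct.spacing.copy(), ct.origin.copy())
    feat_frames = [_smooth_feature(m, feature_sigma) for m in sample.us_masks]
    bundles = bundles_from_frames(ct, sample.us_frames, feat_frames, nw=nw,
                                  mid_poses=sample.gt_poses)
    return ct_feat, bundles


def generate_training_pairs(ct: Volume3D, ct_feat: Volume3D, windows,
                            dist: TransformDistribution, nt: int, seed: int = 0,
                            min_retained: float = 0.9) -> list:
    """``nt`` training pairs: for each, the reference CT (aligned to the
    window's middle frame) is warped by the *inverse* of a sampled
    transform.  Samples that push the kidney out of the grid (feature mass
    retained below ``min_retained``) are redrawn; the redraw count is
    recorded on the function as ``generate_training_pairs.last_redraws``.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one US window")
    pairs = []
    redraws = 0
    draw_seed = seed
    feat_total = ct_feat.voxels.sum()
    for i in range(nt):
        w = windows[i % len(windows)]
        aligned_ct = resample_rigid(ct, w.mid_pose) if w.mid_pose is not None else ct
        aligned_feat = resample_rigid(ct_feat, w.mid_pose) if w.mid_pose is not None else ct_feat
        while True:
            t = sample_transforms(dist, 1, seed=draw_seed)[0]
            draw_seed += 1
            moving_feat = resample_rigid(aligned_feat, invert(t))
            if moving_feat.voxels.sum() >= min_retained * feat_total:
                break
            redraws += 1
        moving_ct = resample_rigid(aligned_ct, invert(t))
        pairs.append(TrainingPair(ct=moving_ct, ct_feat=moving_feat, window=w,
                                  gt_transform=t))
    generate_training_pairs.last_redraws = redraws
    return pairs


# ---------------------------------------------------------------------------
# Optimisation loops
# ---------------------------------------------------------------------------

def _window_step(model: RegNet, opt, ct: Volume3D, ct_feat: Volume3D,
                 bundle: WindowBundle, warper: WindowWarper,
                 weights: FimWeights, mind_cache: dict,
                 feature_dice: str = "set", step_log: list | None = None) -> float:
    opt.zero_grad()
    params = model.combined_params(ct_feat.voxels, bundle.us_feat.voxels, ct.spacing)
    key = id(bundle)
    if key not in mind_cache:
        mind_cache[key] = fixed_mind_slab(bundle.us_img, warper)
    br = fim_loss(bundle.us_img.voxels, ct.voxels, bundle.us_feat.voxels,
                  ct_feat.voxels, params, warper, weights=weights,
                  mind_fix=mind_cache[key], feature_dice=feature_dice)
    br.total.backward()
    opt.step()
    if step_log is not None:
        row = br.as_dict()
        row["step"] = len(step_log)
        step_log.append(row)
    return br.total.item()


def pretrain(model: RegNet, pairs, epochs: int, seed: int = 0, lr: float | None = None,
             weights: FimWeights | None = None, feature_dice: str = "set",
             trainable: str = "all", step_log: list | None = None):
    """Unsupervised pretraining on generated pairs; returns (model, history)
    with per-epoch mean losses.  Aborts on NaN loss.

    The feature term uses the soft set Dice by default: the printed
    elementwise form rewards covering the fixed map rather than matching
    it, and its optimum is measurably biased away from the true pose on
    desk-scale phantoms (see the methods note).

    ``trainable="heads"`` freezes the convolutional trunk and trains only
    the transform heads on cached trunk features — an order of magnitude
    cheaper per step, used as a second pretraining phase after the trunk
    has been shaped end to end."""
    from .engine import Adam

    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one training pair")
    if weights is None:
        weights = FimWeights()
    first = pairs[0]
    warper = WindowWarper(shape=first.ct.shape, spacing=first.ct.spacing,
                          window_size=model.cfg.window_size)
    rng = np.random.default_rng(seed)
    if trainable == "all":
        params = model.param_list()
        feats = None
    elif trainable == "heads":
        named = model.params()
        params = [v for k, v in named.items() if k.startswith("head")]
        feats = [model.head_features(p.ct_feat.voxels, p.window.us_feat.voxels)
                 for p in pairs]
    else:
        raise ValueError("trainable must be 'all' or 'heads'")
    opt = Adam(params, lr=lr if lr is not None else model.cfg.learning_rate)
    history = []
    order = np.arange(len(pairs))
    mind_cache = {}
    for epoch in range(int(epochs)):
        rng.shuffle(order)
        losses = []
        for i in order:
            p = pairs[i]
            if feats is None:
                loss = _window_step(model, opt, p.ct, p.ct_feat, p.window, warper,
                                    weights, mind_cache, feature_dice, step_log)
            else:
                opt.zero_grad()
                pr = model.params_from_head_features(feats[i], p.ct.spacing)
                key = id(p.window)
                if key not in mind_cache:
                    mind_cache[key] = fixed_mind_slab(p.window.us_img, warper)
                br = fim_loss(p.window.us_img.voxels, p.ct.voxels,
                              p.window.us_feat.voxels, p.ct_feat.voxels, pr, warper,
                              weights=weights, mind_fix=mind_cache[key],
                              feature_dice=feature_dice)
                br.total.backward()
                opt.step()
                loss = br.total.item()
                if step_log is not None:
                    row = br.as_dict()
                    row["step"] = len(step_log)
                    step_log.append(row)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, pair {i}")
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def one_cycle_transfer(model: RegNet, ct: Volume3D, ct_feat: Volume3D,
                       cycle_windows, epochs: int = 2, seed: int = 0,
                       lr: float | None = None,
                       weights: FimWeights | None = None,
                       feature_dice: str = "set",
                       trainable: str = "all",
                       cached_features: dict | None = None) -> RegNet:
    """Refine a *copy* of the pretrained model on the first-cycle windows
    of one sequence for exactly ``epochs`` (default two) epochs; the
    pretrained model is untouched.

    ``trainable`` selects which parameters adapt: ``"all"`` (every
    layer), ``"heads"`` (the transform heads), or ``"head_bias"`` (only
    the head biases — a per-patient constant pose offset through the tanh,
    which is the stable choice when the per-window variation is already
    captured by pretraining; see the methods note).
    """
    from .engine import Adam

    cycle_windows = list(cycle_windows)
    if not cycle_windows:
        raise ValueError("no first-cycle windows found")
    if weights is None:
        weights = FimWeights()
    refined = model.copy()
    if trainable == "all":
        params = refined.param_list()
    elif trainable in ("heads", "head_bias"):
        named = refined.params()
        suffix = ".b" if trainable == "head_bias" else ""
        params = [v for k, v in named.items()
                  if k.startswith("head") and k.endswith(suffix)]
        # freeze the rest so the backward pass stops at the head inputs
        chosen = {id(v) for v in params}
        for v in named.values():
            if id(v) not in chosen:
                v.requires_grad = False
    else:
        raise ValueError("trainable must be 'all', 'heads' or 'head_bias'")
    if not params:
        raise ValueError("no trainable parameters selected")
    warper = WindowWarper(shape=ct.shape, spacing=ct.spacing,
                          window_size=model.cfg.window_size)
    rng = np.random.default_rng(seed)
    opt = Adam(params, lr=lr if lr is not None else model.cfg.learning_rate)
    order = np.arange(len(cycle_windows))
    mind_cache = {}
    feats = None
    if trainable != "all":
        # frozen trunk: the head inputs are constant per window — cache them
        if cached_features is not None:
            feats = [cached_features[id(w)] for w in cycle_windows]
        else:
            feats = [refined.head_features(ct_feat.voxels, w.us_feat.voxels)
                     for w in cycle_windows]
    for _ in range(int(epochs)):
        rng.shuffle(order)
        for i in order:
            if feats is None:
                loss = _window_step(refined, opt, ct, ct_feat, cycle_windows[i], warper,
                                    weights, mind_cache, feature_dice)
            else:
                w = cycle_windows[i]
                opt.zero_grad()
                p = refined.params_from_head_features(feats[i], ct.spacing)
                key = id(w)
                if key not in mind_cache:
                    mind_cache[key] = fixed_mind_slab(w.us_img, warper)
                br = fim_loss(w.us_img.voxels, ct.voxels, w.us_feat.voxels,
                              ct_feat.voxels, p, warper, weights=weights,
                              mind_fix=mind_cache[key], feature_dice=feature_dice)
                br.total.backward()
                opt.step()
                loss = br.total.item()
            if not np.isfinite(loss):
                raise RuntimeError("transfer learning diverged (non-finite loss)")
    return refined


def first_cycle_frames(us_feature_frames, fallback: int | None = None) -> int:
    """Number of frames in the first breathing cycle, detected as the
    second zero crossing of the mean-centred IS centroid trajectory of the
    US feature maps."""
    traj = []
    for f in us_feature_frames:
        f = np.asarray(f, dtype=float)
        total = f.sum()
        if total <= 0:
            traj.append(np.nan)
            continue
        is_idx = np.arange(f.shape[1])[None, :]
        traj.append(float((f * is_idx).sum() / total))
    traj = np.asarray(traj)
    traj = traj - np.nanmean(traj)
    crossings = np.where(np.diff(np.signbit(traj)))[0]
    if len(crossings) >= 2:
        return int(crossings[1] + 1)
    if fallback is not None:
        return fallback
    raise ValueError("could not detect a breathing cycle")


def infer_sequence(model: RegNet, ct: Volume3D, ct_feat: Volume3D, windows,
                   cached_features: dict | None = None,
                   compute_planes: bool = True) -> dict:
    """Register every window and assign each frame the pose from the window
    where it is the middle frame.

    Returns ``{frame_index: (RigidTransform, cutting-plane slice)}``; edge
    frames that are never a middle frame are absent.  ``cached_features``
    (mapping ``id(window)`` to precomputed head features) skips the
    convolutional trunk — valid only if the trunk is unchanged since the
    cache was built.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("sequence shorter than the window size")
    out = {}
    centre = ct.centre_mm
    for w in windows:
        if cached_features is not None:
            params = model.params_from_head_features(
                cached_features[id(w)], ct.spacing).data
        else:
            params = model.combined_params(ct_feat.voxels, w.us_feat.voxels, ct.spacing).data
        mid = (len(w.frame_indices) - 1) // 2
        pose = RigidTransform(params[mid, :3].astype(float),
                              params[mid, 3:].astype(float), centre=centre)
        plane = None
        if compute_planes:
            plane = resample_rigid(ct, pose).voxels[ct.shape[0] // 2]
        out[w.middle_frame] = (pose, plane)
    return out
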