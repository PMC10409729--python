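"""Desk-scale synthetic-patient benchmark for the full two-step pipeline.

The benchmark mirrors the clinical workflow on phantoms small enough for a
CPU: a registration model is pretrained once on generated pairs from
aligned reference phantoms, then for each synthetic test patient — whose
CT is misaligned from the scanned kidney by a random rigid offset drawn
from the small-transformation ("group A") distribution — the model is
refined by one-cycle transfer learning and used to infer per-frame poses,
which are scored against the exact simulated ground truth.

Problem sizes (grids, pair counts, epochs) are the package's desk profile,
chosen so the full benchmark runs in minutes on one CPU while exercising
every pipeline stage; they are configurable through
:class:`BenchmarkConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import evaluate_sequence
from .geometry import RigidTransform, Volume3D, compose, resample_rigid
from .learning import (
    TransformDistribution,
    first_cycle_frames,
    generate_training_pairs,
    group_a_distribution,
    infer_sequence,
    make_window_bundles,
    one_cycle_transfer,
    pretrain,
    sample_transforms,
)
from .phantom import RespirationModel, desk_spec, make_ct_phantom, simulate_us_sequence
from .preprocess import centroid_align
from .regnet import RegNet, build_regnet, desk_regnet_config

__all__ = ["BenchmarkConfig", "Patient", "make_patient", "pretrain_reference_model",
           "register_patient", "run_benchmark"]


@dataclass
class BenchmarkConfig:
    """Desk-profile benchmark sizes and training hyper-parameters.

    Sequences are one breathing cycle of 40 frames plus a margin, so the
    one-cycle transfer phase sees 36 windows (72 unsupervised steps over
    its two epochs); transfer adapts the transform heads on cached trunk
    features (see the methods note on head-only adaptation).
    """

    n_patients: int = 10
    n_reference: int = 2
    n_frames: int = 46
    period: int = 40
    ref_n_frames: int = 26
    ref_period: int = 20
    n_pairs: int = 40
    pretrain_epochs: int = 12
    transfer_epochs: int = 2
    pretrain_lr: float = 3e-3
    transfer_lr: float = 1e-2
    transfer_trainable: str = "heads"
    max_translation_vox: float = 4.0
    head: str = "flatten"
    feature_sigma: float = 0.5
    dist: TransformDistribution = field(default_factory=group_a_distribution)
    noise: dict = field(default_factory=lambda: {"speckle_sigma": 0.15, "blur_sigma": 0.6})


@dataclass
class Patient:
    sample: object
    ct_feat: Volume3D
    bundles: list
    misalignment: RigidTransform


def make_patient(cfg: BenchmarkConfig, seed: int, misaligned: bool = True,
                 reference: bool = False) -> Patient:
    """One synthetic patient: varied kidney shape, breathing phase, and
    (for test patients) a group-A rigid misalignment of the CT.

    ``reference=True`` uses the (shorter) reference-sequence length, which
    keeps pair generation cheap while test patients get full-length
    breathing cycles."""
    rng = np.random.default_rng(seed)
    spec = desk_spec(seed=seed)
    ct, mask = make_ct_phantom(spec, seed=seed)
    resp = RespirationModel(
        period=cfg.ref_period if reference else cfg.period,
        translation_amplitude_mm=np.array([0.5, 1.5, 5.0]) * rng.uniform(0.8, 1.2),
        rotation_amplitude_deg=np.array([2.0, 0.5, 0.5]) * rng.uniform(0.8, 1.2),
        phase=rng.uniform(0, 2 * np.pi),
    )
    mis = RigidTransform.identity()
    if misaligned:
        mis = sample_transforms(cfg.dist, 1, seed=seed + 7919)[0]
    sample = simulate_us_sequence(ct, mask, resp,
                                  n_frames=cfg.ref_n_frames if reference else cfg.n_frames,
                                  noise=cfg.noise, seed=seed, base_pose=mis)
    ct_feat, bundles = make_window_bundles(sample, feature_sigma=cfg.feature_sigma)
    return Patient(sample=sample, ct_feat=ct_feat, bundles=bundles, misalignment=mis)


def pretrain_reference_model(cfg: BenchmarkConfig, seed: int = 0):
    """Build the desk registration network and pretrain it on generated
    pairs pooled over the aligned reference phantoms."""
    pairs = []
    for r in range(cfg.n_reference):
        ref = make_patient(cfg, seed=seed + 1000 + r, misaligned=False, reference=True)
        per_ref = cfg.n_pairs // cfg.n_reference
        pairs.extend(generate_training_pairs(
            ref.sample.ct, ref.ct_feat, ref.bundles, cfg.dist,
            nt=per_ref, seed=seed + 2000 + r))
    ref_shape = pairs[0].ct.shape if pairs else None
    model = build_regnet(desk_regnet_config(
        max_translation_vox=cfg.max_translation_vox, seed=seed,
        head=cfg.head, input_shape=ref_shape if cfg.head == "flatten" else None))
    model, history = pretrain(model, pairs, epochs=cfg.pretrain_epochs,
                              seed=seed, lr=cfg.pretrain_lr)
    return model, history, pairs


def _prealign(patient: Patient) -> tuple:
    """Centroid pre-alignment of the CT against the first window's US map."""
    align = centroid_align(patient.ct_feat, patient.bundles[0].us_feat)
    ct_al = resample_rigid(patient.sample.ct, align)
    feat_al = resample_rigid(patient.ct_feat, align)
    return ct_al, feat_al, align


def build_feature_cache(model: RegNet, patient: Patient, ct_feat_al: Volume3D) -> dict:
    """Precompute per-window head-input features (valid while the model's
    convolutional trunk is unchanged, i.e. for head-only transfer)."""
    return {id(b): model.head_features(ct_feat_al.voxels, b.us_feat.voxels)
            for b in patient.bundles}


def register_patient(model: RegNet, patient: Patient, cfg: BenchmarkConfig,
                     seed: int = 0, transfer: bool = True,
                     prealigned: tuple | None = None,
                     feature_cache: dict | None = None):
    """Two-step (or pretrained-only) registration of one patient.

    Returns ``(per-frame report DataFrame, refined model or None)``.
    """
    ct_al, feat_al, align = prealigned if prealigned is not None else _prealign(patient)
    centre = ct_al.centre_mm
    align.centre = None  # pure translation; centre irrelevant
    if feature_cache is None and cfg.transfer_trainable != "all":
        feature_cache = build_feature_cache(model, patient, feat_al)
    refined = None
    active = model
    if transfer:
        n_cycle = first_cycle_frames(
            [b for b in patient.sample.us_masks], fallback=cfg.period)
        n_cycle = max(n_cycle, model.cfg.window_size)
        cycle_bundles = [b for b in patient.bundles
                         if b.frame_indices[-1] < n_cycle]
        if not cycle_bundles:
            cycle_bundles = patient.bundles[:1]
        refined = one_cycle_transfer(model, ct_al, feat_al, cycle_bundles,
                                     epochs=cfg.transfer_epochs, seed=seed,
                                     lr=cfg.transfer_lr,
                                     trainable=cfg.transfer_trainable,
                                     cached_features=feature_cache)
        active = refined
    cache_ok = feature_cache is not None and (not transfer or cfg.transfer_trainable != "all")
    results = infer_sequence(active, ct_al, feat_al, patient.bundles,
                             cached_features=feature_cache if cache_ok else None,
                             compute_planes=False)
    poses = {}
    for frame, (rel_pose, _) in results.items():
        rel = RigidTransform(rel_pose.rotation, rel_pose.translation, centre)
        est = compose(rel, RigidTransform(np.zeros(3), align.translation, centre))
        poses[frame] = est
    report = evaluate_sequence(patient.sample, poses)
    return report, refined


def run_benchmark(cfg: BenchmarkConfig, seed: int = 0) -> dict:
    """Pretrain once, register every test patient with and without transfer
    learning, and pool per-frame metrics."""
    model, history, _ = pretrain_reference_model(cfg, seed=seed)
    two_step, one_step = [], []
    for p in range(cfg.n_patients):
        patient = make_patient(cfg, seed=seed + 100 + p, misaligned=True)
        prealigned = _prealign(patient)
        cache = None
        if cfg.transfer_trainable != "all":
            cache = build_feature_cache(model, patient, prealigned[1])
        rep2, _ = register_patient(model, patient, cfg, seed=seed + p, transfer=True,
                                   prealigned=prealigned, feature_cache=cache)
        rep1, _ = register_patient(model, patient, cfg, seed=seed + p, transfer=False,
                                   prealigned=prealigned, feature_cache=cache)
        rep2["patient"] = p
        rep1["patient"] = p
        two_step.append(rep2)
        one_step.append(rep1)
    return {
        "pretrain_history": history,
        "two_step": pd.concat(two_step, ignore_index=True),
        "one_step": pd.concat(one_step, ignore_index=True),
    }
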