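"""Training strategy: transform statistics, 2-sigma sampling, pair
generation closure, and the unsupervised-training contracts."""

import numpy as np
import pytest

from slicereg.geometry import RigidTransform, invert, resample_rigid
from slicereg.learning import (
    TransformDistribution,
    first_cycle_frames,
    fit_transform_distribution,
    generate_training_pairs,
    group_a_distribution,
    infer_sequence,
    make_window_bundles,
    one_cycle_transfer,
    pretrain,
    sample_transforms,
)
from slicereg.phantom import PhantomSpec, RespirationModel, make_ct_phantom, simulate_us_sequence
from slicereg.regnet import build_regnet, desk_regnet_config


def small_sample(seed=0, n_frames=9, misaligned=False):
    """A small-grid phantom sequence cheap enough for unit tests."""
    spec = PhantomSpec(shape=(16, 24, 32), spacing=3.2,
                       semi_axes_mm=np.array([12.0, 18.0, 30.0]))
    ct, mask = make_ct_phantom(spec, seed=seed)
    resp = RespirationModel(period=6, translation_amplitude_mm=np.array([0.3, 0.8, 3.0]),
                            rotation_amplitude_deg=np.array([1.0, 0.3, 0.3]))
    base = None
    if misaligned:
        base = sample_transforms(group_a_distribution(), 1, seed=seed + 1)[0]
    return simulate_us_sequence(ct, mask, resp, n_frames=n_frames, seed=seed,
                                base_pose=base)


def small_model(seed=0):
    return build_regnet(desk_regnet_config(
        encoder_filters=(2, 4, 4), decoder_filters=(4, 4, 4, 4, 2, 2),
        max_translation_vox=4.0, seed=seed))


class TestFitTransformDistribution:
    def test_identical_references_zero_sigma(self):
        t = RigidTransform(np.radians([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        d = fit_transform_distribution([t, t, t])
        np.testing.assert_allclose(d.std, 0.0, atol=1e-12)
        np.testing.assert_allclose(d.mean, [1, 2, 3, 4, 5, 6], atol=1e-9)

    def test_two_sample_hand_statistics(self):
        a = RigidTransform(np.zeros(3), np.array([0.0, 0.0, 2.0]))
        b = RigidTransform(np.zeros(3), np.array([0.0, 0.0, 4.0]))
        d = fit_transform_distribution([a, b])
        assert d.mean[5] == pytest.approx(3.0)
        assert d.std[5] == pytest.approx(np.sqrt(2.0))

    def test_parameter_recovery_from_known_gaussian(self):
        true = TransformDistribution(np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0]),
                                     np.array([2.0, 1.0, 1.5, 1.0, 0.5, 2.0]))
        ts = sample_transforms(true, 200, seed=3)
        fitted = fit_transform_distribution(ts)
        assert np.all(np.abs(fitted.mean - true.mean) <= 0.15 * true.std + 1e-9)
        # a normal truncated at 2 sigma has sd = 0.8796 sigma
        np.testing.assert_allclose(fitted.std, 0.8796 * true.std, rtol=0.15)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError):
            fit_transform_distribution([RigidTransform.identity()])


class TestSampleTransforms:
    def test_zero_sigma_returns_mean(self):
        d = TransformDistribution(np.array([1.0, 0, 0, 0, 0, 5.0]), np.zeros(6))
        ts = sample_transforms(d, 10, seed=0)
        for t in ts:
            assert np.degrees(t.rotation[0]) == pytest.approx(1.0)
            assert t.translation[2] == pytest.approx(5.0)

    def test_group_a_samples_within_two_sigma(self):
        d = group_a_distribution()
        ts = sample_transforms(d, 1000, seed=1)
        rows = np.stack([np.concatenate([np.degrees(t.rotation), t.translation]) for t in ts])
        assert np.all(np.abs(rows - d.mean) <= 2.0 * d.std + 1e-12)

    def test_empirical_mean_clt_bound(self):
        d = group_a_distribution()
        ts = sample_transforms(d, 1000, seed=2)
        rows = np.stack([np.concatenate([np.degrees(t.rotation), t.translation]) for t in ts])
        bound = 3.0 * d.std / np.sqrt(len(ts))
        assert np.all(np.abs(rows.mean(axis=0) - d.mean) <= bound)

    def test_deterministic_given_seed(self):
        d = group_a_distribution()
        a = sample_transforms(d, 5, seed=9)
        b = sample_transforms(d, 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.parameters, y.parameters)


class TestGenerateTrainingPairs:
    def test_identity_distribution_keeps_alignment(self):
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        ident = TransformDistribution(np.zeros(6), np.zeros(6))
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles, ident, nt=2, seed=0)
        from slicereg.losses import WindowWarper, fim_loss
        from slicereg.engine import Tensor

        p = pairs[0]
        warper = WindowWarper(shape=p.ct.shape, spacing=p.ct.spacing, window_size=5)

        def loss_at(offset_mm):
            params = np.zeros((5, 6))
            params[:, 5] = offset_mm
            return fim_loss(p.window.us_img.voxels, p.ct.voxels, p.window.us_feat.voxels,
                            p.ct_feat.voxels, Tensor(params), warper).total.item()

        assert loss_at(0.0) < loss_at(6.4)
        assert loss_at(0.0) < loss_at(-6.4)

    def test_closure_restores_alignment(self):
        """Warping the moving CT mask by the stored transform recovers the
        reference-aligned mask."""
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles,
                                        group_a_distribution(), nt=3, seed=1)
        for p in pairs:
            restored = resample_rigid(p.ct_feat, p.gt_transform)
            aligned = resample_rigid(ct_feat, p.window.mid_pose)
            # compare soft-mask centroids: must agree within one voxel
            from slicereg.preprocess import centroid_align

            res = centroid_align(restored, aligned)
            assert np.linalg.norm(res.translation) < np.max(sample.ct.spacing)

    def test_pair_count(self):
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles,
                                        group_a_distribution(), nt=7, seed=0)
        assert len(pairs) == 7


class TestPretrain:
    def test_zero_epochs_leaves_model_unchanged(self):
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles,
                                        group_a_distribution(), nt=1, seed=0)
        model = small_model()
        before = {k: v.data.copy() for k, v in model.params().items()}
        model, hist = pretrain(model, pairs, epochs=0, seed=0)
        assert hist == []
        for k, v in model.params().items():
            np.testing.assert_array_equal(before[k], v.data)

    def test_seeded_rerun_reproducible(self):
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles,
                                        group_a_distribution(), nt=2, seed=0)
        h1 = pretrain(small_model(), pairs, epochs=1, seed=5)[1]
        h2 = pretrain(small_model(), pairs, epochs=1, seed=5)[1]
        np.testing.assert_array_equal(h1, h2)

    def test_ground_truth_never_enters_training(self):
        """Stripping the diagnostic transforms changes nothing."""
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        pairs = generate_training_pairs(sample.ct, ct_feat, bundles,
                                        group_a_distribution(), nt=2, seed=0)
        m1, _ = pretrain(small_model(seed=3), pairs, epochs=1, seed=0)
        for p in pairs:
            p.gt_transform = None
        m2, _ = pretrain(small_model(seed=3), pairs, epochs=1, seed=0)
        for (k, a), (_, b) in zip(sorted(m1.params().items()), sorted(m2.params().items())):
            np.testing.assert_array_equal(a.data, b.data)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            pretrain(small_model(), [], epochs=1)


class TestTransferAndInference:
    def test_transfer_returns_copy_and_pretrained_untouched(self):
        sample = small_sample()
        ct_feat, bundles = make_window_bundles(sample)
        model = small_model()
        before = {k: v.data.copy() for k, v in model.params().items()}
        refined = one_cycle_transfer(model, sample.ct, ct_feat, bundles[:2],
                                     epochs=2, seed=0)
        for k, v in model.params().items():
            np.testing.assert_array_equal(before[k], v.data)
        assert refined is not model

    def test_no_cycle_windows_rejected(self):
        sample = small_sample()
        ct_feat, _ = make_window_bundles(sample)
        with pytest.raises(ValueError):
            one_cycle_transfer(small_model(), sample.ct, ct_feat, [], epochs=2)

    def test_infer_sequence_bookkeeping(self):
        sample = small_sample(n_frames=9)
        ct_feat, bundles = make_window_bundles(sample)
        model = small_model()
        out = infer_sequence(model, sample.ct, ct_feat, bundles)
        # 9 frames, Nw = 5 -> 5 posed frames (middles 2..6)
        assert sorted(out.keys()) == [2, 3, 4, 5, 6]
        for pose, plane in out.values():
            assert plane.shape == sample.ct.shape[1:]

    def test_static_aligned_pair_near_identity_poses(self):
        spec = PhantomSpec(shape=(16, 24, 32), spacing=3.2,
                           semi_axes_mm=np.array([12.0, 18.0, 30.0]))
        ct, mask = make_ct_phantom(spec, seed=0)
        resp = RespirationModel(period=6, translation_amplitude_mm=np.zeros(3),
                                rotation_amplitude_deg=np.zeros(3))
        sample = simulate_us_sequence(ct, mask, resp, n_frames=6,
                                      noise={"speckle_sigma": 0.0, "blur_sigma": 0.0},
                                      seed=0)
        ct_feat, bundles = make_window_bundles(sample)
        out = infer_sequence(small_model(), ct, ct_feat, bundles)
        for pose, _ in out.values():
            assert np.linalg.norm(pose.translation) < 1e-6
            assert np.linalg.norm(pose.rotation) < 1e-6


class TestFirstCycleDetection:
    def test_detects_sinusoidal_period(self):
        period = 12
        frames = []
        for t in range(3 * period):
            f = np.zeros((20, 40))
            c = 20 + int(round(6 * np.sin(2 * np.pi * t / period)))
            f[8:12, c - 3 : c + 3] = 1.0
            frames.append(f)
        n = first_cycle_frames(frames)
        assert abs(n - period) <= 2

    def test_fallback_when_no_crossing(self):
        frames = [np.ones((4, 4))] * 6
        assert first_cycle_frames(frames, fallback=5) == 5
        with pytest.raises(ValueError):
            first_cycle_frames(frames)
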