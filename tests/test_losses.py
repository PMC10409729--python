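"""FIM loss terms: MIND brute-force oracle, Dice identities, warping bookkeeping."""

from _oracles import mind_bruteforce

import numpy as np
import pytest

from slicereg import geometry as geo
from slicereg import losses
from slicereg.engine import Tensor
from slicereg.geometry import RigidTransform, Volume3D, WindowTransformSet
from slicereg.losses import (
    DISPLACEMENTS,
    FimWeights,
    WindowWarper,
    elementwise_dice,
    feature_loss,
    fim_loss,
    image_loss,
    mind_descriptor,
    transform_loss,
)

rng = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# MIND
# ---------------------------------------------------------------------------

class TestMindDescriptor:
    def test_constant_volume_all_ones(self):
        c = mind_descriptor(np.full((6, 7, 8), 3.5)).data
        np.testing.assert_allclose(c, 1.0)

    def test_per_voxel_max_is_one(self):
        c = mind_descriptor(rng.normal(size=(9, 8, 7))).data
        np.testing.assert_allclose(c.max(axis=0), 1.0, atol=1e-12)
        assert c.min() > 0.0

    def test_matches_bruteforce_oracle(self):
        for _ in range(3):
            vol = rng.normal(size=(6, 6, 6))
            ours = mind_descriptor(vol).data
            ref = mind_bruteforce(vol)
            np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestElementwiseDice:
    def test_saturated_overlap(self):
        x = np.ones((4, 4))
        assert elementwise_dice(x, x).item() == pytest.approx(2.0 / (2.0 + 1e-6))

    def test_disjoint(self):
        assert elementwise_dice(np.ones((4, 4)), np.zeros((4, 4))).item() == pytest.approx(0.0)

    def test_binary_agreement_returns_foreground_fraction(self):
        x = (rng.random((10, 10)) < 0.3).astype(float)
        p = x.mean()
        assert elementwise_dice(x, x, eps=1e-12).item() == pytest.approx(p, abs=1e-6)


# ---------------------------------------------------------------------------
# Window losses on a small canonical grid
# ---------------------------------------------------------------------------

SHAPE = (16, 20, 24)


def make_warper():
    return WindowWarper(shape=SHAPE, spacing=np.ones(3), window_size=5)


def identity_params(nw=5):
    return Tensor(np.zeros((nw, 6)))


def blob_volume(shape=SHAPE, centre_shift=(0, 0, 0), widths=(3.0, 4.0, 5.0), texture=0.0, seed=0):
    idx = np.indices(shape, dtype=float)
    ctr = (np.array(shape) - 1) / 2.0 + np.asarray(centre_shift, dtype=float)
    q = sum(((idx[a] - ctr[a]) / widths[a]) ** 2 for a in range(3))
    v = np.exp(-q)
    if texture:
        r = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        v = v * (1.0 + texture * gaussian_filter(r.normal(size=shape), 1.0))
    return v


def embed_frames(frames, shape=SHAPE):
    """Place Nw (H, W) frames at RL indices centred on shape[0] // 2."""
    vol = np.zeros(shape)
    mid = shape[0] // 2
    start = mid - (len(frames) - 1) // 2
    for i, f in enumerate(frames):
        vol[start + i] = f
    return vol


class TestFeatureLoss:
    def test_perfect_alignment_all_ones(self):
        w = make_warper()
        m_mov = np.ones(SHAPE)
        m_fix = embed_frames([np.ones(SHAPE[1:])] * 5)
        lf = feature_loss(m_fix, m_mov, identity_params(), w)
        assert lf.item() == pytest.approx(-1.0, abs=1e-5)

    def test_disjoint_masks(self):
        w = make_warper()
        lf = feature_loss(embed_frames([np.ones(SHAPE[1:])] * 5), np.zeros(SHAPE),
                          identity_params(), w)
        assert lf.item() == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_window_of_one(self):
        w = WindowWarper(shape=SHAPE, spacing=np.ones(3), window_size=1)
        m_mov = blob_volume()
        m_fix = embed_frames([m_mov[SHAPE[0] // 2]])
        lf = feature_loss(m_fix, m_mov, Tensor(np.zeros((1, 6))), w)
        direct = -losses.elementwise_dice(m_mov[SHAPE[0] // 2], m_mov[SHAPE[0] // 2]).item()
        assert lf.item() == pytest.approx(direct, abs=1e-6)

    def test_rejects_mismatched_window(self):
        with pytest.raises(ValueError):
            feature_loss(np.zeros(SHAPE), np.zeros(SHAPE), Tensor(np.zeros((3, 6))), make_warper())


class TestImageLoss:
    def test_identical_slabs_give_zero(self):
        w = make_warper()
        i_mov = blob_volume(texture=0.3, seed=3)
        mid = SHAPE[0] // 2
        i_fix = np.zeros(SHAPE)
        i_fix[mid - 2 : mid + 3] = i_mov[mid - 2 : mid + 3]
        li = image_loss(i_fix, i_mov, np.ones(SHAPE), identity_params(), w)
        assert li.item() == pytest.approx(0.0, abs=1e-6)

    def test_affine_intensity_invariance(self):
        w = make_warper()
        i_mov = blob_volume(texture=0.5, seed=4)
        i_fix = embed_frames(list(np.roll(i_mov, 1, axis=2)[SHAPE[0] // 2 - 2 : SHAPE[0] // 2 + 3]))
        m = np.ones(SHAPE)
        base = image_loss(i_fix, i_mov, m, identity_params(), w).item()
        # remap ONLY the fixed image; MIND normalisation absorbs it.  The CT
        # side is masked (multiplied) so its remap must preserve zero.
        remapped = image_loss(2.3 * i_fix + 0.7, i_mov, m, identity_params(), w).item()
        assert remapped == pytest.approx(base, rel=0.05)

    def test_composition_oracle_random_pose(self):
        """image_loss equals mind_descriptor o resample_rigid o slice o mean-abs."""
        w = make_warper()
        i_mov = blob_volume(texture=0.4, seed=5)
        m_mov = blob_volume(widths=(4.0, 5.0, 6.0))
        i_fix = embed_frames([rng.random(SHAPE[1:]) for _ in range(5)])
        t = RigidTransform(np.array([0.05, -0.08, 0.1]), np.array([0.7, -0.5, 1.1]))
        params = np.zeros((5, 6))
        params[2] = t.parameters
        li = image_loss(i_fix, i_mov, m_mov, Tensor(params), w).item()

        vol = Volume3D((i_mov * m_mov), np.ones(3))
        warped = geo.resample_rigid(vol, t, interpolation="linear").voxels
        mid = SHAPE[0] // 2
        eps = 1e-6 * np.ptp(i_mov * m_mov) ** 2  # floor anchored to the unwarped image
        mind_mov = mind_descriptor(warped[mid - 2 : mid + 3], eps=eps).data
        mind_fix = mind_descriptor(i_fix[mid - 2 : mid + 3]).data
        expected = np.abs(mind_mov[:, 2] - mind_fix[:, 2]).mean()
        assert li == pytest.approx(expected, abs=1e-9)


class TestTransformLoss:
    def test_all_identity_is_zero(self):
        assert transform_loss(identity_params()).item() == pytest.approx(0.0, abs=1e-9)

    def test_constant_velocity_kills_gradD(self):
        params = np.zeros((5, 6))
        params[:, 5] = np.arange(5) * 1.5  # arithmetic progression in IS translation
        full = transform_loss(Tensor(params), mix=(0.01, 0.99)).item()
        dist_only = transform_loss(Tensor(params), mix=(0.01, 0.0)).item()
        assert full == pytest.approx(dist_only, abs=1e-9)

    def test_matches_loop_oracle(self):
        params = rng.normal(scale=0.3, size=(5, 6))
        ts = [RigidTransform(p[:3], p[3:]) for p in params]
        mats = [geo.to_matrix(t, translation_scale=2.0) for t in ts]
        dist = np.mean([np.linalg.norm(m - np.eye(4)) for m in mats])
        grad_d = np.mean([np.linalg.norm(mats[i + 1] + mats[i - 1] - 2 * mats[i])
                          for i in range(1, 4)])
        expected = 0.01 * dist + 0.99 * grad_d
        got = transform_loss(Tensor(params), translation_scale=2.0).item()
        assert got == pytest.approx(expected, rel=1e-9)

    def test_rejects_short_window(self):
        with pytest.raises(ValueError):
            transform_loss(Tensor(np.zeros((1, 6))))


class TestFimLoss:
    def aligned_pair(self):
        w = make_warper()
        i_mov = blob_volume(texture=0.3, seed=6)
        m_mov = np.ones(SHAPE)
        mid = SHAPE[0] // 2
        i_fix = np.zeros(SHAPE)
        i_fix[mid - 2 : mid + 3] = i_mov[mid - 2 : mid + 3]
        m_fix = embed_frames([np.ones(SHAPE[1:])] * 5)
        return w, i_fix, i_mov, m_fix, m_mov

    def test_global_optimum_breakdown(self):
        w, i_fix, i_mov, m_fix, m_mov = self.aligned_pair()
        br = fim_loss(i_fix, i_mov, m_fix, m_mov, identity_params(), w)
        assert br.feature.item() == pytest.approx(-1.0, abs=1e-5)
        assert br.image.item() == pytest.approx(0.0, abs=1e-6)
        assert br.motion.item() == pytest.approx(0.0, abs=1e-9)
        assert br.total.item() == pytest.approx(-1.0, abs=1e-4)

    def test_weight_ablation_reduces_to_feature_term(self):
        w, i_fix, i_mov, m_fix, m_mov = self.aligned_pair()
        params = Tensor(rng.normal(scale=0.1, size=(5, 6)))
        weights = FimWeights(lambda1=0.0, lambda2=0.0)
        br = fim_loss(i_fix, i_mov, m_fix, m_mov, params, w, weights=weights)
        lf = feature_loss(m_fix, m_mov, params, w)
        assert br.total.item() == pytest.approx(lf.item(), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        w = WindowWarper(shape=(16, 16, 16), spacing=np.ones(3), window_size=5)
        i_mov = blob_volume(shape=(16, 16, 16), texture=0.4, seed=8)
        m_mov = blob_volume(shape=(16, 16, 16), widths=(4.0, 4.0, 4.0))
        i_fix = embed_frames([rng.random((16, 16)) * 0.5 + 0.25 for _ in range(5)], (16, 16, 16))
        m_fix = embed_frames([blob_volume((16, 16, 16))[8] for _ in range(5)], (16, 16, 16))
        p0 = rng.normal(scale=0.08, size=(5, 6))

        def value(p):
            return fim_loss(i_fix, i_mov, m_fix, m_mov, Tensor(np.asarray(p)), w).total

        pt = Tensor(p0, requires_grad=True)
        fim_loss(i_fix, i_mov, m_fix, m_mov, pt, w).total.backward()
        eps = 1e-6
        num = np.zeros_like(p0)
        for i in range(5):
            for j in range(6):
                pp, pm = p0.copy(), p0.copy()
                pp[i, j] += eps
                pm[i, j] -= eps
                num[i, j] = (value(pp).item() - value(pm).item()) / (2 * eps)
        rel_err = np.linalg.norm(pt.grad - num) / np.linalg.norm(num)
        assert rel_err < 1e-3

    def test_translation_sweep_has_minimum_at_truth(self):
        """1-D IS-translation sweep of the loss bottoms out at the true offset."""
        shape = (16, 24, 24)
        w = WindowWarper(shape=shape, spacing=np.ones(3), window_size=5)
        i_mov = blob_volume(shape, widths=(4.0, 5.0, 6.0), texture=0.3, seed=9)
        m_mov = blob_volume(shape, widths=(4.0, 5.0, 6.0))
        true_is = 2.0
        t_true = RigidTransform(np.zeros(3), np.array([0.0, 0.0, true_is]))
        warped_i = geo.resample_rigid(Volume3D(i_mov * m_mov, np.ones(3)), t_true).voxels
        warped_m = geo.resample_rigid(Volume3D(m_mov, np.ones(3)), t_true).voxels
        mid = shape[0] // 2
        i_fix = np.zeros(shape)
        i_fix[mid - 2 : mid + 3] = warped_i[mid - 2 : mid + 3]
        m_fix = np.zeros(shape)
        m_fix[mid - 2 : mid + 3] = warped_m[mid - 2 : mid + 3]
        offsets = np.arange(-2.0, 7.0, 1.0)
        vals = []
        for dz in offsets:
            p = np.zeros((5, 6))
            p[:, 5] = dz
            vals.append(fim_loss(i_fix, i_mov, m_fix, m_mov, Tensor(p), w).total.item())
        best = offsets[int(np.argmin(vals))]
        assert abs(best - true_is) <= 1.0
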