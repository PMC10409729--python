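"""Registration network: shape/range contracts, identity at init, the
hierarchical combination rule, and gradient flow through the FIM loss."""

import numpy as np
import pytest

from slicereg.engine import Adam, Tensor
from slicereg.geometry import RigidTransform, WindowTransformSet
from slicereg.losses import WindowWarper, fim_loss
from slicereg.regnet import (
    RegNet,
    RegNetConfig,
    ScaleTransformStack,
    build_regnet,
    combine_hierarchical,
    desk_regnet_config,
    register_window,
)

rng = np.random.default_rng(11)


def tiny_config(**kw):
    kw.setdefault("encoder_filters", (2, 4, 4))
    kw.setdefault("decoder_filters", (4, 4, 4, 4, 2, 2))
    return RegNetConfig(**kw)


def random_stack(n_scales=4, nw=5, seed=0):
    r = np.random.default_rng(seed)
    sets = []
    for _ in range(n_scales):
        sets.append(WindowTransformSet([
            RigidTransform(r.normal(scale=0.1, size=3), r.normal(scale=2.0, size=3))
            for _ in range(nw)
        ]))
    return ScaleTransformStack(sets)


class TestConfig:
    def test_weights_follow_printed_rule(self):
        cfg = RegNetConfig()
        np.testing.assert_allclose(cfg.translation_weights, (2.0, 1.0, 0.5, 0.25))

    def test_inconsistent_weights_rejected(self):
        with pytest.raises(ValueError):
            RegNetConfig(translation_weights=(1.0, 1.0, 1.0, 1.0))

    def test_flatten_requires_input_shape(self):
        with pytest.raises(ValueError):
            RegNetConfig(head="flatten")


class TestForward:
    def test_desk_forward_shapes_and_tanh_range(self):
        model = build_regnet(desk_regnet_config())
        ct = rng.random((32, 56, 72))
        us = rng.random((32, 56, 72))
        outs = model.forward(ct, us)
        assert len(outs) == 4
        cfg = model.cfg
        for p in outs:
            assert p.shape == (5, 6)
            assert np.all(np.abs(p.data[:, :3]) <= cfg.max_rotation_rad)
            assert np.all(np.abs(p.data[:, 3:]) <= cfg.max_translation_vox)

    def test_zero_init_head_gives_identity(self):
        model = build_regnet(tiny_config())
        ct = rng.random((16, 24, 32))
        us = rng.random((16, 24, 32))
        transforms, warped = register_window(model, ct, us)
        assert len(transforms) == 5
        for t in transforms:
            assert t.is_identity()
        np.testing.assert_allclose(warped[0].voxels, ct, atol=1e-6)

    def test_indivisible_dims_rejected(self):
        model = build_regnet(tiny_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((15, 24, 32)), np.zeros((15, 24, 32)))

    def test_parameter_count_closed_form(self):
        """Layer-by-layer hand count for the desk profile (pool head):
        encoder convs 2->4->8->8, decoder convs 8,8,8,4,2,2 (3^3 kernels),
        four 6*Nw heads at channels 8,8,8,2."""
        model = build_regnet(desk_regnet_config())
        hand = (
            (4 * 2 * 27 + 4) + (8 * 4 * 27 + 8) + (8 * 8 * 27 + 8)   # encoder
            + 3 * (8 * 8 * 27 + 8) + (4 * 8 * 27 + 4)                 # decoder 1/8..1/1
            + (2 * 4 * 27 + 2) + (2 * 2 * 27 + 2)                     # finest refinements
            + 3 * (8 * 30 + 30) + (2 * 30 + 30)                       # heads
        )
        total = sum(p.data.size for p in model.param_list())
        assert total == hand

    def test_save_load_round_trip(self, tmp_path):
        model = build_regnet(tiny_config())
        # give the heads nonzero weights so the check is nontrivial
        for h in model.heads:
            h.w.data = rng.normal(scale=0.01, size=h.w.data.shape).astype(np.float32)
        path = tmp_path / "reg.npz"
        model.save(path)
        back = RegNet.load(path)
        ct = rng.random((16, 24, 32))
        us = rng.random((16, 24, 32))
        a = model.combined_params(ct, us, np.ones(3)).data
        b = back.combined_params(ct, us, np.ones(3)).data
        np.testing.assert_array_equal(a, b)


class TestCombineHierarchical:
    def test_coarse_only_unit_translation(self):
        cfg = RegNetConfig()
        sets = []
        for s in range(4):
            ts = []
            for _ in range(5):
                t = np.zeros(3)
                if s == 0:
                    t = np.array([1.0, 0.0, 0.0])  # one coarse (1/8-scale) voxel
                ts.append(RigidTransform(np.zeros(3), t))
            sets.append(WindowTransformSet(ts))
        out = combine_hierarchical(ScaleTransformStack(sets), cfg, spacing=np.ones(3))
        for t in out:
            np.testing.assert_allclose(t.translation, [2.0, 0.0, 0.0], atol=1e-12)

    def test_equal_rotations_average_to_themselves(self):
        cfg = RegNetConfig()
        r = np.array([0.1, -0.2, 0.3])
        sets = [WindowTransformSet([RigidTransform(r.copy(), np.zeros(3)) for _ in range(5)])
                for _ in range(4)]
        out = combine_hierarchical(ScaleTransformStack(sets), cfg, np.ones(3))
        for t in out:
            np.testing.assert_allclose(t.rotation, r, atol=1e-7)

    def test_loop_oracle_on_random_stacks(self):
        cfg = RegNetConfig()
        spacing = np.array([3.2, 3.2, 3.2])
        for seed in range(100):
            stack = random_stack(seed=seed)
            out = combine_hierarchical(stack, cfg, spacing)
            for i in range(5):
                rot = np.mean([s[i].rotation for s in stack.sets], axis=0)
                trans = np.zeros(3)
                for w, s in zip(cfg.translation_weights, stack.sets):
                    trans += w * s[i].translation
                trans *= spacing
                np.testing.assert_allclose(out[i].rotation, rot, atol=1e-6)
                np.testing.assert_allclose(out[i].translation, trans, atol=1e-5)

    def test_mismatched_scale_count_rejected(self):
        cfg = RegNetConfig()
        with pytest.raises(ValueError):
            combine_hierarchical(random_stack(n_scales=3), cfg, np.ones(3))


class TestHierarchyConsistency:
    def test_coarse_translation_moves_image_as_combined(self):
        """A pure coarse-scale translation prediction displaces the warped
        image by the combine rule's full-resolution output."""
        from slicereg.geometry import Volume3D, resample_rigid

        cfg = RegNetConfig()
        sets = []
        for s in range(4):
            t = np.array([0.0, 0.0, 2.0]) if s == 0 else np.zeros(3)  # 2 coarse voxels IS
            sets.append(WindowTransformSet(
                [RigidTransform(np.zeros(3), t.copy()) for _ in range(5)]))
        combined = combine_hierarchical(ScaleTransformStack(sets), cfg, np.ones(3))
        # expected displacement: 2 * 2 = 4 full-res voxels along IS
        vol = Volume3D(rng.random((12, 12, 16)), np.ones(3))
        warped = resample_rigid(vol, combined[2], interpolation="nearest")
        np.testing.assert_allclose(warped.voxels[:, :, 4:], vol.voxels[:, :, :-4])


class TestGradientFlow:
    def test_fim_gradients_finite_for_all_parameters(self):
        shape = (16, 24, 32)
        model = build_regnet(tiny_config())
        warper = WindowWarper(shape=shape, spacing=np.ones(3), window_size=5)
        idx = np.indices(shape, dtype=float)
        q = (((idx[0] - 7.5) / 4) ** 2 + ((idx[1] - 11.5) / 6) ** 2 + ((idx[2] - 15.5) / 8) ** 2)
        m_mov = np.exp(-q)
        i_mov = m_mov * (1 + 0.3 * rng.standard_normal(shape))
        mid = shape[0] // 2
        m_fix = np.zeros(shape)
        m_fix[mid - 2 : mid + 3] = np.roll(m_mov, 2, axis=2)[mid - 2 : mid + 3]
        i_fix = np.zeros(shape)
        i_fix[mid - 2 : mid + 3] = np.roll(i_mov, 2, axis=2)[mid - 2 : mid + 3]
        params = model.combined_params(m_mov, m_fix, np.ones(3))
        br = fim_loss(i_fix, i_mov, m_fix, m_mov, params, warper)
        br.total.backward()
        n_grads = 0
        for p in model.param_list():
            if p.grad is not None:
                assert np.all(np.isfinite(p.grad))
                n_grads += 1
        assert n_grads == len(model.param_list())


class TestConvergenceDirection:
    def test_hierarchical_reaches_threshold_before_single_scale(self):
        """On a fixed misaligned phantom window, the 4-scale hierarchical
        model reaches the single-scale model's final loss in fewer steps."""
        shape = (16, 24, 32)
        warper = WindowWarper(shape=shape, spacing=np.ones(3), window_size=5)
        idx = np.indices(shape, dtype=float)
        q = (((idx[0] - 7.5) / 4) ** 2 + ((idx[1] - 11.5) / 6) ** 2 + ((idx[2] - 15.5) / 8) ** 2)
        m_mov = np.exp(-q)
        i_mov = m_mov.copy()
        offset = 4
        mid = shape[0] // 2
        m_fix = np.zeros(shape)
        m_fix[mid - 2 : mid + 3] = np.roll(m_mov, offset, axis=2)[mid - 2 : mid + 3]
        i_fix = m_fix.copy()

        def run(cfg, steps=40):
            model = build_regnet(cfg)
            opt = Adam(model.param_list(), lr=3e-3)
            losses = []
            for _ in range(steps):
                opt.zero_grad()
                params = model.combined_params(m_mov, m_fix, np.ones(3))
                br = fim_loss(i_fix, i_mov, m_fix, m_mov, params, warper)
                br.total.backward()
                opt.step()
                losses.append(br.total.item())
            return np.array(losses)

        hier = run(tiny_config(seed=0))
        single = run(tiny_config(seed=0, emit_scales=(3,)))
        threshold = single.min()
        steps_hier = int(np.argmax(hier <= threshold)) if np.any(hier <= threshold) else len(hier)
        assert steps_hier < len(single)
        assert hier.min() <= single.min()
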