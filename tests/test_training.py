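"""Transform sampling, view generation, loss functions, and their gradients."""

import numpy as np
import pytest

from lodestar.model import FeatureMapStack, pooled_prediction, train_weights
from lodestar.nn import Conv2d, MaxPool2, ReLU, Sequential
from lodestar.simulate import (GridSpec, OpticalConfig, SceneTruth,
                               default_shape, render_shape, simulate_hologram)
from lodestar.training import (TrainConfig, TransformSpec, batch_losses,
                               consistency_loss, internal_loss,
                               invert_prediction, sample_transform, train,
                               transform_image)


class TestSampleTransform:
    def test_degenerate_ranges_give_identity(self, rng):
        cfg = TrainConfig(translation_range=0.0, rotations=False, reflections=False,
                          contrast_range=0.0)
        sp = sample_transform(cfg, rng)
        assert sp.translation == (0.0, 0.0) and sp.angle == 0.0
        assert not sp.flip_x and not sp.flip_y and sp.dz is None and sp.ln_scale is None
        assert sp.contrast is None

    def test_distributions(self):
        rng = np.random.default_rng(0)
        cfg = TrainConfig(translation_range=8.0)
        draws = [sample_transform(cfg, rng) for _ in range(10_000)]
        angles = np.array([d.angle for d in draws])
        trans = np.array([d.translation for d in draws])
        assert abs(angles.mean() - np.pi) < 3 * (2 * np.pi / np.sqrt(12)) / 100
        assert np.all(np.abs(trans.mean(axis=0)) < 3 * (16 / np.sqrt(12)) / 100)
        flips = np.array([d.flip_x for d in draws])
        assert abs(flips.mean() - 0.5) < 0.02

    def test_seeded_reproducibility(self):
        cfg = TrainConfig(dz_range=1.0, ln_scale_range=0.5)
        a = [sample_transform(cfg, np.random.default_rng(4)) for _ in range(5)]
        b = [sample_transform(cfg, np.random.default_rng(4)) for _ in range(5)]
        assert a == b


class TestTransformImage:
    def test_identity_exact(self, rng):
        img = rng.random((48, 48))
        out = transform_image(img, TransformSpec())
        assert np.allclose(out, img, atol=1e-12)

    def test_rotation_pi_of_symmetric_disk(self):
        grid = GridSpec(48, 48)
        img = render_shape(default_shape("sphere"), (23.5, 23.5), 0.0, grid)
        out = transform_image(img, TransformSpec(angle=np.pi))
        assert np.abs(out - img).max() / img.max() < 1e-3

    def test_translation_against_cross_correlation(self):
        grid = GridSpec(64, 64)
        img = render_shape(default_shape("point"), (31.5, 31.5), 0.0, grid)
        shift = (3.5, -2.25)
        out = transform_image(img, TransformSpec(translation=shift))
        # locate the translated peak by quadratic interpolation of the
        # cross-correlation through its maximum
        from scipy.signal import fftconvolve

        corr = fftconvolve(out - out.min(), (img - img.min())[::-1, ::-1], mode="same")
        pk = np.unravel_index(np.argmax(corr), corr.shape)

        def subpix(v, i):
            d = (v[i + 1] - v[i - 1]) / (2 * (2 * v[i] - v[i + 1] - v[i - 1]))
            return i + d

        est = (
            subpix(corr[:, pk[1]], pk[0]) - (corr.shape[0] // 2),
            subpix(corr[pk[0], :], pk[1]) - (corr.shape[1] // 2),
        )
        assert abs(est[0] - shift[0]) < 0.1 and abs(est[1] - shift[1]) < 0.1

    def test_complex_field_extras_route(self, rng):
        optics = OpticalConfig()
        truth = SceneTruth.from_records([{"x": 23.5, "y": 23.5, "radius": 0.228,
                                          "refractive_index": 1.5}])
        fld, _ = simulate_hologram(truth, optics, snr=None, grid=GridSpec(48, 48, optics.pixel_size))
        sp = TransformSpec(ln_scale=np.log(2.0))
        out = transform_image(fld, sp, optics)
        assert np.allclose(np.abs(out.values - 1.0), 2 * np.abs(fld.values - 1.0), atol=1e-9)

    def test_translation_margin_guard(self, rng):
        with pytest.raises(ValueError):
            transform_image(rng.random((8, 8)), TransformSpec(translation=(6.0, 0.0)))


class TestInvertPrediction:
    def test_identity_and_roundtrip(self, rng):
        from lodestar.model import PooledPrediction

        sp = TransformSpec((3.0, -2.0), 1.1, True, False, dz=1.5, ln_scale=0.3)
        p0 = PooledPrediction(20.0, 25.0, np.array([2.0, 0.7]))
        # forward-transform the point by hand, then invert
        c = np.array([23.5, 23.5])
        q = sp.matrix @ (np.array([20.0, 25.0]) - c) + c + np.array(sp.translation)
        moved = PooledPrediction(q[0], q[1], p0.extras + sp.extra_offsets())
        back = invert_prediction(moved, sp, (48, 48))
        assert np.allclose([back.x, back.y], [p0.x, p0.y], atol=1e-10)
        assert np.allclose(back.extras, p0.extras, atol=1e-10)
        ident = invert_prediction(p0, TransformSpec(), (48, 48))
        assert (ident.x, ident.y) == (p0.x, p0.y)

    def test_dz_subtraction(self):
        from lodestar.model import PooledPrediction

        sp = TransformSpec(dz=1.5)
        p = PooledPrediction(1.0, 1.0, np.array([2.0]))
        assert invert_prediction(p, sp, (48, 48)).extras[0] == pytest.approx(0.5)


class TestLosses:
    def test_consistency_loss_hand_values(self):
        assert consistency_loss(np.array([[0.0], [2.0]])) == pytest.approx(2.0)
        assert consistency_loss(np.array([[1.0, 2.0]] * 4)) == 0.0

    def test_consistency_loss_permutation_invariant(self, rng):
        preds = rng.standard_normal((8, 3))
        perm = preds[rng.permutation(8)]
        assert consistency_loss(preds) == pytest.approx(consistency_loss(perm))

    def test_internal_loss_cases(self, rng):
        w = np.full((4, 4), 1 / 16)
        const = np.ones((4, 4, 2))
        assert internal_loss(const, np.array([1.0, 1.0]), w) == 0.0
        w1 = np.zeros((4, 4))
        w1[2, 1] = 1.0
        maps = rng.standard_normal((4, 4, 1))
        pooled = np.array([0.3])
        assert internal_loss(maps, pooled, w1) == pytest.approx(abs(maps[2, 1, 0] - 0.3))

    def test_internal_loss_brute_force(self, rng):
        maps = rng.standard_normal((6, 5, 3))
        pooled = rng.standard_normal(3)
        w = rng.random((6, 5))
        brute = sum(
            abs(maps[i, j, c] - pooled[c]) * w[i, j]
            for i in range(6) for j in range(5) for c in range(3)
        )
        assert internal_loss(maps, pooled, w) == pytest.approx(brute, rel=1e-10)


class TestBatchLosses:
    def _setup(self, rng, extras=2):
        K, n, m = 4, 6, 5
        C = 3 + extras
        out = rng.standard_normal((K, n, m, C))
        specs = [
            TransformSpec(tuple(rng.uniform(-3, 3, 2)), rng.uniform(0, 2 * np.pi),
                          bool(rng.random() < 0.5), bool(rng.random() < 0.5),
                          rng.uniform(-1, 1) if extras >= 1 else None,
                          rng.uniform(-0.5, 0.5) if extras >= 2 else None)
            for _ in range(K)
        ]
        masks = (rng.random((K, n, m)) >= 0.01).astype(float)
        return out, specs, masks, (2 * n, 2 * m)

    def test_gradient_matches_finite_differences(self, rng):
        out, specs, masks, shape = self._setup(rng)
        _, _, grad = batch_losses(out, specs, shape, 2, masks)

        def loss(o):
            a, b, _ = batch_losses(o, specs, shape, 2, masks)
            return a + b

        eps = 1e-6
        for _ in range(40):
            ix = tuple(rng.integers(s) for s in out.shape)
            o1, o2 = out.copy(), out.copy()
            o1[ix] += eps
            o2[ix] -= eps
            fd = (loss(o1) - loss(o2)) / (2 * eps)
            assert grad[ix] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_agrees_with_reference_ops(self, rng):
        """The vectorized batch computation must reproduce the per-view ops:
        train weights, pooled prediction, inverse transform, both losses."""
        from lodestar.model import position_maps

        out, specs, masks, shape = self._setup(rng)
        la, lb, _ = batch_losses(out, specs, shape, 2, masks)
        K = out.shape[0]
        inverted, lb_ref = [], 0.0
        for k in range(K):
            stack = FeatureMapStack(out[k], shape, 2)
            s = 1.0 / (1.0 + np.exp(-stack.rho))
            num = 1e-6 + s * masks[k]
            w = num / num.sum()
            p = pooled_prediction(stack, weights=w)
            inv = invert_prediction(p, specs[k], shape)
            inverted.append([inv.x, inv.y, *inv.extras])
            x, y = position_maps(stack, convention="top-left")
            maps = np.concatenate([x[..., None], y[..., None], stack.extras], axis=-1)
            lb_ref += internal_loss(maps, np.array([p.x, p.y, *p.extras]), w)
        la_ref = consistency_loss(np.array(inverted))
        assert la == pytest.approx(la_ref, rel=1e-9)
        assert lb == pytest.approx(lb_ref, rel=1e-9)

    def test_identical_views_zero_consistency_loss(self, rng):
        K, n, m = 3, 6, 6
        out = np.tile(rng.standard_normal((1, n, m, 3)), (K, 1, 1, 1))
        specs = [TransformSpec() for _ in range(K)]
        masks = np.ones((K, n, m))
        la, lb, _ = batch_losses(out, specs, (12, 12), 2, masks)
        assert la == pytest.approx(0.0, abs=1e-10)
        assert lb >= 0.0

    def test_constant_maps_zero_internal_loss(self):
        K, n, m = 2, 5, 5
        out = np.zeros((K, n, m, 3))
        out[..., 0] = 1.3  # constant dx
        out[..., 1] = -0.4
        # constant decoded maps would need dx to cancel the grid ramp
        gi = np.arange(n)[:, None] * 2.0
        gj = np.arange(m)[None, :] * 2.0
        out[..., 0] = 5.0 - gi
        out[..., 1] = 5.0 - gj
        specs = [TransformSpec() for _ in range(K)]
        la, lb, _ = batch_losses(out, specs, (10, 10), 2, np.ones((K, n, m)))
        assert lb == pytest.approx(0.0, abs=1e-10)
        assert la == pytest.approx(0.0, abs=1e-10)


class TestTrainLoop:
    def _tiny_net(self, seed=0):
        rng = np.random.default_rng(seed)
        return Sequential([
            Conv2d(1, 8, 3, rng), ReLU(), MaxPool2(),
            Conv2d(8, 8, 3, rng), ReLU(), Conv2d(8, 3, 1, rng),
        ])

    def _crop(self):
        grid = GridSpec(32, 32)
        return render_shape(default_shape("point"), (15.5, 15.5), 0.0, grid)

    def test_zero_steps_leaves_network_unchanged(self):
        net = self._tiny_net()
        before = [p.copy() for p in net.params]
        train(self._crop(), TrainConfig(n_batches=0, translation_range=4.0), net)
        for p, b in zip(net.params, before):
            assert np.array_equal(p, b)

    def test_same_seed_identical_history(self):
        cfg = TrainConfig(n_batches=3, translation_range=4.0, seed=11)
        h1 = train(self._crop(), cfg, self._tiny_net(1))
        h2 = train(self._crop(), cfg, self._tiny_net(1))
        assert h1["loss_a"] == h2["loss_a"]
        assert h1["loss_b"] == h2["loss_b"]

    def test_losses_finite_and_recorded(self):
        cfg = TrainConfig(n_batches=5, translation_range=4.0)
        hist = train(self._crop(), cfg, self._tiny_net(2))
        assert len(hist["loss_a"]) == 5
        assert np.all(np.isfinite(hist["loss_a"]))
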