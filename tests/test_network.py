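"""UNet architecture contracts, training behaviour, tiled inference."""

import numpy as np
import pytest

from somaloc.core import Volume
from somaloc.nn import (
    NetworkConfig,
    UNet3D,
    bce_loss,
    build_unet,
    cosine_warm_restart_lr,
    predict_soft,
    scaled_down_config,
    train,
)
from somaloc.nn.training import TrainingDiverged
from somaloc.phantom import PhantomConfig, generate_slab
from somaloc.targets import make_soft_target

TINY = NetworkConfig(
    n_levels=1, res_blocks_per_level=1, base_filters=4, stem_kernel=3, epochs=2, seed=0
)


class TestArchitecture:
    def test_output_shape_and_range(self):
        m = UNet3D(TINY)
        out = m.predict(np.random.default_rng(0).random((16, 16, 16), dtype=np.float32))
        assert out.shape == (16, 16, 16)
        assert np.all((out > 0) & (out < 1))

    def test_zero_weights_give_half_everywhere(self):
        m = UNet3D(TINY)
        for _, v, _ in m.params():
            v[...] = 0.0
        out = m.predict(np.zeros((8, 8, 8), dtype=np.float32))
        np.testing.assert_allclose(out, 0.5, atol=1e-7)

    def test_full_profile_parameter_count_near_18m(self):
        _, n = build_unet(NetworkConfig())
        assert abs(n - 18e6) / 18e6 < 0.25

    def test_indivisible_input_raises_with_divisor(self):
        m = UNet3D(scaled_down_config())
        with pytest.raises(ValueError, match="divisible by 4"):
            m.forward_logits(np.zeros((10, 12, 12), dtype=np.float32))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = UNet3D(TINY)
        x = rng.random((4, 4, 4)).astype(np.float32)
        y = (rng.random((4, 4, 4)) > 0.7).astype(np.float32)
        _, d = bce_loss(m.forward_logits(x), y)
        m.zero_grad()
        m.backward(d)
        check_rng = np.random.default_rng(1)
        rows = []
        for _, v, g in m.params():
            flat, gf = v.ravel(), g.ravel()
            for idx in check_rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps, old = 1e-3, flat[idx]
                flat[idx] = old + eps
                lp = bce_loss(m.forward_logits(x), y)[0]
                flat[idx] = old - eps
                lm = bce_loss(m.forward_logits(x), y)[0]
                flat[idx] = old
                rows.append(((lp - lm) / (2 * eps), float(gf[idx])))
        gmax = max(abs(a) for _, a in rows)
        for num, ana in rows:
            # float32 finite differences: absolute agreement at the scale of
            # the gradient distribution
            assert abs(num - ana) <= 3e-3 * gmax + 2e-4


class TestTraining:
    def _pair(self, seed, shape=(16, 16, 16), density=25_000):
        cfg = PhantomConfig(shape=shape, density=density, min_separation_um=8, seed=seed)
        vol, centers = generate_slab(cfg)
        assert len(centers) > 0
        soft, _ = make_soft_target(centers, shape)
        return vol, soft

    def test_same_seed_identical_histories(self):
        pair = self._pair(3)
        hists = []
        for _ in range(2):
            cfg = NetworkConfig(
                n_levels=1, res_blocks_per_level=1, base_filters=4,
                stem_kernel=3, epochs=3, seed=5,
            )
            m = UNet3D(cfg)
            hists.append(train(m, [pair], cfg))
        assert hists[0] == hists[1]

    def test_lr_returns_to_max_at_restart(self):
        lrs = [cosine_warm_restart_lr(e, 0.1, 0.001, 50) for e in range(120)]
        assert lrs[0] == pytest.approx(0.1)
        assert lrs[50] == pytest.approx(0.1)
        assert lrs[100] == pytest.approx(0.1)
        assert lrs[49] < 0.01

    def test_loss_trends_down_over_first_50_epochs(self):
        pairs = [self._pair(seed) for seed in (10, 11, 12, 13)]
        cfg = scaled_down_config(epochs=50, restart_period=50, seed=1)
        m = UNet3D(cfg)
        hist = train(m, pairs, cfg)
        assert np.mean(hist[-10:]) < np.mean(hist[:10])

    def test_overfits_single_sparse_pair(self):
        # capacity check: a sparse 32-cube pair whose soft target has a BCE
        # entropy floor well below 0.01 (soft labels make zero unreachable)
        cfg_p = PhantomConfig(shape=(32, 32, 32), density=800, min_separation_um=20, seed=6)
        vol, centers = generate_slab(cfg_p)
        soft, _ = make_soft_target(centers, (32, 32, 32), bounds=(1.0, 1.2))
        y = soft.data
        floor = float(np.mean(-(np.where(y > 0, y * np.log(np.maximum(y, 1e-12)), 0)
                                + (1 - y) * np.log1p(-np.minimum(y, 1 - 1e-12)))))
        assert floor < 0.008  # sparse enough for the target bound
        cfg = scaled_down_config(epochs=300, restart_period=300, lr_max=0.15, seed=2)
        m = UNet3D(cfg)
        train(m, [(vol, soft)], cfg, crop_shape=(16, 16, 16))
        from somaloc.nn.ops import percentile_normalize

        final, _ = bce_loss(m.forward_logits(percentile_normalize(vol.data)), y)
        assert final < 0.01

    def test_nan_loss_aborts_with_diagnostic(self):
        vol = Volume(np.random.default_rng(0).random((8, 8, 8)))
        bad = np.full((8, 8, 8), np.nan)  # raw grid: Volume rejects non-finite
        cfg = NetworkConfig(
            n_levels=1, res_blocks_per_level=1, base_filters=4,
            stem_kernel=3, epochs=2, seed=0,
        )
        m = UNet3D(cfg)
        with pytest.raises(TrainingDiverged, match="epoch 0"):
            train(m, [(vol, bad)], cfg)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train(UNet3D(TINY), [], TINY)


class TestPredictSoft:
    def test_single_tile_equals_direct_forward(self, rng):
        m = UNet3D(TINY)
        x = rng.random((16, 16, 16)).astype(np.float32)
        direct = m.predict(x)
        tiled = predict_soft(m, x, tile_shape=(16, 16, 16), normalize=False)
        np.testing.assert_allclose(tiled.data, direct, atol=1e-6)

    def test_two_tilings_agree_in_interior(self, rng):
        # blending contract probed with a translation-equivariant local
        # operator (receptive field < overlap); a normalisation-bearing
        # network adds tile-statistics drift on top of this guarantee
        class BlurModel:
            class cfg:
                divisor = 1

            @staticmethod
            def predict(x):
                from scipy.ndimage import gaussian_filter

                return gaussian_filter(x, 1.0, truncate=2.0)

        x = rng.random((24, 24, 24)).astype(np.float32)
        m = BlurModel()
        a = predict_soft(m, x, tile_shape=(16, 16, 16), overlap=8, normalize=False).data
        b = predict_soft(m, x, tile_shape=(24, 24, 16), overlap=8, normalize=False).data
        interior = (slice(6, 18),) * 3
        assert np.abs(a[interior] - b[interior]).max() < 1e-3

    def test_constant_zero_model_gives_half_field(self, rng):
        m = UNet3D(TINY)
        for _, v, _ in m.params():
            v[...] = 0.0
        x = rng.random((24, 24, 24)).astype(np.float32)
        out = predict_soft(m, x, tile_shape=(16, 16, 16), overlap=4, normalize=False)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-6)

    def test_oversized_tile_pads_and_crops(self, rng):
        m = UNet3D(TINY)
        x = rng.random((12, 12, 12)).astype(np.float32)
        out = predict_soft(m, x, tile_shape=(16, 16, 16), normalize=False)
        assert out.data.shape == (12, 12, 12)
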