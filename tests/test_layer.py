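"""Saliency-layer forward paths, pooling, scale fitting, baseline units."""

import numpy as np
import pytest

from hdsn.frontend import ChannelStack
from hdsn.ggd import GGDClassModel
from hdsn.layer import (
    ChannelModels,
    PoolingSpec,
    RBFSpec,
    baseline_unit,
    fit_channel_scales,
    forward_algorithmic,
    forward_bio,
    forward_nn,
    pool_average,
    pool_max,
)
from hdsn.synth import sample_ggd

POOL = PoolingSpec(spatial_extent=5, scale_depth=2, stride=3)


def _random_models(rng, n):
    out = []
    for _ in range(n):
        a0, a1 = np.exp(rng.uniform(np.log(0.5), np.log(4.0), size=2))
        out.append(GGDClassModel(scale_pow_background=a0, scale_pow_target=a1, shape=0.5))
    return ChannelModels(models=out)


class TestFitChannelScales:
    def test_identical_samples_silent_channels(self, rng):
        x = [rng.standard_normal(200) for _ in range(3)]
        models = fit_channel_scales(x, x)
        assert np.all(models.gains == 0.0)
        assert np.all(models.thresholds == 0.0)

    def test_presence_and_absence_signs(self):
        strong = [sample_ggd(4.0, 0.5, 50_000, seed=1)]
        weak = [sample_ggd(1.0, 0.5, 50_000, seed=2)]
        presence = fit_channel_scales(strong, weak)
        assert presence.gains[0] > 0 and presence.thresholds[0] > 0
        absence = fit_channel_scales(weak, strong)
        assert absence.gains[0] < 0 and absence.thresholds[0] < 0

    def test_channel_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fit_channel_scales([rng.standard_normal(10)],
                               [rng.standard_normal(10), rng.standard_normal(10)])


class TestForwardPaths:
    def test_silent_models_zero_map(self, small_stack):
        models = ChannelModels(models=[GGDClassModel(1.0, 1.0)] * 3)
        out = forward_nn(small_stack, models, POOL)
        assert all(np.all(m == 0.0) for m in out.maps)
        alg = forward_algorithmic(small_stack, models, POOL)
        assert all(np.all(m == 0.0) for m in alg.maps)

    def test_single_neighborhood_hand_case(self):
        # complex unit averaging rectified LLR values {-1, 2, 4, -3} over its
        # full window: S = (0 + 2 + 4 + 0) / 4 = 1.5
        llr = np.array([[-1.0, 2.0], [4.0, -3.0]])
        stack = ChannelStack(maps=[np.maximum(llr, 0.0)[None]])
        pool = PoolingSpec(spatial_extent=2, scale_depth=1, stride=1)
        pooled = pool_average(stack, pool)
        # the window fully covering the map sits at index (1, 1)
        assert pooled.maps[0][0, 1, 1] == pytest.approx(1.5)

    def test_nn_equals_rectified_llr_average(self, rng, small_stack, presence_models):
        nn = forward_nn(small_stack, presence_models, POOL)
        # independent evaluation: rectified LLR then pool_average
        gains = presence_models.gains[:, None, None]
        thr = presence_models.thresholds[:, None, None]
        psi = [np.maximum(gains * np.abs(m) ** 0.5 - thr, 0.0) for m in small_stack.maps]
        ref = pool_average(ChannelStack(maps=psi), POOL)
        for a, b in zip(nn.maps, ref.maps):
            assert np.max(np.abs(a - b)) < 1e-12

    def test_bio_equals_nn_canonical(self, rng):
        for trial in range(20):
            maps = [rng.standard_normal((3, 12, 12)), rng.standard_normal((3, 9, 9))]
            stack = ChannelStack(maps=maps)
            models = _random_models(rng, 3)
            nn = forward_nn(stack, models, POOL)
            bio = forward_bio(stack, models, POOL)
            half = forward_bio(stack, models, POOL, xi_variant="paper")
            for a, b, c in zip(nn.maps, bio.maps, half.maps):
                assert np.max(np.abs(a - b)) < 1e-9
                assert np.max(np.abs(a / 2 - c)) < 1e-9

    def test_jensen_bound_prior_disabled(self, rng):
        for trial in range(20):
            stack = ChannelStack(maps=[rng.standard_normal((2, 11, 11))])
            models = _random_models(rng, 2)
            nn = forward_nn(stack, models, POOL)
            alg = forward_algorithmic(stack, models, POOL, prior=None)
            for a, b in zip(nn.maps, alg.maps):
                assert np.all(b <= np.maximum(a, 0.0) + 1e-12)

    def test_nonnegative_and_channel_preserving(self, small_stack, presence_models):
        for fwd in (forward_nn, forward_bio):
            out = fwd(small_stack, presence_models, POOL)
            assert out.n_channels == small_stack.n_channels
            assert all(np.all(m >= 0) for m in out.maps)

    def test_matched_training_near_silent_on_noise(self, rng):
        # both classes trained on the same distribution: the layer stays quiet
        samples = [rng.standard_normal(20_000) for _ in range(2)]
        other = [rng.standard_normal(20_000) for _ in range(2)]
        models = fit_channel_scales(samples, other)
        stack = ChannelStack(maps=[rng.standard_normal((2, 20, 20))])
        out = forward_nn(stack, models, POOL)
        assert np.mean(out.maps[0]) < 1e-2

    def test_pooling_window_misfit(self, presence_models):
        stack = ChannelStack(maps=[np.ones((3, 3, 3))])
        with pytest.raises(ValueError, match="pooling"):
            forward_nn(stack, presence_models, POOL)


class TestPooling:
    def test_constant_map_fixed_point(self):
        stack = ChannelStack(maps=[np.full((1, 7, 7), 2.5)])
        pool = PoolingSpec(spatial_extent=3, scale_depth=1, stride=1)
        assert np.allclose(pool_average(stack, pool).maps[0], 2.5)
        assert np.allclose(pool_max(stack, pool).maps[0], 2.5)

    def test_whole_map_window(self):
        m = np.arange(1.0, 10.0).reshape(1, 3, 3)
        stack = ChannelStack(maps=[m])
        pool = PoolingSpec(spatial_extent=3, scale_depth=1, stride=1)
        assert pool_average(stack, pool).maps[0][0, 1, 1] == pytest.approx(5.0)
        assert pool_max(stack, pool).maps[0][0, 1, 1] == pytest.approx(9.0)

    def test_cross_scale_pooling_combines_levels(self):
        maps = [np.full((1, 8, 8), 1.0), np.full((1, 4, 4), 3.0)]
        stack = ChannelStack(maps=maps)
        pool = PoolingSpec(spatial_extent=3, scale_depth=2, stride=1)
        avg = pool_average(stack, pool)
        assert np.allclose(avg.maps[0], 2.0)   # equal-weight scale mean
        assert np.allclose(pool_max(stack, pool).maps[0], 3.0)

    def test_stride_subsampling_and_grid_meta(self):
        stack = ChannelStack(maps=[np.random.default_rng(0).random((1, 12, 12))])
        pool = PoolingSpec(spatial_extent=3, scale_depth=1, stride=3)
        out = pool_average(stack, pool)
        assert out.maps[0].shape == (1, 4, 4)
        assert out.grid_meta[0] == {"origin": 1.0, "stride": 3.0}


class TestBaselineUnits:
    def _stack_and_templates(self, rng, n=3):
        stack = ChannelStack(maps=[rng.random((2, 10, 10))])
        templates = [rng.standard_normal((3, 3, 2)) for _ in range(n)]
        return stack, templates

    def test_exact_match_gives_maximum_lu(self, rng):
        stack = ChannelStack(maps=[rng.random((2, 10, 10))])
        patch = np.transpose(stack.maps[0][:, 2:5, 2:5], (1, 2, 0))
        lu = baseline_unit(stack, [patch], kind="LU", rbf=RBFSpec(sharpness=1.0))
        # at the sampling location (window center) the distance is zero
        assert lu.maps[0][0, 3, 3] == pytest.approx(1.0, abs=1e-9)
        assert lu.maps[0].max() == pytest.approx(1.0, abs=1e-9)

    def test_pu_sums_to_one(self, rng):
        stack, templates = self._stack_and_templates(rng)
        pu = baseline_unit(stack, templates, kind="PU")
        assert np.allclose(pu.maps[0].sum(axis=0), 1.0, atol=1e-9)

    def test_vector_quantizer_limit(self, rng):
        # sharpness -> 0+: soft assignment hardens to the nearest template
        stack, templates = self._stack_and_templates(rng)
        pu = baseline_unit(stack, templates, kind="PU", rbf=RBFSpec(sharpness=1e-3))
        # one-hot wherever the nearest template is unique (ties stay split)
        assert np.mean(pu.maps[0].max(axis=0) > 0.999) > 0.9

    def test_cpu_class_sums(self, rng):
        stack, templates = self._stack_and_templates(rng, n=4)
        pu = baseline_unit(stack, templates, kind="PU")
        cpu = baseline_unit(stack, templates, kind="CPU",
                            class_index_sets=[[0, 1], [2, 3]])
        assert cpu.maps[0].shape[0] == 2
        assert np.allclose(cpu.maps[0][0], pu.maps[0][:2].sum(axis=0))

    def test_empty_template_set_rejected(self, rng):
        stack, _ = self._stack_and_templates(rng)
        with pytest.raises(ValueError):
            baseline_unit(stack, [], kind="LU")
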