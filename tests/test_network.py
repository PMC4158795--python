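"""Network assembly, training, features, channel selection, persistence."""

import numpy as np
import pytest

from hdsn.config import RunConfig
from hdsn.frontend import ChannelStack
from hdsn.ggd import GGDClassModel
from hdsn.layer import ChannelModels
from hdsn.network import (
    HDSN,
    HDSNResults,
    fit_classifier,
    predict_class,
    sample_templates,
    select_channels,
)
from hdsn.synth import background_scene, make_classification_dataset, make_scene, scene_for_class

SMALL_CFG = RunConfig(n_scales=6, templates_per_class=3, template_sizes=(4, 8),
                      pool_scale_depths=(3,), pool_area_fracs=(0.2,))


@pytest.fixture(scope="module")
def small_dataset():
    return make_classification_dataset(2, 4, seed=21, size=64, box_side=24)


@pytest.fixture(scope="module")
def trained(small_dataset):
    return HDSN(small_dataset.targets, small_dataset.background, SMALL_CFG).fit(seed=3)


class TestTraining:
    def test_feature_dimension_bookkeeping(self, trained):
        assert trained.feature_dim == 2 * 3
        f = trained.extract_features(np.random.default_rng(0).random((64, 64)))
        assert f.shape == (6,)
        assert np.all(f >= 0.0)

    def test_determinism(self, small_dataset):
        a = HDSN(small_dataset.targets, small_dataset.background, SMALL_CFG).fit(seed=3)
        b = HDSN(small_dataset.targets, small_dataset.background, SMALL_CFG).fit(seed=3)
        img = small_dataset.targets["class0"][0]
        assert np.array_equal(a.extract_features(img), b.extract_features(img))
        for label in a.labels:
            assert np.array_equal(a.class_params[label]["models"].gains,
                                  b.class_params[label]["models"].gains)

    def test_matched_background_near_silent(self, small_dataset):
        imgs = small_dataset.background
        res = HDSN({"null": imgs}, imgs, RunConfig(n_scales=6, templates_per_class=0)).fit(
            seed=0, n_layers=1)
        gains = res.class_params["null"]["models"].gains
        assert np.max(np.abs(gains)) < 1e-12  # identical sample sets per channel

    def test_empty_inputs_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            HDSN({}, small_dataset.background)
        with pytest.raises(ValueError):
            HDSN({"a": []}, small_dataset.background)
        with pytest.raises(ValueError):
            HDSN(small_dataset.targets, [])

    def test_summary_mentions_classes_and_features(self, trained):
        text = trained.summary()
        assert "class0" in text and "class1" in text
        assert "feature dimension: 6" in text


class TestEndToEndSelectivity:
    def test_target_images_score_higher_than_background(self, small_dataset, trained):
        # mean feature response under a class's own templates: target vs texture
        tgt = small_dataset.targets["class0"][0]
        bg = small_dataset.background[0]
        f_t = trained.extract_features(tgt)[:3].mean()
        f_b = trained.extract_features(bg)[:3].mean()
        assert f_t != f_b  # responses are class sensitive
        smap_t = trained.saliency_map(tgt, "class0", layer=1)
        assert smap_t.min() >= 0.0 and smap_t.shape == tgt.shape

    def test_orientation_selectivity_of_layer1(self):
        # 0-degree targets in orthogonal texture: the 0-degree Gabor channel
        # carries the largest trained saliency and ranks first in selection
        from hdsn.experiments import _easy_spec, _scene_seeds

        rng = np.random.default_rng(0)
        imgs = [make_scene(_easy_spec(s, size=64))[0] for s in _scene_seeds(rng, 6)]
        bg = [background_scene(size=64, seed=s, orientations=(np.pi / 2,), noise=0.02,
                               jitter_deg=0.0, amplitude_mod=0.0)
              for s in _scene_seeds(rng, 6)]
        res = HDSN({"t": imgs}, bg, RunConfig(n_scales=6, templates_per_class=0)).fit(
            seed=0, n_layers=1)
        models = res.class_params["t"]["models"]
        frontend_stacks = [res._frontend.stack(im) for im in imgs]
        _, sel = select_channels(models, frontend_stacks, 1)
        assert models.labels[sel[0]] == "gabor_0"


class TestSelectChannels:
    def _models(self):
        return ChannelModels(models=[
            GGDClassModel(1.0, 2.0), GGDClassModel(1.0, 1.0), GGDClassModel(1.0, 1.5)],
            labels=["a", "b", "c"])

    def test_identity_when_k_covers_all(self, rng):
        models = self._models()
        sub, sel = select_channels(models, [], 3)
        assert sel == [0, 1, 2] and sub is models

    def test_silent_channel_never_selected(self, rng):
        models = self._models()
        # responses large enough to clear the dead zones of the tuned channels
        stacks = [ChannelStack(maps=[100.0 * rng.standard_normal((3, 12, 12))])]
        _, sel = select_channels(models, stacks, 2)
        assert 1 not in sel  # gain-zero channel has zero pooled saliency

    def test_k_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            select_channels(self._models(), [], 0)


class TestSampleTemplates:
    def _stacks(self, rng, value=None):
        maps = [rng.random((2, 16, 16)) if value is None else np.full((2, 16, 16), value)]
        return [ChannelStack(maps=maps)]

    def test_deterministic_given_seed(self, rng):
        stacks = self._stacks(np.random.default_rng(5))
        a = sample_templates(stacks, (4, 8), 5, np.random.default_rng(7))
        b = sample_templates(stacks, (4, 8), 5, np.random.default_rng(7))
        for x, y in zip(a, b):
            assert np.array_equal(x.patch, y.patch) and x.origin == y.origin

    def test_patch_normalization_and_depth(self, rng):
        tmpl = sample_templates(self._stacks(rng), (8,), 3, rng)
        for t in tmpl:
            assert t.patch.shape == (8, 8, 2)
            assert abs(t.patch.mean()) < 1e-9
            assert np.linalg.norm(t.patch) == pytest.approx(1.0, abs=1e-9)
            assert t.pooling.scale_depth in (3, 5, 7)
            assert t.pooling.spatial_extent in (0.10, 0.20, 0.30)

    def test_constant_output_rejected(self, rng):
        with pytest.raises(ValueError, match="template"):
            sample_templates(self._stacks(rng, value=0.0), (4,), 2, rng)

    def test_impossible_fit_rejected(self, rng):
        stacks = [ChannelStack(maps=[rng.random((2, 3, 3))])]
        with pytest.raises(ValueError):
            sample_templates(stacks, (8, 16), 2, rng)


class TestClassifier:
    def test_separable_toy_is_perfect(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        y = ["a"] * 5 + ["b"] * 5
        clf = fit_classifier(X, y)
        assert list(predict_class(X, clf)) == y

    def test_order_invariance(self, rng):
        X = rng.random((20, 4))
        y = ["a"] * 10 + ["b"] * 10
        clf = fit_classifier(X, y)
        perm = rng.permutation(20)
        clf2 = fit_classifier(X[perm], [y[i] for i in perm])
        probe = rng.random((8, 4))
        assert list(predict_class(probe, clf)) == list(predict_class(probe, clf2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_classifier(np.ones((4, 2)), ["a"] * 4)


class TestPersistence:
    def test_roundtrip_is_lossless(self, trained, small_dataset, tmp_path):
        path = tmp_path / "model.h5"
        trained.save(path)
        back = HDSNResults.load(path)
        img = small_dataset.targets["class1"][2]
        assert np.array_equal(trained.extract_features(img), back.extract_features(img))
        assert list(trained.predict([img])) == list(back.predict([img]))
        for label in trained.labels:
            a = trained.class_params[label]
            b = back.class_params[label]
            assert np.array_equal(a["models"].gains, b["models"].gains)
            assert a["norm_scale"] == b["norm_scale"]
            for ta, tb in zip(a["templates"], b["templates"]):
                assert np.array_equal(ta.patch, tb.patch)
                assert ta.origin == tb.origin and ta.pooling == tb.pooling
                assert ta.model == tb.model

    def test_save_twice_identical_content(self, trained, tmp_path):
        p1, p2 = tmp_path / "m1.h5", tmp_path / "m2.h5"
        trained.save(p1)
        trained.save(p2)
        a, b = HDSNResults.load(p1), HDSNResults.load(p2)
        for label in a.labels:
            assert np.array_equal(
                a.class_params[label]["models"].gains, b.class_params[label]["models"].gains)


class TestSaliencyAndDetection:
    def test_layer2_requires_two_layer_model(self, small_dataset):
        res = HDSN(small_dataset.targets, small_dataset.background,
                   RunConfig(n_scales=6, templates_per_class=0)).fit(seed=0, n_layers=1)
        with pytest.raises(RuntimeError):
            res.saliency_map(small_dataset.targets["class0"][0], "class0", layer=2)

    def test_unknown_class_rejected(self, trained, small_dataset):
        with pytest.raises(KeyError):
            trained.saliency_map(small_dataset.targets["class0"][0], "nope")

    def test_detect_returns_valid_boxes(self, trained, small_dataset):
        img = small_dataset.targets["class0"][0]
        boxes = trained.detect(img, "class0", box_size=24, layer=1)
        for b in boxes:
            assert 0 <= b.x and b.x + b.w <= 64 and 0 <= b.y and b.y + b.h <= 64
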