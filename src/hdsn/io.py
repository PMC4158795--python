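"""HDF5 persistence of trained networks.

A single hierarchical file holds every array (template patches, scale
powers, classifier weights) as float64 datasets plus a JSON echo of the run
configuration, so a saved network reloads losslessly.

Schema (version 1)::

    /                 attrs: format_version, config_json, labels_json, seed, n_layers
    /class/<label>/   attrs: selected (indices), channel_labels_json
        scale_pow_background, scale_pow_target      (C,) float64
        templates/<i>/  attrs: origin_image, origin_scale, origin_row, origin_col,
                               pool_area_frac, pool_scale_depth, center (3,),
                               scale_pow_background, scale_pow_target (absent
                               until layer 2 is fitted)
            patch       (n, n, C) float64
    /classifier/      coef, intercept, classes_json   (only if fitted)
"""

from __future__ import annotations

import json

import h5py
import numpy as np
from sklearn.svm import LinearSVC

from .config import RunConfig
from .ggd import GGDClassModel
from .layer import ChannelModels, PoolingSpec

FORMAT_VERSION = 1

__all__ = ["save_results", "load_results"]


def _ds(group, name, data):
    group.create_dataset(name, data=np.asarray(data, dtype=np.float64), track_times=False)


def save_results(results, path):
    from .network import HDSNResults  # noqa: F401  (documents the contract)

    with h5py.File(path, "w", libver="latest") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_json"] = json.dumps(results.config.to_dict())
        f.attrs["labels_json"] = json.dumps(results.labels)
        f.attrs["seed"] = results.seed
        f.attrs["n_layers"] = results.n_layers
        croot = f.create_group("class")
        for label in results.labels:
            p = results.class_params[label]
            g = croot.create_group(label)
            g.attrs["selected"] = np.asarray(p["selected"], dtype=np.int64)
            g.attrs["norm_scale"] = float(p.get("norm_scale", 0.0))
            g.attrs["channel_labels_json"] = json.dumps(p["models"].labels)
            _ds(g, "scale_pow_background",
                [m.scale_pow_background for m in p["models"].models])
            _ds(g, "scale_pow_target", [m.scale_pow_target for m in p["models"].models])
            tg = g.create_group("templates")
            for i, tmpl in enumerate(p["templates"]):
                t = tg.create_group(str(i))
                _ds(t, "patch", tmpl.patch)
                t.attrs["origin_image"] = tmpl.origin[0]
                t.attrs["origin_scale"] = tmpl.origin[1]
                t.attrs["origin_row"] = tmpl.origin[2][0]
                t.attrs["origin_col"] = tmpl.origin[2][1]
                t.attrs["pool_area_frac"] = tmpl.pooling.spatial_extent
                t.attrs["pool_scale_depth"] = tmpl.pooling.scale_depth
                t.attrs["center"] = np.asarray(tmpl.pooling.center, dtype=np.int64)
                if tmpl.model is not None:
                    t.attrs["scale_pow_background"] = tmpl.model.scale_pow_background
                    t.attrs["scale_pow_target"] = tmpl.model.scale_pow_target
        if results.classifier is not None:
            cg = f.create_group("classifier")
            _ds(cg, "coef", results.classifier.coef_)
            _ds(cg, "intercept", results.classifier.intercept_)
            _ds(cg, "feature_mean", results.feature_mean)
            _ds(cg, "feature_std", results.feature_std)
            cg.attrs["classes_json"] = json.dumps(list(results.classifier.classes_))


def load_results(path):
    from .network import HDSNResults, SaliencyTemplate

    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise RuntimeError(f"model file format v{version} not supported (expect v{FORMAT_VERSION})")
        config = RunConfig.from_dict(json.loads(f.attrs["config_json"]))
        labels = json.loads(f.attrs["labels_json"])
        seed = int(f.attrs["seed"])
        n_layers = int(f.attrs["n_layers"])
        class_params = {}
        for label in labels:
            g = f["class"][label]
            a0 = np.asarray(g["scale_pow_background"])
            a1 = np.asarray(g["scale_pow_target"])
            ch_labels = json.loads(g.attrs["channel_labels_json"])
            models = ChannelModels(
                models=[GGDClassModel(scale_pow_background=float(b), scale_pow_target=float(t),
                                      shape=config.shape) for b, t in zip(a0, a1)],
                labels=ch_labels)
            templates = []
            tg = g["templates"]
            for i in sorted(tg, key=int):
                t = tg[i]
                center = tuple(int(v) for v in t.attrs["center"])
                pooling = PoolingSpec(kind="template-centered",
                                      spatial_extent=float(t.attrs["pool_area_frac"]),
                                      scale_depth=int(t.attrs["pool_scale_depth"]),
                                      center=center)
                model = None
                if "scale_pow_background" in t.attrs:
                    model = GGDClassModel(
                        scale_pow_background=float(t.attrs["scale_pow_background"]),
                        scale_pow_target=float(t.attrs["scale_pow_target"]),
                        shape=config.shape)
                templates.append(SaliencyTemplate(
                    patch=np.asarray(t["patch"]),
                    origin=(int(t.attrs["origin_image"]), int(t.attrs["origin_scale"]),
                            (int(t.attrs["origin_row"]), int(t.attrs["origin_col"]))),
                    pooling=pooling, class_label=label, model=model))
            class_params[label] = {"models": models,
                                   "selected": [int(v) for v in g.attrs["selected"]],
                                   "templates": templates,
                                   "norm_scale": float(g.attrs.get("norm_scale", 0.0))}
        classifier = None
        feature_mean = feature_std = None
        if "classifier" in f:
            cg = f["classifier"]
            classifier = LinearSVC(C=config.classifier_c, dual=False)
            classifier.coef_ = np.asarray(cg["coef"])
            classifier.intercept_ = np.asarray(cg["intercept"])
            classifier.classes_ = np.asarray(json.loads(cg.attrs["classes_json"]))
            feature_mean = np.asarray(cg["feature_mean"])
            feature_std = np.asarray(cg["feature_std"])
    results = HDSNResults(config=config, class_params=class_params, labels=labels,
                          seed=seed, n_layers=n_layers, classifier=classifier,
                          feature_mean=feature_mean, feature_std=feature_std)
    return results
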