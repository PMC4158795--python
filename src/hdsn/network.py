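"""The hierarchical discriminant saliency network (HDSN).

``HDSN`` is a model object built from class-labeled images plus a pool of
"natural background" (null-class) images; ``fit`` trains the two-layer
network and returns an ``HDSNResults`` carrying all estimated parameters:

* layer 1: per-class, per-channel GGD scale powers fitted on Gabor (and
  optionally DCT) responses pooled over the entire channel, with the
  class-tuned parametric-ReLU rectifiers they induce, and optionally the
  most salient channel subset;
* layer 2: per class, randomly sampled multi-channel saliency templates,
  each with its own pooling neighborhood and GGD model fitted on the
  template's correlation responses;
* a linear maximum-margin classifier on the layer-2 complex-unit features
  (one feature per template, concatenated across classes).

Training is deterministic given (data, config, seed), and results
round-trip through the HDF5 container losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from . import locdet
from .config import RunConfig
from .frontend import (
    ChannelStack,
    build_dct_bank,
    build_gabor_bank,
    build_pyramid,
    contrast_normalize,
    convolve_bank,
    max_feasible_scales,
)
from .ggd import EstimatorPrior, GGDClassModel, rectifier_from_model
from .layer import ChannelModels, PoolingSpec, fit_channel_scales, forward_nn
from scipy.ndimage import correlate
from skimage.transform import resize

__all__ = [
    "SaliencyTemplate",
    "HDSN",
    "HDSNResults",
    "sample_templates",
    "select_channels",
    "fit_classifier",
    "predict_class",
    "train_network",
]


@dataclass
class SaliencyTemplate:
    """A layer-2 template: a multi-channel patch sampled from layer-1 output.

    ``patch`` is (n, n, C), zero mean and unit norm over all channels
    jointly.  ``origin`` records where it was sampled (image index, scale
    index, (row, col) of the patch's top-left corner on the layer-1 C grid);
    the template's complex unit is centered there.  ``pooling`` is the
    template-specific neighborhood (area fraction and scale depth);
    ``model`` the GGD class model fitted to the template's correlation
    responses once layer 2 is trained.
    """

    patch: np.ndarray
    origin: tuple
    pooling: PoolingSpec
    class_label: str
    model: GGDClassModel | None = None

    @property
    def size(self) -> int:
        return self.patch.shape[0]

    @property
    def rectifier(self):
        if self.model is None:
            raise RuntimeError("template has no fitted scale model yet")
        return rectifier_from_model(self.model)


class _Frontend:
    """Filter banks + pyramid: image -> multi-scale multi-channel stack."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.banks = [build_gabor_bank(config.gabor)]
        if config.use_dct:
            self.banks.append(build_dct_bank(config.dct_size))
        self.kernel_size = max(b.kernel_size for b in self.banks)
        self.labels = [lab for b in self.banks for lab in b.labels]

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def stack(self, image) -> ChannelStack:
        image = np.asarray(image, dtype=float)
        n = max_feasible_scales(image.shape, self.config.n_scales, self.kernel_size,
                                self.config.factor_base)
        if n < 1:
            raise ValueError(f"image {image.shape} smaller than the filter kernel "
                             f"{self.kernel_size}")
        pyr = build_pyramid(image, n, self.config.factor_base, min_size=self.kernel_size)
        per_bank = [convolve_bank(pyr, b) for b in self.banks]
        maps = [np.concatenate([pb.maps[s] for pb in per_bank]) for s in range(n)]
        return ChannelStack(maps=maps, labels=list(self.labels), factors=list(pyr.factors))


def _subset_stack(stack: ChannelStack, idx) -> ChannelStack:
    idx = list(idx)
    out = stack.copy_with([m[idx] for m in stack.maps])
    out.labels = [stack.labels[i] for i in idx] if stack.labels else []
    return out


def _channel_samples(stacks, cap, rng):
    """Pool responses over all locations, scales and images, per channel."""
    C = stacks[0].n_channels
    per_channel = [[] for _ in range(C)]
    for st in stacks:
        for m in st.maps:
            flat = m.reshape(C, -1)
            for c in range(C):
                per_channel[c].append(flat[c])
    out = []
    for c in range(C):
        vals = np.concatenate(per_channel[c])
        if cap is not None and vals.size > cap:
            vals = vals[rng.choice(vals.size, size=cap, replace=False)]
        out.append(vals)
    return out


def select_channels(models: ChannelModels, feature_stacks, k):
    """Keep the k channels of largest whole-field pooled saliency.

    Per channel, the saliency score is the mean rectified LLR over every
    location and scale of every training stack; ties break by channel index
    (stable ordering).  Returns (subset models, selected indices).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= len(models):
        return models, list(range(len(models)))
    gains = models.gains[:, None]
    thresholds = models.thresholds[:, None]
    total = np.zeros(len(models))
    count = 0
    for st in feature_stacks:
        for m in st.maps:
            u = np.power(np.abs(m.reshape(len(models), -1)), models.shape)
            total += np.maximum(gains * u - thresholds, 0.0).sum(axis=1)
            count += m.shape[1] * m.shape[2]
    scores = total / max(count, 1)
    order = np.lexsort((np.arange(len(models)), -scores))
    sel = sorted(order[:k].tolist())
    return models.subset(sel), sel


def sample_templates(layer1_stacks, sizes, count, rng, area_fracs=(0.10, 0.20, 0.30),
                     scale_depths=(3, 5, 7), class_label="", max_attempts=200):
    """Randomly sample zero-mean unit-norm templates from layer-1 saliency output.

    Draws (size, image, scale, location) uniformly among feasible choices;
    patches of negligible norm are rejected and redrawn.  Deterministic
    given the generator state.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    sizes = [int(s) for s in sizes]
    feasible_any = any(min(m.shape[1:]) >= min(sizes)
                       for st in layer1_stacks for m in st.maps)
    if not feasible_any:
        raise ValueError("no pyramid level can fit any requested template size")
    templates = []
    for _ in range(count):
        for _attempt in range(max_attempts):
            n = sizes[rng.integers(len(sizes))]
            img = int(rng.integers(len(layer1_stacks)))
            st = layer1_stacks[img]
            scales = [s for s, m in enumerate(st.maps) if min(m.shape[1:]) >= n]
            if not scales:
                continue
            s = scales[rng.integers(len(scales))]
            H, W = st.maps[s].shape[1:]
            r = int(rng.integers(0, H - n + 1))
            c = int(rng.integers(0, W - n + 1))
            patch = np.transpose(st.maps[s][:, r:r + n, c:c + n], (1, 2, 0)).astype(float).copy()
            patch -= patch.mean()
            norm = np.linalg.norm(patch)
            if norm < 1e-9:
                continue
            patch /= norm
            pooling = PoolingSpec(kind="template-centered",
                                  spatial_extent=float(area_fracs[rng.integers(len(area_fracs))]),
                                  scale_depth=int(scale_depths[rng.integers(len(scale_depths))]),
                                  center=(s, r + n // 2, c + n // 2))
            templates.append(SaliencyTemplate(patch=patch, origin=(img, s, (r, c)),
                                              pooling=pooling, class_label=class_label))
            break
        else:
            raise ValueError("could not sample a non-degenerate template "
                             "(layer-1 output everywhere ~zero?)")
    return templates


# ---------------------------------------------------------------------------
# layer-2 machinery

def _template_scale_span(template: SaliencyTemplate, n_scales: int):
    s0 = template.origin[1]
    d = template.pooling.scale_depth
    lo = max(0, s0 - d // 2)
    hi = min(n_scales, s0 + d // 2 + 1)
    return range(lo, hi)

def _template_response(ybar: ChannelStack, template: SaliencyTemplate, scale: int):
    """Correlation of the normalized layer-1 output with the template at one scale."""
    m = ybar.maps[scale]
    n = template.size
    if min(m.shape[1:]) < n:
        return None
    resp = np.zeros(m.shape[1:])
    for c in range(m.shape[0]):
        resp += correlate(m[c], template.patch[:, :, c], mode="constant", cval=0.0)
    return resp


def _pool_window(resp, template, scale, origin_shape):
    """Samples of a response map inside the template's pooling neighborhood.

    The window is a square whose area is the template's area fraction of the
    map at this scale, centered at the template's origin location mapped by
    the map-shape ratio, clipped at the map borders.
    """
    H, W = resp.shape
    side = max(1, int(round(np.sqrt(template.pooling.spatial_extent * H * W))))
    r0, c0 = template.pooling.center[1], template.pooling.center[2]
    r = int(round(r0 * H / origin_shape[0]))
    c = int(round(c0 * W / origin_shape[1]))
    half = side // 2
    rows = slice(max(0, r - half), min(H, r - half + side))
    cols = slice(max(0, c - half), min(W, c - half + side))
    return resp[rows, cols].ravel()


def _collect_template_samples(ybar_by_size, template, n_scales):
    origin_scale = template.origin[1]
    origin_shape = ybar_by_size[template.size].maps[origin_scale].shape[1:]
    vals = []
    for s in _template_scale_span(template, n_scales):
        resp = _template_response(ybar_by_size[template.size], template, s)
        if resp is None:
            continue
        vals.append(_pool_window(resp, template, s, origin_shape))
    return np.concatenate(vals) if vals else np.array([])


def _normalized_by_size(y1: ChannelStack, sizes, saturation=0.0):
    return {n: contrast_normalize(y1, window=int(n), saturation=saturation)
            for n in set(int(s) for s in sizes)}


def _mean_cross_channel_energy(stacks):
    """Mean per-location cross-channel saliency over a list of stacks.

    Used as the trained semisaturation level of the layer-2 input
    normalization: the typical layer-1 response of the class at training
    time defines the unit's operating point."""
    total, count = 0.0, 0
    for st in stacks:
        for m in st.maps:
            total += float(np.abs(m).sum())
            count += m.shape[1] * m.shape[2]
    return total / max(count, 1)


# ---------------------------------------------------------------------------
# classifier ops

def fit_classifier(features, labels, C=1.0):
    """Linear maximum-margin classifier (one-vs-rest for multiclass)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    clf = LinearSVC(C=C, dual=False)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def predict_class(features, classifier):
    """Argmax-class predictions of a fitted linear classifier."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return classifier.predict(features)


# ---------------------------------------------------------------------------
# the model object

class HDSN:
    """Hierarchical discriminant saliency network model.

    Parameters
    ----------
    targets : mapping of class label -> list of 2-D grayscale images in [0, 1]
    background : list of 2-D images of the null (natural background) class
    config : RunConfig, defaults to the reference configuration

    ``fit(seed)`` trains the network; see ``HDSNResults``.
    """

    def __init__(self, targets, background, config: RunConfig | None = None):
        if not targets:
            raise ValueError("at least one target class required")
        for label, imgs in targets.items():
            if not imgs:
                raise ValueError(f"class {label!r} has no images")
        if not background:
            raise ValueError("background image set must be non-empty")
        self.targets = {str(k): [np.asarray(im, dtype=float) for im in v]
                        for k, v in targets.items()}
        self.background = [np.asarray(im, dtype=float) for im in background]
        self.config = config or RunConfig()

    @classmethod
    def from_directories(cls, target_dir, background_dir, config: RunConfig | None = None):
        """Build from class subdirectories of rasters plus a background directory."""
        from pathlib import Path

        from .frontend import load_image

        config = config or RunConfig()
        target_dir, background_dir = Path(target_dir), Path(background_dir)
        if not target_dir.is_dir():
            raise IOError(f"target directory not readable: {target_dir}")
        if not background_dir.is_dir():
            raise IOError(f"background directory not readable: {background_dir}")
        exts = {".png", ".jpg", ".jpeg", ".pgm", ".tif", ".tiff"}
        def _images(d):
            return [load_image(p, max_side=config.max_side)
                    for p in sorted(d.iterdir()) if p.suffix.lower() in exts]
        bg_resolved = background_dir.resolve()
        classes = [d for d in sorted(target_dir.iterdir())
                   if d.is_dir() and d.resolve() != bg_resolved]
        if classes:
            targets = {d.name: _images(d) for d in classes}
        else:
            targets = {target_dir.name: _images(target_dir)}
        return cls(targets, _images(background_dir), config)

    @property
    def prior(self) -> EstimatorPrior:
        return EstimatorPrior(eta=self.config.eta, nu=self.config.nu)

    def _layer1_pooling(self) -> PoolingSpec:
        cfg = self.config
        return PoolingSpec(kind="uniform-grid", spatial_extent=cfg.layer1_pool_extent,
                           scale_depth=cfg.layer1_pool_depth, stride=cfg.layer1_c_stride)

    def fit(self, seed: int = 0, n_layers: int = 2) -> "HDSNResults":
        """Train the network; deterministic given (data, config, seed)."""
        if n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 or 2")
        cfg = self.config
        frontend = _Frontend(cfg)
        prior = self.prior
        l1_pool = self._layer1_pooling()
        labels = list(self.targets)
        ss = np.random.SeedSequence(seed)
        class_seeds = ss.spawn(len(labels))

        bg_stacks = [frontend.stack(im) for im in self.background]
        class_params = {}
        for label, cseed in zip(labels, class_seeds):
            rng = np.random.default_rng(cseed)
            tgt_stacks = [frontend.stack(im) for im in self.targets[label]]
            t_samples = _channel_samples(tgt_stacks, cfg.max_train_samples_per_channel, rng)
            b_samples = _channel_samples(bg_stacks, cfg.max_train_samples_per_channel, rng)
            models = fit_channel_scales(t_samples, b_samples, shape=cfg.shape, prior=prior,
                                        labels=frontend.labels)
            if cfg.n_selected_channels is not None:
                models, sel = select_channels(models, tgt_stacks, cfg.n_selected_channels)
            else:
                sel = list(range(frontend.n_channels))
            templates = []
            norm_scale = 0.0
            if n_layers >= 2 and cfg.templates_per_class > 0:
                y1_t = [forward_nn(_subset_stack(st, sel), models, l1_pool) for st in tgt_stacks]
                y1_b = [forward_nn(_subset_stack(st, sel), models, l1_pool) for st in bg_stacks]
                templates = sample_templates(
                    y1_t, cfg.template_sizes, cfg.templates_per_class, rng,
                    area_fracs=cfg.pool_area_fracs, scale_depths=cfg.pool_scale_depths,
                    class_label=label)
                norm_scale = _mean_cross_channel_energy(y1_t)
                t_norm = [_normalized_by_size(y, cfg.template_sizes, norm_scale) for y in y1_t]
                b_norm = [_normalized_by_size(y, cfg.template_sizes, norm_scale) for y in y1_b]
                for tmpl in templates:
                    tgt_vals = np.concatenate(
                        [_collect_template_samples(nb, tmpl, len(nb[tmpl.size].maps))
                         for nb in t_norm] or [np.array([])])
                    bg_vals = np.concatenate(
                        [_collect_template_samples(nb, tmpl, len(nb[tmpl.size].maps))
                         for nb in b_norm] or [np.array([])])
                    a1 = _map_estimate(tgt_vals, cfg.shape, prior)
                    a0 = _map_estimate(bg_vals, cfg.shape, prior)
                    tmpl.model = GGDClassModel(scale_pow_background=a0, scale_pow_target=a1,
                                               shape=cfg.shape)
            class_params[label] = {"models": models, "selected": sel, "templates": templates,
                                   "norm_scale": norm_scale if templates else 0.0}

        results = HDSNResults(config=cfg, class_params=class_params, labels=labels,
                              seed=seed, n_layers=n_layers)
        if n_layers >= 2 and len(labels) >= 2 and cfg.templates_per_class > 0:
            feats, ys = [], []
            for label in labels:
                for im in self.targets[label]:
                    feats.append(results.extract_features(im))
                    ys.append(label)
            feats = np.array(feats)
            # template gains vary over orders of magnitude, so features do not
            # share a natural scale; standardize before the margin classifier
            mu = feats.mean(axis=0)
            sd = feats.std(axis=0)
            sd[sd == 0] = 1.0
            results.feature_mean = mu
            results.feature_std = sd
            results.classifier = fit_classifier((feats - mu) / sd, ys, C=cfg.classifier_c)
        return results


def _map_estimate(samples, shape, prior):
    from .ggd import map_scale_estimate
    return map_scale_estimate(samples, shape=shape, prior=prior)


class HDSNResults:
    """Trained HDSN: estimated parameters plus feature/saliency/decision methods."""

    def __init__(self, config, class_params, labels, seed, n_layers=2, classifier=None,
                 feature_mean=None, feature_std=None):
        self.config = config
        self.class_params = class_params
        self.labels = labels
        self.seed = seed
        self.n_layers = n_layers
        self.classifier = classifier
        self.feature_mean = feature_mean
        self.feature_std = feature_std
        self._frontend = _Frontend(config)

    def _standardize(self, feats):
        if self.feature_mean is None:
            return feats
        return (feats - self.feature_mean) / self.feature_std

    # -- feature extraction -------------------------------------------------
    def _layer1_output(self, image, label):
        p = self.class_params[label]
        stack = self._frontend.stack(image)
        sub = _subset_stack(stack, p["selected"])
        pool = PoolingSpec(kind="uniform-grid", spatial_extent=self.config.layer1_pool_extent,
                           scale_depth=self.config.layer1_pool_depth,
                           stride=self.config.layer1_c_stride)
        return forward_nn(sub, p["models"], pool)

    def extract_features(self, image) -> np.ndarray:
        """One non-negative scalar per template, concatenated across classes."""
        if self.n_layers < 2:
            raise RuntimeError("feature extraction requires a two-layer network")
        feats = []
        for label in self.labels:
            p = self.class_params[label]
            y1 = self._layer1_output(image, label)
            norm = _normalized_by_size(y1, self.config.template_sizes,
                                       p.get("norm_scale", 0.0))
            for tmpl in p["templates"]:
                vals = _collect_template_samples(norm, tmpl, y1.n_scales)
                if vals.size == 0:
                    feats.append(0.0)
                    continue
                r = tmpl.rectifier
                psi = np.maximum(r.gain * np.power(np.abs(vals), r.shape) - r.threshold, 0.0)
                feats.append(float(psi.mean()))
        return np.array(feats)

    def predict(self, images):
        """Predicted class labels for a list of images."""
        if self.classifier is None:
            raise RuntimeError("no classifier was fitted (need >= 2 classes, 2 layers)")
        feats = np.array([self.extract_features(im) for im in images])
        return predict_class(self._standardize(feats), self.classifier)

    def decision_scores(self, image):
        if self.classifier is None:
            raise RuntimeError("no classifier was fitted")
        f = self._standardize(self.extract_features(image))[None, :]
        return self.classifier.decision_function(f).ravel()

    # -- saliency maps ------------------------------------------------------
    def saliency_map(self, image, label, layer=None) -> np.ndarray:
        """Class saliency map: rectified unit outputs summed over channels and
        scales, resampled to the input resolution.

        ``layer=1`` sums the layer-1 parametric-ReLU responses; ``layer=2``
        (default for a two-layer network) sums the rectified layer-2
        template responses.
        """
        if label not in self.class_params:
            raise KeyError(f"unknown class {label!r}")
        layer = layer or self.n_layers
        image = np.asarray(image, dtype=float)
        base_shape = image.shape
        p = self.class_params[label]
        if layer == 1:
            stack = self._frontend.stack(image)
            sub = _subset_stack(stack, p["selected"])
            models = p["models"]
            gains = models.gains[:, None, None]
            thr = models.thresholds[:, None, None]
            total = np.zeros(base_shape)
            for m in sub.maps:
                psi = np.maximum(gains * np.power(np.abs(m), models.shape) - thr, 0.0)
                total += resize(psi.sum(axis=0), base_shape, anti_aliasing=False)
            return total
        if layer == 2:
            if self.n_layers < 2 or not p["templates"]:
                raise RuntimeError("layer-2 saliency requires a trained two-layer network")
            y1 = self._layer1_output(image, label)
            norm = _normalized_by_size(y1, self.config.template_sizes,
                                       p.get("norm_scale", 0.0))
            total = np.zeros(base_shape)
            for tmpl in p["templates"]:
                r = tmpl.rectifier
                # only scales inside the template's pooling span: the unit's
                # GGD model was fitted on responses from those scales
                for s in _template_scale_span(tmpl, y1.n_scales):
                    resp = _template_response(norm[tmpl.size], tmpl, s)
                    if resp is None:
                        continue
                    psi = np.maximum(r.gain * np.power(np.abs(resp), r.shape) - r.threshold, 0.0)
                    total += resize(psi, base_shape, anti_aliasing=False)
            return total
        raise ValueError("layer must be 1 or 2")

    def detect(self, image, label, box_size=None, layer=None):
        """Box-filter + NMS detections on the class saliency map."""
        cfg = self.config
        box = box_size or cfg.box_size
        if box is None:
            raise ValueError("box_size must be given (config.box_size unset)")
        smap = self.saliency_map(image, label, layer=layer)
        return locdet.detect(smap, box, nms_iou=cfg.nms_iou, n_max=cfg.n_max_detections,
                             threshold=cfg.detect_threshold)

    # -- bookkeeping ---------------------------------------------------------
    @property
    def feature_dim(self) -> int:
        return sum(len(p["templates"]) for p in self.class_params.values())

    def summary(self) -> str:
        """Human-readable account of the trained network."""
        cfg = self.config
        lines = []
        lines.append("Hierarchical Discriminant Saliency Network")
        lines.append("=" * 58)
        lines.append(f"layers: {self.n_layers}    classes: {len(self.labels)}    "
                     f"seed: {self.seed}")
        lines.append(f"front end: {self._frontend.n_channels} channels, "
                     f"{cfg.n_scales} scales (factors 2^(i/4)), beta={cfg.shape}")
        lines.append(f"feature dimension: {self.feature_dim}")
        lines.append("-" * 58)
        lines.append(f"{'class':<12}{'channels':>9}{'templates':>11}"
                     f"{'max|gain|':>12}{'neg gains':>10}")
        for label in self.labels:
            p = self.class_params[label]
            gains = p["models"].gains
            lines.append(f"{label:<12}{len(p['selected']):>9}{len(p['templates']):>11}"
                         f"{np.max(np.abs(gains)):>12.4f}{int(np.sum(gains < 0)):>10}")
        lines.append("-" * 58)
        if self.classifier is not None:
            lines.append(f"classifier: linear SVM (C={cfg.classifier_c}, one-vs-rest), "
                         f"{self.classifier.coef_.shape[0]} decision function(s)")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        from .io import save_results
        save_results(self, path)

    @classmethod
    def load(cls, path):
        from .io import load_results
        return load_results(path)


def train_network(targets, background, config=None, seed=0, n_layers=2) -> HDSNResults:
    """Functional wrapper: build an ``HDSN`` model and fit it."""
    return HDSN(targets, background, config).fit(seed=seed, n_layers=n_layers)
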