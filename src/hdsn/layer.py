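"""One discriminant saliency layer: simple and complex sub-layers.

A saliency layer classifies each feature response of a channel stack as
target vs background and pools the evidence.  Its simple (S) sub-layer is a
grid of discriminant units sharing per-channel GGD class models; its complex
(C) sub-layer averages rectified evidence over a pooling neighborhood that
spans space and adjacent pyramid scales, then subsamples to the C grid.

The layer admits three provably related forward implementations:

``forward_nn``
    Parametric-ReLU rectification psi(x) = max(gamma |x|^beta - T, 0)
    followed by average pooling (the neural-network path).
``forward_bio``
    Differential divisive normalization -> sigmoid -> the logit-style
    nonlinearity xi -> additive pooling (the biologically plausible path).
    With the canonical xi(p) = log(p/(1-p)) for p >= 1/2 (0 otherwise) this
    equals ``forward_nn`` exactly, since xi(sigma(g)) = max(g, 0); a printed
    variant of xi carries a 1/2 factor, making the output forward_nn / 2.
``forward_algorithmic``
    Per neighborhood, a local MAP estimate of the target scale power
    followed by the closed-form expected saliency gamma * alpha1^beta(l) - T
    (a local KL divergence).  Not rectified per sample, so it can go
    negative; by Jensen's inequality it never exceeds ``forward_nn`` when
    the estimator prior is disabled.

Cross-scale pooling maps coarser-scale coordinates by the scale-factor
ratio (nearest pixel, no value resampling) and weighs each scale equally:
the pooled value is the mean of the per-scale clipped-window means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate, maximum_filter, uniform_filter
from scipy.special import expit, logit

from .frontend import ChannelStack
from .ggd import (
    EstimatorPrior,
    GGDClassModel,
    RectifierParams,
    abs_pow,
    map_scale_estimate,
    rectifier_from_model,
)

__all__ = [
    "PoolingSpec",
    "ChannelModels",
    "RBFSpec",
    "fit_channel_scales",
    "forward_nn",
    "forward_bio",
    "forward_algorithmic",
    "pool_average",
    "pool_max",
    "baseline_unit",
]


@dataclass(frozen=True)
class PoolingSpec:
    """Where and how widely complex units pool simple-unit responses.

    kind : "uniform-grid" pools every location and subsamples by ``stride``;
        "template-centered" pools a single neighborhood around ``center``.
    spatial_extent : odd window side in grid units (uniform kind) or the
        fraction of map area covered (template-centered kind).
    scale_depth : number of adjacent pyramid levels spanned (current plus
        next coarser ones, clipped at the pyramid end).
    center : (scale_index, row, col) for the template-centered kind.
    """

    kind: str = "uniform-grid"
    spatial_extent: float = 5
    scale_depth: int = 2
    center: tuple | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("uniform-grid", "template-centered"):
            raise ValueError(f"unknown pooling kind {self.kind!r}")
        if self.scale_depth < 1:
            raise ValueError("scale_depth must be >= 1")
        if self.kind == "uniform-grid":
            if int(self.spatial_extent) < 1:
                raise ValueError("spatial_extent must be >= 1")
            if self.stride < 1:
                raise ValueError("stride must be >= 1")
        else:
            if not 0 < self.spatial_extent <= 1:
                raise ValueError("template-centered extent is an area fraction in (0, 1]")
            if self.center is None:
                raise ValueError("template-centered pooling requires a center")


@dataclass
class ChannelModels:
    """Per-channel two-class GGD models with their derived rectifiers."""

    models: list
    rectifiers: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rectifiers:
            self.rectifiers = [rectifier_from_model(m) for m in self.models]
        if len(self.rectifiers) != len(self.models):
            raise ValueError("one rectifier per model required")
        for m, r in zip(self.models, self.rectifiers):
            ref = rectifier_from_model(m)
            if not (np.isclose(ref.gain, r.gain) and np.isclose(ref.threshold, r.threshold)):
                raise ValueError("rectifier parameters inconsistent with their GGD model")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(len(self.models))]

    def __len__(self) -> int:
        return len(self.models)

    @property
    def gains(self):
        return np.array([r.gain for r in self.rectifiers])

    @property
    def thresholds(self):
        return np.array([r.threshold for r in self.rectifiers])

    @property
    def shape(self):
        return self.models[0].shape

    def subset(self, idx):
        return ChannelModels(models=[self.models[i] for i in idx],
                             rectifiers=[self.rectifiers[i] for i in idx],
                             labels=[self.labels[i] for i in idx])


@dataclass(frozen=True)
class RBFSpec:
    """Tuning of the radial-basis baseline units.

    ``sharpness`` scales the squared distance in exp(-||p - t||^2 / sharpness);
    as sharpness -> 0+ the soft assignment hardens into a vector quantizer.
    (Named to avoid clashing with the GGD shape parameter.)
    """

    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")


def fit_channel_scales(target_responses, background_responses, shape=0.5,
                       prior: EstimatorPrior | None = EstimatorPrior(),
                       labels=None) -> ChannelModels:
    """MAP-fit per-channel target/background scale powers and attach rectifiers.

    ``target_responses`` and ``background_responses`` are equal-length lists
    of per-channel sample arrays (possibly empty: prior-only estimate).
    """
    if len(target_responses) != len(background_responses):
        raise ValueError(
            f"channel count mismatch: {len(target_responses)} target vs "
            f"{len(background_responses)} background")
    if not target_responses:
        raise ValueError("at least one channel required")
    models = []
    for tgt, bg in zip(target_responses, background_responses):
        a1 = map_scale_estimate(tgt, shape=shape, prior=prior)
        a0 = map_scale_estimate(bg, shape=shape, prior=prior)
        models.append(GGDClassModel(scale_pow_background=a0, scale_pow_target=a1, shape=shape))
    return ChannelModels(models=models, labels=list(labels) if labels else [])


# ---------------------------------------------------------------------------
# pooling machinery

def _clipped_window_stats(m, size, reduce):
    """Per-channel windowed mean/max over in-bounds samples only.

    Returns (stat, count) where count is the number of in-bounds samples in
    each window (identical across channels).
    """
    ones = np.ones(m.shape[1:])
    counts = uniform_filter(ones, size=size, mode="constant", cval=0.0) * (size * size)
    counts = np.round(counts)
    if reduce == "mean":
        sums = uniform_filter(m, size=(1, size, size), mode="constant", cval=0.0) * (size * size)
        return sums / counts[None], counts
    if reduce == "max":
        return maximum_filter(m, size=(1, size, size), mode="constant", cval=-np.inf), counts
    raise ValueError(reduce)


def _map_to_scale(src, target_shape):
    """Nearest-pixel coordinate mapping of a (C, h, w) map onto target (H, W)."""
    C, h, w = src.shape
    H, W = target_shape
    rows = np.clip(np.round(np.arange(H) * (h / H)).astype(int), 0, h - 1)
    cols = np.clip(np.round(np.arange(W) * (w / W)).astype(int), 0, w - 1)
    return src[:, rows][:, :, cols]


def _pool_uniform(value_maps, pooling: PoolingSpec, reduce="mean", with_counts=False):
    """Cross-scale pooling on the uniform grid; returns per-scale pooled maps.

    For scale s the neighborhood spans scales s .. s+depth-1 (clipped); each
    contributing scale's clipped-window statistic is computed in its own
    resolution and mapped to scale s by nearest-pixel coordinates, then the
    scales are combined (equal weight for "mean", elementwise for "max").
    """
    size = int(pooling.spatial_extent)
    per_scale = [_clipped_window_stats(m, size, reduce) for m in value_maps]
    pooled, counts_out = [], []
    n_scales = len(value_maps)
    for s in range(n_scales):
        span = range(s, min(s + pooling.scale_depth, n_scales))
        shape_s = value_maps[s].shape[1:]
        stats = [_map_to_scale(per_scale[t][0], shape_s) for t in span]
        cnts = [_map_to_scale(per_scale[t][1][None], shape_s)[0] for t in span]
        if reduce == "mean":
            pooled.append(np.mean(stats, axis=0))
        else:
            pooled.append(np.max(stats, axis=0))
        counts_out.append(np.sum(cnts, axis=0))
    if with_counts:
        return pooled, counts_out
    return pooled


def _subsample(maps, stride, factors=None):
    if stride == 1:
        sub = maps
    else:
        off = stride // 2
        sub = [m[:, off::stride, off::stride] for m in maps]
    return sub


def _grid_meta(stack: ChannelStack, stride):
    off = stride // 2 if stride > 1 else 0
    meta = []
    for s in range(stack.n_scales):
        base = stack.grid_meta[s]
        meta.append({"origin": base["origin"] + off * base["stride"],
                     "stride": base["stride"] * stride})
    return meta


def _finalize(stack: ChannelStack, maps, stride):
    out = stack.copy_with(_subsample(maps, stride))
    out.grid_meta = _grid_meta(stack, stride)
    return out


def _check_pooling(features: ChannelStack, pooling: PoolingSpec):
    size = int(pooling.spatial_extent)
    for s, m in enumerate(features.maps):
        if size > min(m.shape[1:]):
            raise ValueError(f"pooling window {size} exceeds map {m.shape[1:]} at scale {s}")


def pool_average(stack: ChannelStack, pooling: PoolingSpec) -> ChannelStack:
    """Per-channel average over each pooling neighborhood (space x scales)."""
    _check_pooling(stack, pooling)
    return _finalize(stack, _pool_uniform(stack.maps, pooling, "mean"), pooling.stride)


def pool_max(stack: ChannelStack, pooling: PoolingSpec) -> ChannelStack:
    """Per-channel maximum over each pooling neighborhood (space x scales)."""
    _check_pooling(stack, pooling)
    return _finalize(stack, _pool_uniform(stack.maps, pooling, "max"), pooling.stride)


# ---------------------------------------------------------------------------
# the three forward implementations

def _llr_maps(features: ChannelStack, models: ChannelModels):
    if len(models) != features.n_channels:
        raise ValueError(f"{len(models)} channel models for {features.n_channels} channels")
    gains = models.gains[:, None, None]
    thresholds = models.thresholds[:, None, None]
    return [gains * abs_pow(m, models.shape) - thresholds for m in features.maps]


def forward_nn(features: ChannelStack, models: ChannelModels, pooling: PoolingSpec) -> ChannelStack:
    """Neural-network path: parametric ReLU then average pooling."""
    _check_pooling(features, pooling)
    psi = [np.maximum(g, 0.0) for g in _llr_maps(features, models)]
    return _finalize(features, _pool_uniform(psi, pooling, "mean"), pooling.stride)


def forward_bio(features: ChannelStack, models: ChannelModels, pooling: PoolingSpec,
                xi_variant: str = "canonical") -> ChannelStack:
    """Biologically plausible path: divisive normalization, sigmoid, xi, pooling.

    The LLR is produced by differential divisive normalization
    |x|^beta / alpha0^beta - |x|^beta / alpha1^beta - T, passed through the
    sigmoid to a posterior probability, re-expanded by xi, and pooled
    additively.  ``xi_variant="paper"`` keeps the printed 1/2 factor in xi,
    halving the output globally.
    """
    if xi_variant not in ("canonical", "paper"):
        raise ValueError(f"unknown xi variant {xi_variant!r}")
    _check_pooling(features, pooling)
    a0 = np.array([m.scale_pow_background for m in models.models])[:, None, None]
    a1 = np.array([m.scale_pow_target for m in models.models])[:, None, None]
    thresholds = models.thresholds[:, None, None]
    transformed = []
    for m in features.maps:
        u = abs_pow(m, models.shape)
        g = u / a0 - u / a1 - thresholds      # differential divisive normalization
        post = expit(g)                       # posterior of the target class
        xi = np.where(post >= 0.5, logit(np.where(post >= 0.5, post, 0.5)), 0.0)
        if xi_variant == "paper":
            xi = 0.5 * xi
        transformed.append(xi)
    return _finalize(features, _pool_uniform(transformed, pooling, "mean"), pooling.stride)


def forward_algorithmic(features: ChannelStack, models: ChannelModels, pooling: PoolingSpec,
                        prior: EstimatorPrior | None = EstimatorPrior()) -> ChannelStack:
    """Algorithmic path: local scale estimate, then closed-form expected saliency.

    Per neighborhood, the local target scale power alpha1^beta(l) is
    MAP-estimated from the responses in the neighborhood, and the saliency
    is gamma * alpha1^beta(l) - T.  The output is not rectified per sample.
    """
    _check_pooling(features, pooling)
    u_maps = [abs_pow(m, models.shape) for m in features.maps]
    means, counts = _pool_uniform(u_maps, pooling, "mean", with_counts=True)
    gains = models.gains[:, None, None]
    thresholds = models.thresholds[:, None, None]
    out = []
    for mean_u, n in zip(means, counts):
        if prior is None:
            est = mean_u
        else:
            est = (mean_u * n[None] + prior.nu) / (n[None] + prior.eta * models.shape)
        out.append(gains * est - thresholds)
    return _finalize(features, out, pooling.stride)


# ---------------------------------------------------------------------------
# baseline (RBF codebook) units

def baseline_unit(features: ChannelStack, templates, kind="LU",
                  rbf: RBFSpec = RBFSpec(), class_index_sets=None) -> ChannelStack:
    """Radial-basis baseline sub-layer: likelihood (LU), posterior (PU) or
    class-posterior (CPU) units.

    ``templates`` is a list of (n, n, C) arrays.  LU responses are Gaussian
    kernels of the patch-template distance, exp(-||patch - t||^2 / sharpness);
    PU divisively normalizes LU across templates so responses sum to one at
    each location; CPU sums PU over each class's template index set.
    Out-of-bounds patch samples count as zeros (matching the zero-padded
    convolution convention).
    """
    if not templates:
        raise ValueError("empty template set")
    if kind not in ("LU", "PU", "CPU"):
        raise ValueError(f"unknown baseline unit kind {kind!r}")
    if kind == "CPU" and not class_index_sets:
        raise ValueError("CPU units require class_index_sets")
    C = features.n_channels
    log_lu_scales = []
    for s, m in enumerate(features.maps):
        log_lu_maps = []
        for t in templates:
            t = np.asarray(t, dtype=float)
            if t.ndim != 3 or t.shape[2] != C:
                raise ValueError(f"template must be (n, n, {C}), got {t.shape}")
            n = t.shape[0]
            if n > min(m.shape[1:]):
                log_lu_maps.append(np.full(m.shape[1:], -np.inf))
                continue
            # ||p||^2 via windowed sum of squares; <p, t> via correlation
            p_sq = uniform_filter(np.sum(m * m, axis=0), size=n, mode="constant", cval=0.0) * n * n
            dot = np.zeros(m.shape[1:])
            for c in range(C):
                dot += correlate(m[c], t[:, :, c], mode="constant", cval=0.0)
            d2 = np.maximum(p_sq - 2.0 * dot + np.sum(t * t), 0.0)
            log_lu_maps.append(-d2 / rbf.sharpness)
        log_lu_scales.append(np.stack(log_lu_maps))
    if kind == "LU":
        out = [np.exp(ll) for ll in log_lu_scales]
    else:
        # normalize in the log domain: stable down to the hard-assignment limit
        pu_scales = []
        for ll in log_lu_scales:
            finite = np.isfinite(ll).any(axis=0)
            shifted = ll - np.where(finite, ll.max(axis=0), 0.0)[None]
            expd = np.exp(shifted)
            total = expd.sum(axis=0)
            pu = np.where(finite[None], expd / total[None], 1.0 / len(templates))
            pu_scales.append(pu)
        if kind == "PU":
            out = pu_scales
        else:
            out = [np.stack([pu[list(idx)].sum(axis=0) for idx in class_index_sets])
                   for pu in pu_scales]
    labels = ([f"{kind.lower()}{i}" for i in range(len(templates))] if kind != "CPU"
              else [f"cpu{i}" for i in range(len(class_index_sets))])
    res = features.copy_with(out)
    res.labels = labels
    return res
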