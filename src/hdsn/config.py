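"""Run configuration: every tunable of the network in one serializable object.

Defaults reproduce the reference two-layer configuration: ten pyramid
resolutions with subsampling factors 2^(i/4); four 11x11 Gabor channels in
layer 1 with a dense S grid, 3x3x1 C-grid subsampling and a 5x5x2 average
pooling window; layer-2 templates randomly sampled at sizes {4, 8, 12, 16}
with template-specific pooling neighborhoods covering {10, 20, 30}% of the
map over {3, 5, 7} scales; GGD shape 0.5 with the conjugate-prior MAP scale
estimator (eta=1, nu=1e-3); linear SVM with C=1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .frontend import GaborSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # GGD / estimator
    shape: float = 0.5
    eta: float = 1.0
    nu: float = 1e-3

    # front end
    n_scales: int = 10
    factor_base: float = 2.0
    max_side: int | None = None
    gabor: GaborSpec = field(default_factory=GaborSpec)
    use_dct: bool = False
    dct_size: int = 8
    n_selected_channels: int | None = None

    # layer 1
    layer1_pool_extent: int = 5
    layer1_pool_depth: int = 2
    layer1_c_stride: int = 3
    max_train_samples_per_channel: int = 1_000_000

    # layer 2
    templates_per_class: int = 40
    template_sizes: tuple = (4, 8, 12, 16)
    pool_area_fracs: tuple = (0.10, 0.20, 0.30)
    pool_scale_depths: tuple = (3, 5, 7)
    xi_variant: str = "canonical"

    # classifier
    classifier_c: float = 1.0

    # detection
    box_size: int | None = None
    nms_iou: float = 0.5
    match_iou: float = 0.5
    detect_threshold: float = 0.0
    n_max_detections: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.shape <= 2:
            raise ValueError("shape must lie in (0, 2]")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.xi_variant not in ("canonical", "paper"):
            raise ValueError(f"unknown xi variant {self.xi_variant!r}")
        if self.templates_per_class < 0:
            raise ValueError("templates_per_class must be >= 0")
        if self.layer1_c_stride < 1 or self.layer1_pool_extent < 1 or self.layer1_pool_depth < 1:
            raise ValueError("layer-1 grid/pooling parameters must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gabor"] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(self.gabor).items()}
        for key in ("template_sizes", "pool_area_fracs", "pool_scale_depths"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "gabor" in d and not isinstance(d["gabor"], GaborSpec):
            g = dict(d["gabor"])
            if "orientations" in g:
                g["orientations"] = tuple(float(t) for t in g["orientations"])
            d["gabor"] = GaborSpec(**g)
        for key in ("template_sizes", "pool_area_fracs", "pool_scale_depths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls.from_dict(data)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
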