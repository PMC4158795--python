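"""Seeded generators for GGD samples and synthetic textured scenes.

Every stage of the network is testable without external datasets: raw
generalized-Gaussian samplers exercise the scale estimators, and a scene
generator emulates strongly textured backgrounds with embedded targets —
oriented texture patches, bright polygon silhouettes, or *blank* regions
(targets defined by feature absence).  Backgrounds mix two oriented
sinusoidal gratings plus white noise by default, so no single oriented
channel is trivially diagnostic of "background".

All generators are deterministic given their seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

__all__ = [
    "sample_ggd",
    "SceneSpec",
    "make_scene",
    "make_classification_dataset",
    "ClassificationDataset",
    "save_dataset",
]


def sample_ggd(scale, shape, n, seed):
    """Draw i.i.d. samples from the generalized Gaussian GGD(alpha, beta).

    Uses the exact Gamma construction: if X ~ GGD(alpha, beta) then
    |X|^beta ~ Gamma(k=1/beta, theta=alpha^beta), so draws are
    sign * G^(1/beta) with G a Gamma variate.  Implies
    E|X|^beta = alpha^beta / beta.
    """
    if scale <= 0 or shape <= 0:
        raise ValueError(f"scale and shape must be positive, got {scale}, {shape}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = rng.gamma(1.0 / shape, scale**shape, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * np.power(g, 1.0 / shape)


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene: textured background plus one target.

    size : square image side in pixels.
    bg_orientations : grating orientations (radians) mixed in the background.
    bg_wavelength : grating wavelength in pixels.
    noise : white-noise standard deviation added everywhere.
    target_kind : "oriented-patch" (grating at target_orientation),
        "polygon-shape" ("disk" or "triangle" silhouette), or
        "blank" (flat region — a target defined by feature absence).
    target_box : (x, y, w, h), 0-based half-open, inside the image.
    contrast : target amplitude relative to the nominal background amplitude;
        0 with a background-matched orientation makes the target invisible.
    amplitude_mod : strength of the smooth contrast-modulation field applied
        to the oriented textures (0 disables it); emulates the non-uniform
        contrast of natural textures.
    """

    size: int = 96
    bg_orientations: tuple = (np.deg2rad(30.0), np.deg2rad(120.0))
    bg_wavelength: float = 7.0
    noise: float = 0.05
    amplitude_mod: float = 0.6
    target_kind: str = "oriented-patch"
    target_orientation: float = 0.0
    target_shape: str = "disk"
    target_box: tuple = (32, 32, 32, 32)
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        x, y, w, h = self.target_box
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > self.size or y + h > self.size:
            raise ValueError(f"target box {self.target_box} not inside {self.size}x{self.size} image")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if self.target_kind not in ("oriented-patch", "polygon-shape", "blank"):
            raise ValueError(f"unknown target kind {self.target_kind!r}")


def _grating(size, theta, wavelength, phase):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase)


def _amplitude_field(rng, size, strength=0.6, smoothness=None):
    """Smooth positive contrast-modulation field with mean ~1.

    Natural textures are not uniform-contrast: their bandpass response
    amplitudes vary smoothly across space, which is what gives those
    responses heavy-tailed (generalized Gaussian) statistics.
    """
    sigma = smoothness if smoothness is not None else size / 8.0
    z = gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = z.std()
    if sd > 0:
        z = z / sd
    field = np.exp(strength * z)
    return field / field.mean()


def make_scene(spec: SceneSpec):
    """Render a scene and its boolean target mask.

    The background is a mean-0.5 mixture of oriented gratings (total
    amplitude 0.25) plus white noise; the target region is replaced
    according to the spec.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    field = (_amplitude_field(rng, size, spec.amplitude_mod) if spec.amplitude_mod > 0
             else np.ones((size, size)))
    amp = 0.25 / max(len(spec.bg_orientations), 1)
    texture = np.zeros((size, size))
    for theta in spec.bg_orientations:
        texture = texture + amp * _grating(size, theta, spec.bg_wavelength,
                                           rng.uniform(0, 2 * np.pi))

    x, y, w, h = spec.target_box
    mask = np.zeros((size, size), dtype=bool)
    if spec.target_kind == "oriented-patch":
        # blend toward the target grating: contrast 0 leaves the background
        # texture untouched (invisible target), contrast >= 1 replaces it
        tgt = 0.25 * _grating(size, spec.target_orientation, spec.bg_wavelength,
                              rng.uniform(0, 2 * np.pi))
        blend = min(spec.contrast, 1.0)
        texture[y:y + h, x:x + w] = ((1.0 - blend) * texture[y:y + h, x:x + w]
                                     + spec.contrast * tgt[y:y + h, x:x + w])
        mask[y:y + h, x:x + w] = True
    elif spec.target_kind == "blank":
        texture[y:y + h, x:x + w] = 0.0  # texture-free region; noise stays global
        mask[y:y + h, x:x + w] = True
    image = 0.5 + field * texture + spec.noise * rng.standard_normal((size, size))
    if spec.target_kind == "polygon-shape":
        if spec.target_shape == "disk":
            rr, cc = disk((y + h / 2, x + w / 2), min(w, h) / 2, shape=image.shape)
        elif spec.target_shape == "triangle":
            rows = np.array([y + h - 1, y + h - 1, y])
            cols = np.array([x, x + w - 1, x + w / 2])
            rr, cc = polygon(rows, cols, shape=image.shape)
        else:
            raise ValueError(f"unknown target shape {spec.target_shape!r}")
        image[rr, cc] = np.clip(0.5 + 0.45 * spec.contrast, 0, 1)
        mask[rr, cc] = True
    return np.clip(image, 0.0, 1.0), mask


def _random_box(rng, size, box_side, jitter=None):
    """Target box placement: uniform when jitter is None, else centered with
    +-jitter px of positional scatter (class images share coarse layout, as
    in photographic object datasets)."""
    if jitter is None:
        x = int(rng.integers(0, size - box_side + 1))
        y = int(rng.integers(0, size - box_side + 1))
    else:
        lo, hi = 0, size - box_side
        x = int(np.clip(round((size - box_side) / 2 + rng.uniform(-jitter, jitter)), lo, hi))
        y = int(np.clip(round((size - box_side) / 2 + rng.uniform(-jitter, jitter)), lo, hi))
    return (x, y, box_side, box_side)


# target families used for classification datasets, cycled by class index
_CLASS_FAMILIES = (
    {"target_kind": "oriented-patch", "target_orientation": 0.0},
    {"target_kind": "oriented-patch", "target_orientation": np.pi / 2},
    {"target_kind": "polygon-shape", "target_shape": "disk"},
    {"target_kind": "oriented-patch", "target_orientation": np.pi / 4},
    {"target_kind": "polygon-shape", "target_shape": "triangle"},
    {"target_kind": "blank"},
)


@dataclass
class ClassificationDataset:
    """Labeled synthetic images plus a target-free natural-background pool."""

    targets: dict
    background: list
    boxes: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)

    @property
    def labels(self):
        return list(self.targets)


def scene_for_class(class_index, size=96, box_side=32, contrast=1.0, noise=0.05,
                    jitter_deg=5.0, box_jitter=12.0, amplitude_mod=0.6, seed=0):
    """SceneSpec for one image of one target family over a randomized background."""
    family = _CLASS_FAMILIES[class_index % len(_CLASS_FAMILIES)]
    rng = np.random.default_rng(seed)
    jit = np.deg2rad(jitter_deg)
    bg = tuple(theta + rng.uniform(-jit, jit) for theta in (np.deg2rad(30), np.deg2rad(120)))
    box = _random_box(rng, size, box_side, jitter=box_jitter)
    return SceneSpec(size=size, bg_orientations=bg, noise=noise, target_box=box,
                     contrast=contrast, amplitude_mod=amplitude_mod,
                     seed=int(rng.integers(0, 2**31 - 1)), **family)


def background_scene(size=96, noise=0.05, jitter_deg=5.0, seed=0, orientations=None,
                     amplitude_mod=0.6):
    """A target-free textured scene (the "natural background" pool)."""
    rng = np.random.default_rng(seed)
    jit = np.deg2rad(jitter_deg)
    base = orientations if orientations is not None else (np.deg2rad(30), np.deg2rad(120))
    bg = tuple(theta + rng.uniform(-jit, jit) for theta in base)
    spec = SceneSpec(size=size, bg_orientations=bg, noise=noise, contrast=0.0,
                     target_kind="oriented-patch", target_orientation=bg[0],
                     amplitude_mod=amplitude_mod,
                     target_box=(0, 0, 1, 1), seed=int(rng.integers(0, 2**31 - 1)))
    img, _ = make_scene(spec)
    return img


def make_classification_dataset(n_classes, n_per_class, seed, size=96, box_side=32,
                                contrast=1.0, noise=0.05, n_background=None):
    """Class-balanced labeled scenes plus a background (null-class) pool.

    Each class is a distinct target family (orientation or shape) rendered
    over randomized two-orientation textured backgrounds.  Disjoint seeds
    give disjoint pixel content.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    ss = np.random.SeedSequence(seed)
    targets, boxes, masks = {}, {}, {}
    for k in range(n_classes):
        label = f"class{k}"
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(k,))
        seeds = child.generate_state(n_per_class) % (2**31 - 1)
        imgs, bxs, mks = [], [], []
        for s in seeds:
            spec = scene_for_class(k, size=size, box_side=box_side, contrast=contrast,
                                   noise=noise, seed=int(s))
            img, mask = make_scene(spec)
            imgs.append(img)
            bxs.append(spec.target_box)
            mks.append(mask)
        targets[label] = imgs
        boxes[label] = bxs
        masks[label] = mks
    nbg = n_background if n_background is not None else n_per_class
    bg_child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(n_classes + 1,))
    bg_seeds = bg_child.generate_state(nbg) % (2**31 - 1)
    background = [background_scene(size=size, noise=noise, seed=int(s)) for s in bg_seeds]
    return ClassificationDataset(targets=targets, background=background, boxes=boxes, masks=masks)


def save_dataset(dataset: ClassificationDataset, out_dir):
    """Write a dataset as PNG images plus CSV ground-truth boxes.

    Layout: <out>/<label>/<index>.png, <out>/background/<index>.png and
    <out>/boxes.csv with columns image,x,y,w,h.
    """
    from imageio.v3 import imwrite

    out = Path(out_dir)
    rows = []
    for label, imgs in dataset.targets.items():
        d = out / label
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(imgs):
            name = f"{label}/{i:03d}.png"
            imwrite(out / name, (np.clip(img, 0, 1) * 255).astype(np.uint8))
            if label in dataset.boxes:
                x, y, w, h = dataset.boxes[label][i]
                rows.append((name, x, y, w, h))
    bgd = out / "background"
    bgd.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(dataset.background):
        imwrite(bgd / f"{i:03d}.png", (np.clip(img, 0, 1) * 255).astype(np.uint8))
    with open(out / "boxes.csv", "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["image", "x", "y", "w", "h"])
        writer.writerows(rows)
    return out
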