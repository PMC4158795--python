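"""Filter banks, multiresolution pyramids, and input normalization.

The network front end turns a grayscale image into a retinotopic, multi-scale,
multi-channel stack of bandpass responses: an anti-aliased image pyramid
(subsampling factors 2^(i/4), ten levels by default) convolved with a bank of
oriented filters.  The reference bank is four 11x11 Gabor kernels in the
Mutch-Lowe parameterization; an optional 8x8 DCT bank (63 kernels, DC removed)
augments the channel pool for feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from imageio.v3 import imread
from scipy.ndimage import correlate, uniform_filter
from skimage.transform import resize
from skimage.util import img_as_float

__all__ = [
    "GaborSpec",
    "FilterBank",
    "ImagePyramid",
    "ChannelStack",
    "load_image",
    "build_gabor_bank",
    "build_dct_bank",
    "build_pyramid",
    "convolve_bank",
    "contrast_normalize",
]

EPS = 1e-8  # guard of the contrast-normalization denominator

DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class GaborSpec:
    """Parameters of the oriented Gabor bank (Mutch-Lowe form).

    kernel_size : odd side length in pixels (11)
    orientations : filter orientations in radians, distinct within [0, pi)
    aspect : envelope aspect ratio gamma (0.3)
    width : envelope width sigma in pixels (4.5)
    wavelength : carrier wavelength lambda in pixels (5.6)
    """

    kernel_size: int = 11
    orientations: tuple = DEFAULT_ORIENTATIONS
    aspect: float = 0.3
    width: float = 4.5
    wavelength: float = 5.6

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        wrapped = np.mod(self.orientations, np.pi)
        if len(np.unique(np.round(wrapped, 12))) != len(self.orientations):
            raise ValueError("orientations must be distinct modulo pi")


@dataclass
class FilterBank:
    """A list of same-sized 2-D kernels with human-readable labels."""

    kernels: list
    labels: list

    def __post_init__(self) -> None:
        shapes = {k.shape for k in self.kernels}
        if len(shapes) > 1:
            raise ValueError(f"all kernels must share a size, got {shapes}")
        if len(self.labels) != len(self.kernels):
            raise ValueError("one label per kernel required")

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def kernel_size(self) -> int:
        return self.kernels[0].shape[0]


@dataclass
class ImagePyramid:
    """Anti-aliased multiresolution replicas of one image.

    ``levels[i]`` has dimensions floor(base / factors[i]) with
    factors[i] = factor_base^(i/4) strictly increasing; level 0 is the input.
    """

    levels: list
    factors: list

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class ChannelStack:
    """Multi-channel, multi-scale retinotopic response maps.

    ``maps[s]`` is a (C, H_s, W_s) array for pyramid scale ``s``; all
    channels share per-scale dimensions.  ``grid_meta`` records, per scale,
    the origin and stride of the sample grid in base-image pixel units so
    subsampled layers stay aligned with the input.
    """

    maps: list
    labels: list = field(default_factory=list)
    factors: list = field(default_factory=list)
    grid_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.maps:
            if m.ndim != 3:
                raise ValueError("each per-scale map must be (channels, H, W)")
        channels = {m.shape[0] for m in self.maps}
        if len(channels) > 1:
            raise ValueError("channel count must be constant across scales")
        if not self.grid_meta:
            self.grid_meta = [{"origin": 0.0, "stride": 1.0} for _ in self.maps]

    @property
    def n_channels(self) -> int:
        return self.maps[0].shape[0]

    @property
    def n_scales(self) -> int:
        return len(self.maps)

    def copy_with(self, maps):
        return ChannelStack(maps=maps, labels=list(self.labels), factors=list(self.factors),
                            grid_meta=[dict(g) for g in self.grid_meta])


def load_image(path, max_side=None):
    """Read a raster image as grayscale luminance in [0, 1].

    RGB(A) input is converted with the Rec. 601 luma weights.  If
    ``max_side`` is given and the longer side exceeds it, the image is
    resized (anti-aliased) so the longer side equals ``max_side``.
    """
    arr = img_as_float(imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        arr = arr @ np.array([0.299, 0.587, 0.114])
    if max_side is not None and max(arr.shape) > max_side:
        scale = max_side / max(arr.shape)
        new_shape = (max(1, round(arr.shape[0] * scale)), max(1, round(arr.shape[1] * scale)))
        arr = resize(arr, new_shape, anti_aliasing=True)
    return arr.astype(float)


def _normalize_kernel(k):
    k = k - k.mean()
    n = np.linalg.norm(k)
    if n > 0:
        k = k / n
    return k


def build_gabor_bank(spec: GaborSpec = GaborSpec()) -> FilterBank:
    """One zero-mean, unit-norm Gabor kernel per orientation.

    At rotated coordinates X = x cos(theta) - y sin(theta),
    Y = x sin(theta) + y cos(theta) the kernel is
    exp(-(X^2 + gamma^2 Y^2) / (2 sigma^2)) * cos(2 pi X / lambda).
    """
    half = spec.kernel_size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    kernels, labels = [], []
    for theta in spec.orientations:
        X = x * np.cos(theta) - y * np.sin(theta)
        Y = x * np.sin(theta) + y * np.cos(theta)
        k = np.exp(-(X**2 + (spec.aspect**2) * Y**2) / (2 * spec.width**2)) * np.cos(2 * np.pi * X / spec.wavelength)
        kernels.append(_normalize_kernel(k))
        labels.append(f"gabor_{np.degrees(theta):.0f}")
    return FilterBank(kernels=kernels, labels=labels)


def build_dct_bank(size: int = 8) -> FilterBank:
    """The size^2 - 1 non-DC kernels of the separable 2-D DCT-II basis.

    Orthonormal and zero-mean (the constant basis function is dropped).
    """
    if size < 2:
        raise ValueError(f"DCT bank size must be >= 2, got {size}")
    n = np.arange(size)
    basis = np.cos(np.pi * (2 * n[None, :] + 1) * n[:, None] / (2 * size))
    basis[0] *= np.sqrt(1.0 / size)
    basis[1:] *= np.sqrt(2.0 / size)
    kernels, labels = [], []
    for u in range(size):
        for v in range(size):
            if u == 0 and v == 0:
                continue
            kernels.append(np.outer(basis[u], basis[v]))
            labels.append(f"dct_{u}_{v}")
    return FilterBank(kernels=kernels, labels=labels)


def pyramid_factors(n_scales, factor_base=2.0):
    return [factor_base ** (i / 4.0) for i in range(n_scales)]


def max_feasible_scales(shape, n_scales, kernel_size, factor_base=2.0):
    """Largest level count <= n_scales whose coarsest level still fits the kernel."""
    n = 0
    for f in pyramid_factors(n_scales, factor_base):
        h, w = int(np.floor(shape[0] / f)), int(np.floor(shape[1] / f))
        if min(h, w) < kernel_size:
            break
        n += 1
    return n


def build_pyramid(image, n_scales=10, factor_base=2.0, min_size=1):
    """Anti-aliased image pyramid with subsampling factors factor_base^(i/4).

    Level 0 is the input itself; level i has dimensions
    floor(base / factor_base^(i/4)).  ``min_size`` (typically the filter
    kernel size) makes an undersized coarsest level an error rather than a
    silent truncation.
    """
    image = np.asarray(image, dtype=float)
    factors = pyramid_factors(n_scales, factor_base)
    levels = []
    for i, f in enumerate(factors):
        shape = (int(np.floor(image.shape[0] / f)), int(np.floor(image.shape[1] / f)))
        if min(shape) < min_size:
            raise ValueError(
                f"image {image.shape} too small: pyramid level {i} would be {shape}, "
                f"below the minimum size {min_size}")
        if i == 0:
            levels.append(image)
        else:
            levels.append(resize(image, shape, anti_aliasing=True))
    return ImagePyramid(levels=levels, factors=factors)


def convolve_bank(pyramid: ImagePyramid, bank: FilterBank) -> ChannelStack:
    """Correlate every pyramid level with every kernel ("same" size, zero padding)."""
    ksize = bank.kernel_size
    maps = []
    for i, level in enumerate(pyramid.levels):
        if min(level.shape) < ksize:
            raise ValueError(f"pyramid level {i} {level.shape} smaller than kernel {ksize}")
        maps.append(np.stack([correlate(level, k, mode="constant", cval=0.0) for k in bank.kernels]))
    return ChannelStack(maps=maps, labels=list(bank.labels), factors=list(pyramid.factors))


def contrast_normalize(stack: ChannelStack, window: int, saturation: float = 0.0) -> ChannelStack:
    """Divisive contrast normalization of a stack by local cross-channel energy.

    Each value is divided by the sum, over a ``window`` x ``window``
    neighborhood of its location and over all channels, of the input
    magnitudes, plus a semisaturation term.  ``saturation`` is the
    semisaturation level expressed per location (it is scaled by the window
    area internally): inputs whose local energy is far below it are
    suppressed rather than renormalized to full range, as in the standard
    divisive-normalization model of cortical gain control.  With
    ``saturation=0`` the operation is a pure ratio (epsilon-guarded) and is
    invariant to global input rescaling.

    The window (normally the layer's template size) is clipped to the map
    dimensions at scales too coarse to fit it; border windows use the
    in-bounds mean scaled to the full window count, so they are not
    artificially under-normalized.
    """
    if window < 1:
        raise ValueError(f"window must be a positive integer, got {window}")
    if saturation < 0:
        raise ValueError("saturation must be >= 0")
    out = []
    for m in stack.maps:
        w = min(window, min(m.shape[1:]))
        ones = np.ones(m.shape[1:])
        counts = uniform_filter(ones, size=w, mode="constant", cval=0.0) * (w * w)
        sums = uniform_filter(np.abs(m).sum(axis=0), size=w, mode="constant", cval=0.0) * (w * w)
        denom = sums / counts * (w * w) + saturation * (w * w) + EPS
        out.append(m / denom[None, :, :])
    return stack.copy_with(out)
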