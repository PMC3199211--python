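"""Image preprocessing and filter-bank feature extraction.

Dermoscopic images are converted to CIE L*a*b* (D65 white point), the
lightness channel is optionally zero-meaned to compensate for uncalibrated
camera exposure, and each of the three channels is filtered with a bank of
Gaussian and Laplacian-of-Gaussian filters at several scales.  With the
default five scales this yields the 30-channel per-pixel observation
vectors the labeling models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

__all__ = [
    "RasterImage",
    "ScaleSet",
    "FeatureStack",
    "DEFAULT_SCALES",
    "rgb_to_lab",
    "normalize_lstar",
    "filter_bank",
]

#: Filter scales (pixels) of the default bank.
DEFAULT_SCALES = (1.25, 2.5, 5.0, 10.0, 20.0)

#: Kernel support is truncated at this many standard deviations.
KERNEL_TRUNCATE = 4.0

_CHANNEL_NAMES = ("L*", "a*", "b*")


@dataclass(frozen=True)
class RasterImage:
    """A height x width x 3 raster in either sRGB ([0,1]) or CIE L*a*b*."""

    pixels: np.ndarray
    color_space: str  # "sRGB" or "CIELab"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if self.color_space not in ("sRGB", "CIELab"):
            raise ValueError(f"unknown color space {self.color_space!r}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleSet:
    """Strictly increasing, positive filter scales sigma."""

    scales: tuple = DEFAULT_SCALES

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.scales)
        if len(s) == 0:
            raise ValueError("ScaleSet must be nonempty")
        if any(v <= 0 for v in s):
            raise ValueError("all scales must be > 0")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)

    def __len__(self) -> int:
        return len(self.scales)


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel observations: N_P x N_C filter responses.

    Row ``i`` corresponds to pixel ``i`` in row-major (C) order; the same
    convention is used for label fields and masks throughout the package.
    """

    values: np.ndarray
    height: int
    width: int
    channel_names: tuple = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (N_P x N_C)")
        if v.shape[0] != self.height * self.width:
            raise ValueError("row count must equal height*width")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_image(self, c: int) -> np.ndarray:
        """Return channel ``c`` reshaped to the image grid."""
        return self.values[:, c].reshape(self.height, self.width)


def rgb_to_lab(img: RasterImage) -> RasterImage:
    """Convert an sRGB image (values in [0,1]) to CIE L*a*b* under D65.

    Raises
    ------
    ValueError
        If the image is not sRGB or has values outside [0, 1].
    """
    if img.color_space != "sRGB":
        raise ValueError("rgb_to_lab expects an sRGB image")
    px = img.pixels
    if px.min() < 0.0 or px.max() > 1.0:
        raise ValueError("sRGB values must lie in [0, 1]")
    lab = _skcolor.rgb2lab(px)
    return RasterImage(lab, "CIELab")


def normalize_lstar(img: RasterImage) -> RasterImage:
    """Zero-mean the L* channel; a* and b* are untouched.

    Subtracting the mean lightness compensates for global exposure
    differences between images acquired with uncalibrated cameras: two
    images differing only by a constant L* offset normalize identically.
    The operation is idempotent.
    """
    if img.color_space != "CIELab":
        raise ValueError("normalize_lstar expects a CIELab image")
    px = img.pixels.copy()
    px[:, :, 0] -= px[:, :, 0].mean()
    return RasterImage(px, "CIELab")


def filter_bank(
    img: RasterImage,
    scales: ScaleSet | None = None,
    *,
    log_scale_normalized: bool = False,
    padding_mode: str = "reflect",
) -> FeatureStack:
    """Gaussian + Laplacian-of-Gaussian filter bank over all 3 channels.

    For each color channel and each scale sigma the stack contains one
    Gaussian-smoothed response and one LoG response, giving
    ``N_C = 2 * len(scales) * 3`` channels (30 for the default scales).

    Channel order (documented, stable): for each source channel in
    (L*, a*, b*), for each scale in increasing order, first the Gaussian
    response then the LoG response.  Names follow
    ``"{channel}/{gauss|log}/s{sigma}"``.

    Parameters
    ----------
    log_scale_normalized:
        If True, LoG responses are multiplied by sigma**2 (scale-normalized
        derivatives).  Off by default: the plain Laplacian of Gaussian.

    The truncated sampled LoG kernel has a small nonzero DC gain; it is
    subtracted from the kernel so that constant images produce exactly
    zero LoG response.
    padding_mode:
        Boundary handling passed to the filters; reflective padding by
        default to avoid border artifacts.
    """
    if img.color_space != "CIELab":
        raise ValueError("filter_bank expects a CIELab image")
    scales = scales if scales is not None else ScaleSet()
    h, w = img.height, img.width
    # DC gain of the truncated sampled LoG kernel; subtracted so that the
    # effective kernel annihilates constant images exactly
    dc = {
        sigma: float(
            ndimage.gaussian_laplace(
                np.ones((1, 1)), sigma, mode=padding_mode, truncate=KERNEL_TRUNCATE
            )[0, 0]
        )
        for sigma in scales.scales
    }
    responses = []
    names = []
    for c, cname in enumerate(_CHANNEL_NAMES):
        chan = img.pixels[:, :, c]
        for sigma in scales.scales:
            g = ndimage.gaussian_filter(
                chan, sigma, mode=padding_mode, truncate=KERNEL_TRUNCATE
            )
            lg = (
                ndimage.gaussian_laplace(
                    chan, sigma, mode=padding_mode, truncate=KERNEL_TRUNCATE
                )
                - dc[sigma] * chan
            )
            if log_scale_normalized:
                lg = sigma**2 * lg
            responses.append(g.ravel())
            names.append(f"{cname}/gauss/s{sigma:g}")
            responses.append(lg.ravel())
            names.append(f"{cname}/log/s{sigma:g}")
    values = np.column_stack(responses)
    return FeatureStack(values, h, w, tuple(names))
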