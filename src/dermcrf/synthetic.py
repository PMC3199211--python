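"""Synthetic dermoscopy-like scenes with exact ground truth.

Each scene is a darker, roughly elliptical lesion on lighter skin with
per-channel Gaussian sensor noise, an optional global lightness (L*)
offset emulating uncalibrated camera exposure, an optional softened lesion
boundary, and optional thin dark hair-like streaks drawn over the scene.
The ground-truth mask is the analytic ellipse membership and is never
altered by noise, exposure or hair — it reflects lesion geometry only.
All randomness is driven by a mandatory seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor
from skimage.draw import line_aa

from .features import RasterImage
from .pp import LabelField

__all__ = ["LesionSceneSpec", "DatasetRanges", "generate_scene", "generate_dataset"]

#: Typical light skin tone under dermoscopy illumination (sRGB).
DEFAULT_SKIN = (0.80, 0.60, 0.52)
#: Typical dark-brown pigmented lesion (sRGB).
DEFAULT_LESION = (0.36, 0.22, 0.18)


@dataclass(frozen=True)
class LesionSceneSpec:
    """Parameters of one synthetic scene.

    ``axes`` are the ellipse semi-axes in pixels, ``rotation`` in radians.
    ``noise_sd`` is the per-channel additive Gaussian sd in sRGB units,
    ``lstar_offset`` a global lightness shift (CIELAB L* units) applied
    after composition, ``edge_sigma`` the Gaussian softness of the color
    transition at the lesion boundary (pixels; 0 = hard edge).  Hair
    streaks are ``n_hairs`` dark anti-aliased polylines of width
    ``hair_width`` whose darkness scales the underlying color by
    ``1 - hair_darkness``.
    """

    height: int = 64
    width: int = 64
    center: tuple = (32.0, 32.0)  # (row, col)
    axes: tuple = (18.0, 12.0)  # semi-axes
    rotation: float = 0.5
    skin_rgb: tuple = DEFAULT_SKIN
    lesion_rgb: tuple = DEFAULT_LESION
    noise_sd: float = 0.02
    lstar_offset: float = 0.0
    edge_sigma: float = 1.0
    n_hairs: int = 0
    hair_width: int = 1
    hair_darkness: float = 0.7
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (1 <= self.hair_width <= 3):
            raise ValueError("hair width must be 1-3 px")


def _ellipse_mask(spec: LesionSceneSpec) -> np.ndarray:
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    dr = rows - spec.center[0]
    dc = cols - spec.center[1]
    c, s = np.cos(spec.rotation), np.sin(spec.rotation)
    u = c * dr + s * dc
    v = -s * dr + c * dc
    return (u / spec.axes[0]) ** 2 + (v / spec.axes[1]) ** 2 <= 1.0


def _draw_hairs(img: np.ndarray, spec: LesionSceneSpec, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    for _ in range(spec.n_hairs):
        # random chord: endpoints on opposite-ish borders
        r0, c0 = int(rng.integers(0, h)), int(rng.integers(0, w))
        r1, c1 = int(rng.integers(0, h)), int(rng.integers(0, w))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        for off in range(spec.hair_width):
            ro = np.clip(rr + off, 0, h - 1)
            atten = 1.0 - spec.hair_darkness * val
            img[ro, cc, :] *= atten[:, None]


def generate_scene(spec: LesionSceneSpec) -> tuple[RasterImage, LabelField]:
    """Render one scene and its exact ground-truth mask.

    Composition order: ellipse recoloring (optionally blended through a
    Gaussian-softened boundary), additive channel noise, hair streaks,
    then the global L* exposure offset applied in CIELAB and converted
    back to sRGB.  The returned mask uses label 1 for lesion pixels.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipse_mask(spec)
    alpha = mask.astype(np.float64)
    if spec.edge_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, spec.edge_sigma, mode="nearest")
    skin = np.asarray(spec.skin_rgb, dtype=np.float64)
    lesion = np.asarray(spec.lesion_rgb, dtype=np.float64)
    img = skin[None, None, :] + alpha[:, :, None] * (lesion - skin)[None, None, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    if spec.n_hairs > 0:
        _draw_hairs(img, spec, rng)
    img = np.clip(img, 0.0, 1.0)
    if spec.lstar_offset != 0.0:
        lab = _skcolor.rgb2lab(img)
        lab[:, :, 0] = np.clip(lab[:, :, 0] + spec.lstar_offset, 0.0, 100.0)
        img = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    image = RasterImage(img, "sRGB")
    truth = LabelField(mask.ravel().astype(np.int64), spec.height, spec.width)
    return image, truth


@dataclass(frozen=True)
class DatasetRanges:
    """Uniform sampling ranges for per-image scene parameters.

    ``axes_frac`` bounds the ellipse semi-axes as a fraction of the image
    side; per-image exposure offsets are drawn independently from
    ``lstar_offset`` to emulate uncalibrated acquisition.
    """

    height: int = 64
    width: int = 64
    axes_frac: tuple = (0.15, 0.35)
    center_jitter_frac: float = 0.1
    skin_rgb: tuple = DEFAULT_SKIN
    lesion_rgb: tuple = DEFAULT_LESION
    color_jitter: float = 0.03
    noise_sd: tuple = (0.01, 0.03)
    lstar_offset: tuple = (-10.0, 10.0)
    edge_sigma: tuple = (0.5, 1.5)
    n_hairs: tuple = (0, 3)
    hair_width: int = 1
    hair_darkness: float = 0.7

    def __post_init__(self) -> None:
        for name in ("axes_frac", "noise_sd", "lstar_offset", "edge_sigma"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}")


def generate_dataset(
    n_images: int,
    ranges: DatasetRanges | None = None,
    seed: int = 0,
) -> list[tuple[RasterImage, LabelField]]:
    """Draw ``n_images`` independent scenes with seed-derived streams.

    Per-image parameters (ellipse geometry, color jitter, noise level,
    exposure offset, hair count) are sampled uniformly from ``ranges``;
    each scene then renders deterministically from its own derived seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ranges = ranges or DatasetRanges()
    rng = np.random.default_rng(seed)
    h, w = ranges.height, ranges.width
    side = min(h, w)
    out = []
    for k in range(n_images):
        axes = rng.uniform(*ranges.axes_frac, size=2) * side
        jit = ranges.center_jitter_frac
        center = (
            h / 2 + rng.uniform(-jit, jit) * h,
            w / 2 + rng.uniform(-jit, jit) * w,
        )
        skin = np.clip(
            np.asarray(ranges.skin_rgb)
            + rng.uniform(-ranges.color_jitter, ranges.color_jitter, 3),
            0.0,
            1.0,
        )
        lesion = np.clip(
            np.asarray(ranges.lesion_rgb)
            + rng.uniform(-ranges.color_jitter, ranges.color_jitter, 3),
            0.0,
            1.0,
        )
        spec = LesionSceneSpec(
            height=h,
            width=w,
            center=tuple(center),
            axes=tuple(np.sort(axes)[::-1]),
            rotation=float(rng.uniform(0, np.pi)),
            skin_rgb=tuple(skin),
            lesion_rgb=tuple(lesion),
            noise_sd=float(rng.uniform(*ranges.noise_sd)),
            lstar_offset=float(rng.uniform(*ranges.lstar_offset)),
            edge_sigma=float(rng.uniform(*ranges.edge_sigma)),
            n_hairs=int(rng.integers(ranges.n_hairs[0], ranges.n_hairs[1] + 1)),
            hair_width=ranges.hair_width,
            hair_darkness=ranges.hair_darkness,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_scene(spec))
    return out
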