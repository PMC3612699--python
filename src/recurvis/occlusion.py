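"""Blob-based partial occlusion.

Images are occluded by repeatedly applying a circular "blob" weighting
filter: weight 1.0 inside a plateau of radius ``r`` (5% of the image size by
default), falling off outside the plateau as a Gaussian with sigma also 5%
of the image size.  The filter interpolates each pixel toward the uniform
background gray, so plateau pixels are *exactly* background and the skirt is
a smooth gradient — no novel edge features are introduced, which matters for
a model with no border-ownership machinery.

The occlusion fraction ``O`` in [0, 1] maps to an integer application count

    N = floor(2.5 * O * (image_size / filter_width + 1) + 0.5)

(round-half-up of the underlying continuous quantity; ``O = 0`` gives no
applications).  Placements are uniform over the image square, partially
off-image blobs allowed, each application at a fresh random position.
Overlapping placements combine by per-pixel maximum of weights, preserving
the fully-occluded plateau semantics.

At 144 px with 5% fractions: r = 7 px, sigma = 7 px, support 42 x 42 px,
N = 6 at O = 0.5 and N = 11 at O = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .images import BACKGROUND_GRAY


@dataclass(frozen=True)
class BlobFilter:
    weights: np.ndarray          # (width, width) in [0, 1]
    radius: int                  # plateau radius, px
    sigma: int                   # Gaussian sigma, px
    background: float = BACKGROUND_GRAY

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_gradient(self) -> float:
        """Largest weight step the filter can introduce between neighbouring
        pixels on a uniform image: the maximum of the interior radial
        gradient and the residual weight at the square support's edge
        (the finite support truncates the Gaussian tail at ~exp(-2))."""
        w = self.weights
        interior = max(np.abs(np.diff(w, axis=0)).max(),
                       np.abs(np.diff(w, axis=1)).max())
        border = max(w[0].max(), w[-1].max(), w[:, 0].max(), w[:, -1].max())
        return float(max(interior, border))


@dataclass(frozen=True)
class OcclusionSpec:
    level: float = 0.0           # occlusion fraction O in [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise InvalidInputError(f"occlusion level must be in [0, 1], got {self.level}")


def build_blob_filter(image_size: int, radius_frac: float = 0.05,
                      sigma_frac: float = 0.05,
                      background: float = BACKGROUND_GRAY) -> BlobFilter:
    """Construct the occluder for a given image size.

    ``r = floor(radius_frac * image_size)``, likewise sigma; the square
    support extends ``r + 2*sigma`` from the centre on each side (width
    ``2*(r + 2*sigma)``).
    """
    for name, frac in (("radius_frac", radius_frac), ("sigma_frac", sigma_frac)):
        if not 0.0 < frac < 0.5:
            raise ConfigurationError(f"{name} must be in (0, 0.5), got {frac}")
    r = int(np.floor(radius_frac * image_size))
    sigma = int(np.floor(sigma_frac * image_size))
    if r < 1 or sigma < 1:
        raise ConfigurationError(
            f"image_size {image_size} too small for fractions {radius_frac}/{sigma_frac}")
    half = r + 2 * sigma
    width = 2 * half
    if width > image_size:
        raise ConfigurationError(
            f"filter support {width} exceeds image size {image_size}")
    c = (width - 1) / 2.0
    yy, xx = np.mgrid[0:width, 0:width]
    d = np.hypot(yy - c, xx - c)
    w = np.where(d <= r, 1.0, np.exp(-((d - r) ** 2) / (2.0 * sigma ** 2)))
    return BlobFilter(weights=w, radius=r, sigma=sigma, background=background)


def n_applications(level: float, image_size: int, filter_width: int) -> int:
    """Number of blob applications for occlusion fraction ``level``."""
    if not 0.0 <= level <= 1.0:
        raise InvalidInputError(f"occlusion level must be in [0, 1], got {level}")
    return int(np.floor(2.5 * level * (image_size / filter_width + 1.0) + 0.5))


def occlusion_mask(image_size: int, filt: BlobFilter, spec: OcclusionSpec) -> np.ndarray:
    """Accumulated per-pixel occlusion weight (max over placements)."""
    n = n_applications(spec.level, image_size, filt.width)
    mask = np.zeros((image_size, image_size))
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    half = filt.width // 2
    for _ in range(n):
        cy = int(rng.integers(0, image_size))
        cx = int(rng.integers(0, image_size))
        y0, x0 = cy - half, cx - half
        ys0, xs0 = max(0, -y0), max(0, -x0)
        yd0, xd0 = max(0, y0), max(0, x0)
        h = min(filt.width - ys0, image_size - yd0)
        w = min(filt.width - xs0, image_size - xd0)
        if h <= 0 or w <= 0:
            continue
        region = mask[yd0:yd0 + h, xd0:xd0 + w]
        np.maximum(region, filt.weights[ys0:ys0 + h, xs0:xs0 + w], out=region)
    return mask


def occlude(img: np.ndarray, filt: BlobFilter, spec: OcclusionSpec,
            return_mask: bool = False):
    """Occlude an image: ``out = w * background + (1 - w) * img`` with the
    accumulated weight mask.  ``O = 0`` returns the input unchanged."""
    img = np.asarray(img, dtype=float)
    mask = occlusion_mask(img.shape[0], filt, spec)
    out = mask * filt.background + (1.0 - mask) * img
    # plateau pixels are background bit-exactly
    out[mask >= 1.0] = filt.background
    if return_mask:
        return out, mask
    return out
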