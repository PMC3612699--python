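"""Image normalisation, affine augmentation and dataset-manifest handling.

The working representation of a visual input throughout the package is a
square 2-D float array of gray values in [0, 1] ("image grid"), produced by
:func:`normalize_image`.  Training and testing presentations perturb that
grid with a single composed affine transform (scale, in-plane rotation,
translation) whose parameters are drawn uniformly from configured ranges —
the stand-in for an observer's fixation-to-fixation variability.

Conventions
-----------
* Rotation is expressed as a fraction of a full turn (1.0 == 360 degrees),
  positive counter-clockwise.
* Translation is a fraction of the image size; ``ty = 1.0`` would move the
  image centre to the top edge.
* Out-of-frame regions are filled with the background gray (0.5), the same
  gray used by the blob occluder, so transform and occlusion artifacts are
  mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.transform import AffineTransform, resize, warp

from .errors import ConfigurationError, InvalidInputError

#: Background gray level used for out-of-frame fill and by the occluder.
BACKGROUND_GRAY = 0.5

#: Default working size (pixels) after normalisation.
DEFAULT_IMAGE_SIZE = 144

MANIFEST_COLUMNS = ["category", "exemplar", "render", "path", "seed"]


@dataclass(frozen=True)
class AffineParams:
    """A single draw of augmentation parameters.

    ``scale`` is a unitless factor, ``tx``/``ty`` fractions of the image
    size, ``rot`` a fraction of a full turn.
    """

    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    rot: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.scale == 1.0 and self.tx == 0.0 and self.ty == 0.0 and self.rot == 0.0

    @property
    def rot_degrees(self) -> float:
        return self.rot * 360.0


@dataclass(frozen=True)
class AffineRanges:
    """Uniform sampling ranges for :func:`sample_affine`.

    Defaults follow the training protocol: scale 0.9-1.1, translation
    -0.15..0.15 on both axes, rotation -0.02..0.02 of a full turn
    (i.e. +/- 7.2 degrees).
    """

    scale: tuple[float, float] = (0.9, 1.1)
    translate: tuple[float, float] = (-0.15, 0.15)
    rotate: tuple[float, float] = (-0.02, 0.02)

    def __post_init__(self) -> None:
        for name in ("scale", "translate", "rotate"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"inverted {name} range: ({lo}, {hi})")

    @classmethod
    def identity(cls) -> "AffineRanges":
        return cls(scale=(1.0, 1.0), translate=(0.0, 0.0), rotate=(0.0, 0.0))


def normalize_image(raw: np.ndarray, target_size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Convert a raster to a square grayscale grid with values in [0, 1].

    RGB(A) input is converted to luminance first.  Integer input is assumed
    8-bit and divided by 255.  Downscaling applies neighbourhood smoothing:
    exact block averaging when the source side is an integer multiple of
    ``target_size`` (so a 2x downscale is a plain 2x2 box filter), otherwise
    anti-aliased bilinear resampling.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    if target_size < 8:
        raise InvalidInputError(f"target_size must be >= 8, got {target_size}")

    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = rgb2gray(arr.astype(float) / (255.0 if arr.dtype.kind in "ui" else 1.0))
    elif arr.ndim == 2:
        arr = arr.astype(float)
        if raw.dtype.kind in "ui":
            arr = arr / 255.0
    else:
        raise InvalidInputError(f"expected 2-D or 3-D raster, got ndim={arr.ndim}")

    h, w = arr.shape
    if h == w == target_size:
        out = arr
    elif h == w and h % target_size == 0:
        f = h // target_size
        out = arr.reshape(target_size, f, target_size, f).mean(axis=(1, 3))
    else:
        out = resize(arr, (target_size, target_size), order=1, mode="reflect",
                     anti_aliasing=(h > target_size or w > target_size))
    return np.clip(out, 0.0, 1.0)


def sample_affine(rng: np.random.Generator, ranges: AffineRanges | None = None) -> AffineParams:
    """Draw independent uniform augmentation parameters from ``ranges``."""
    r = ranges if ranges is not None else AffineRanges()
    return AffineParams(
        scale=float(rng.uniform(*r.scale)),
        tx=float(rng.uniform(*r.translate)),
        ty=float(rng.uniform(*r.translate)),
        rot=float(rng.uniform(*r.rotate)),
    )


def apply_affine(img: np.ndarray, p: AffineParams,
                 background: float = BACKGROUND_GRAY) -> np.ndarray:
    """Apply one composed affine map (scale, then rotate, then translate,
    about the image centre) with bilinear interpolation.

    A single resampling pass is used so interpolation smoothing is not
    compounded.  Identity parameters return a bit-exact copy.
    """
    img = np.asarray(img, dtype=float)
    if p.is_identity:
        return img.copy()
    h, w = img.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = p.rot * 2.0 * np.pi
    # ty > 0 moves content up, i.e. toward smaller row indices.
    to_centre = AffineTransform(translation=(-cx, -cy))
    core = AffineTransform(scale=(p.scale, p.scale), rotation=theta)
    back = AffineTransform(translation=(cx + p.tx * w, cy - p.ty * h))
    tform = to_centre + core + back
    return warp(img, inverse_map=tform.inverse, order=1, mode="constant",
                cval=background, preserve_range=True)


# ---------------------------------------------------------------------------
# manifests and PNG i/o


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file and normalise dtype to float in [0, 1] (no resize)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = (rgb2gray(arr[:, :, :3].astype(float) / 255.0) * 255.0).astype(np.uint8)
    return arr.astype(float) / 255.0


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] gray grid as 8-bit grayscale PNG."""
    iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255.0).astype(np.uint8))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns: {sorted(missing)}")
    return df


def split_train_test(manifest: pd.DataFrame, n_test_exemplars_per_category: int = 2,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a manifest by exemplar: all renders of a held-out exemplar go to
    the test set.  Deterministic given ``seed``.

    Raises :class:`ConfigurationError` naming the first category with too few
    exemplars.
    """
    n_test = int(n_test_exemplars_per_category)
    if n_test < 0:
        raise ConfigurationError("n_test_exemplars_per_category must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    test_rows = []
    for cat, grp in manifest.groupby("category", sort=True):
        exemplars = np.sort(grp["exemplar"].unique())
        if n_test > 0 and len(exemplars) <= n_test:
            raise ConfigurationError(
                f"category {cat!r} has only {len(exemplars)} exemplars; "
                f"cannot reserve {n_test} for testing")
        held = rng.choice(exemplars, size=n_test, replace=False)
        test_rows.append(grp[grp["exemplar"].isin(held)])
    if test_rows and sum(len(t) for t in test_rows) > 0:
        test = pd.concat(test_rows)
    else:
        test = manifest.iloc[0:0]
    train = manifest.drop(index=test.index)
    return train.reset_index(drop=True), test.reset_index(drop=True)
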