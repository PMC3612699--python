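"""Synthetic-shape dataset generator.

Emulates the structure of a rendered 3-D object dataset — categories, each
with several exemplars, each rendered many times under pose and lighting
variability — without any 3-D assets.  Every category is defined by a small
"shape grammar": a composite of 2-4 parametric primitives (ellipse, ring,
rectangle, bar, cross) with fixed geometry.  Exemplars jitter that geometry;
renders additionally jitter pose (small in-plane rotation and anisotropic
scaling, a statistical surrogate for +/-20-degree in-depth rotations) and
apply a linear brightness gradient whose direction is drawn from an
80-degree overhead arc (the lighting surrogate).  Exemplar jitter is larger
than render jitter, so exemplar identity carries more pixel variance than
render identity.

Everything is a pure function of the dataset seed and the (category,
exemplar, render) indices, so regeneration is byte-identical.  Images are
quantised to 8-bit gray levels at the end, which makes the in-memory arrays
equal to a PNG round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .images import BACKGROUND_GRAY, MANIFEST_COLUMNS

_PRIMITIVE_KINDS = ("ellipse", "ring", "rect", "bar", "cross")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the synthetic dataset.

    ``exemplars_per_category`` may be a single count or one count per
    category (the latter matches datasets with uneven exemplar coverage).
    ``cluster_of`` optionally assigns each category to a visual cluster;
    categories sharing a cluster are look-alikes built from a common
    prototype, which is what gives a semantics experiment its visually
    confusable neighbours.
    """

    n_categories: int = 10
    exemplars_per_category: int | Sequence[int] = 4
    renders_per_exemplar: int = 5
    image_size: int = 144
    exemplar_jitter: float = 0.12
    render_jitter: float = 1.0
    cluster_of: tuple[int, ...] | None = None
    supersample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.renders_per_exemplar < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.exemplar_jitter < 0 or self.render_jitter < 0:
            raise ConfigurationError("jitter magnitudes must be >= 0")
        if self.cluster_of is not None and len(self.cluster_of) != self.n_categories:
            raise ConfigurationError("cluster_of must assign every category")

    def exemplar_counts(self) -> np.ndarray:
        if np.isscalar(self.exemplars_per_category):
            counts = np.full(self.n_categories, int(self.exemplars_per_category))
        else:
            counts = np.asarray(self.exemplars_per_category, dtype=int)
            if len(counts) != self.n_categories:
                raise ConfigurationError("one exemplar count per category required")
        if np.any(counts < 1):
            raise ConfigurationError("counts must be >= 1")
        return counts

    def category_label(self, c: int) -> str:
        return f"cat{c:03d}"


def _rng(*key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(list(key)))


def _sample_primitives(rng: np.random.Generator) -> list[dict]:
    n = int(rng.integers(2, 5))
    prims = []
    for _ in range(n):
        kind = _PRIMITIVE_KINDS[rng.integers(len(_PRIMITIVE_KINDS))]
        prims.append({
            "kind": kind,
            "cx": rng.uniform(0.3, 0.7),
            "cy": rng.uniform(0.3, 0.7),
            "a": rng.uniform(0.08, 0.28),
            "b": rng.uniform(0.05, 0.22),
            "angle": rng.uniform(0, np.pi),
            "intensity": rng.uniform(0.02, 0.38),
        })
    return prims


def _jitter_primitives(prims: list[dict], rng: np.random.Generator, mag: float) -> list[dict]:
    out = []
    for p in prims:
        q = dict(p)
        q["cx"] = float(np.clip(p["cx"] + rng.uniform(-mag, mag) * 0.4, 0.1, 0.9))
        q["cy"] = float(np.clip(p["cy"] + rng.uniform(-mag, mag) * 0.4, 0.1, 0.9))
        q["a"] = float(np.clip(p["a"] * (1 + rng.uniform(-mag, mag)), 0.02, 0.4))
        q["b"] = float(np.clip(p["b"] * (1 + rng.uniform(-mag, mag)), 0.02, 0.4))
        q["angle"] = p["angle"] + rng.uniform(-mag, mag) * 1.2
        q["intensity"] = float(np.clip(p["intensity"] + rng.uniform(-mag, mag) * 0.25, 0.0, 0.45))
        out.append(q)
    return out


def category_primitives(spec: SyntheticDatasetSpec, category: int) -> list[dict]:
    """Base geometry for a category (cluster prototype + category tweak if
    clustered, otherwise sampled directly from the category stream)."""
    if spec.cluster_of is None:
        return _sample_primitives(_rng(spec.seed, 7, category))
    proto = _sample_primitives(_rng(spec.seed, 5, int(spec.cluster_of[category])))
    # within-cluster siblings differ more than exemplars but keep the layout
    return _jitter_primitives(proto, _rng(spec.seed, 7, category), 1.8 * spec.exemplar_jitter)


def _inside(kind: str, xr: np.ndarray, yr: np.ndarray, a: float, b: float) -> np.ndarray:
    if kind == "ellipse":
        return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if kind == "ring":
        r2 = (xr / a) ** 2 + (yr / b) ** 2
        return (r2 <= 1.0) & (r2 >= 0.45)
    if kind == "rect":
        return (np.abs(xr) <= a) & (np.abs(yr) <= b)
    if kind == "bar":
        return (np.abs(xr) <= a) & (np.abs(yr) <= 0.35 * b)
    if kind == "cross":
        return ((np.abs(xr) <= a) & (np.abs(yr) <= 0.3 * b)) | \
               ((np.abs(xr) <= 0.3 * a) & (np.abs(yr) <= b))
    raise ConfigurationError(f"unknown primitive kind {kind!r}")


def render_image(spec: SyntheticDatasetSpec, category: int, exemplar: int,
                 render: int) -> np.ndarray:
    """Render one (category, exemplar, render) image deterministically."""
    prims = _jitter_primitives(category_primitives(spec, category),
                               _rng(spec.seed, 11, category, exemplar),
                               spec.exemplar_jitter)
    rrng = _rng(spec.seed, 13, category, exemplar, render)
    rj = spec.render_jitter
    pose_rot = rrng.uniform(-np.pi / 22.5, np.pi / 22.5) * rj        # +/- 8 deg
    pose_sx = 1.0 + rrng.uniform(-0.08, 0.08) * rj                   # foreshortening
    pose_sy = 1.0 + rrng.uniform(-0.08, 0.08) * rj
    light_angle = rrng.uniform(-np.pi * 40 / 180, np.pi * 40 / 180)  # overhead arc
    light_strength = rrng.uniform(0.0, 0.25) * rj

    s = spec.image_size * spec.supersample
    coord = (np.arange(s) + 0.5) / s
    x, y = np.meshgrid(coord, coord)
    # pose applied as an inverse coordinate map about the image centre
    xc, yc = x - 0.5, y - 0.5
    cr, sr = np.cos(pose_rot), np.sin(pose_rot)
    xp = (cr * xc + sr * yc) / pose_sx + 0.5
    yp = (-sr * xc + cr * yc) / pose_sy + 0.5

    img = np.full((s, s), BACKGROUND_GRAY)
    dx, dy = np.sin(light_angle), -np.cos(light_angle)
    gradient = 1.0 + light_strength * 2.0 * ((x - 0.5) * dx + (y - 0.5) * dy)
    for p in prims:
        xo, yo = xp - p["cx"], yp - p["cy"]
        ca, sa = np.cos(p["angle"]), np.sin(p["angle"])
        xr = ca * xo + sa * yo
        yr = -sa * xo + ca * yo
        mask = _inside(p["kind"], xr, yr, p["a"], p["b"])
        img[mask] = np.clip(p["intensity"] * gradient[mask], 0.0, 1.0)

    f = spec.supersample
    img = img.reshape(spec.image_size, f, spec.image_size, f).mean(axis=(1, 3))
    return np.round(img * 255.0) / 255.0


def make_manifest(spec: SyntheticDatasetSpec) -> pd.DataFrame:
    counts = spec.exemplar_counts()
    rows = []
    for c in range(spec.n_categories):
        for e in range(counts[c]):
            for r in range(spec.renders_per_exemplar):
                rows.append((spec.category_label(c), e, r, "", spec.seed))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def make_synthetic_dataset(spec: SyntheticDatasetSpec, render_images: bool = True,
                           ) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Build the manifest and (optionally) render every image.

    With ``render_images=False`` only the manifest is produced; images can be
    regenerated row by row with :func:`render_image` (`manifest` row order
    matches the returned image array).
    """
    manifest = make_manifest(spec)
    if not render_images:
        return manifest, None
    label_to_idx = {spec.category_label(c): c for c in range(spec.n_categories)}
    images = np.empty((len(manifest), spec.image_size, spec.image_size))
    for i, row in enumerate(manifest.itertuples(index=False)):
        images[i] = render_image(spec, label_to_idx[row.category], row.exemplar, row.render)
    return manifest, images
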