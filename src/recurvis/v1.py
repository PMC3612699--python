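"""Fixed oriented-filter front-end standing in for retina -> LGN -> V1.

Simple cells are modelled as Gabor quadrature pairs (even/odd phase) at a
small number of orientations and spatial scales; all filters are zero-mean
and unit L2 norm, so a uniform field produces no response.  Complex cells
pool the rectified simple-cell responses over phase (max of |even|, |odd|)
and over a small spatial neighbourhood (non-overlapping max-pool).  A
k-winners-take-all cut applied per scale across the whole pooled layer keeps
at most a configured fraction of units active, mirroring the sparse activity
levels imposed by inhibitory competition downstream.

The exact filter geometry of the biological counterpart is not reproduced
here; the defaults (4 orientations x 2 scales, 2x2 pooling) are declared
surrogates and everything is configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .errors import ConfigurationError

__all__ = ["FilterBank", "V1Activation", "build_filter_bank", "v1_responses",
           "v1_encode", "v1_dim"]


@dataclass(frozen=True)
class FilterBank:
    """Oriented even/odd filter pairs; ``filters[s][o]`` is a (2, fs, fs)
    array for scale ``s``, orientation ``o``."""

    filters: tuple                 # nested tuples of ndarrays
    orientations: np.ndarray       # radians
    pool_size: int

    @property
    def n_scales(self) -> int:
        return len(self.filters)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)

    @property
    def content_hash(self) -> str:
        h = hashlib.sha1()
        for scale in self.filters:
            for pair in scale:
                h.update(np.ascontiguousarray(pair).tobytes())
        return h.hexdigest()[:12]


@dataclass
class V1Activation:
    """Sparse oriented-edge code for one image."""

    maps: list                     # per scale: (n_orient, H', W') in [0, 1]
    active_fraction: float

    def flat(self) -> np.ndarray:
        return np.concatenate([m.ravel() for m in self.maps])


def _gabor_pair(size: int, wavelength: float, theta: float,
                sigma: float, gamma: float = 0.8) -> np.ndarray:
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    env = np.exp(-(xr ** 2 + (gamma * yr) ** 2) / (2.0 * sigma ** 2))
    even = env * np.cos(2.0 * np.pi * xr / wavelength)
    odd = env * np.sin(2.0 * np.pi * xr / wavelength)
    even -= even.mean()
    odd -= odd.mean()
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return np.stack([even, odd])


def build_filter_bank(n_orientations: int = 4, n_scales: int = 2,
                      filter_size: int = 7, pool_size: int = 2) -> FilterBank:
    """Build the quadrature filter bank.  Scale ``s`` doubles the filter
    size and wavelength of scale ``s - 1``."""
    if n_orientations < 2:
        raise ConfigurationError("need at least 2 orientations")
    if n_scales < 1 or filter_size < 3 or pool_size < 1:
        raise ConfigurationError("invalid filter bank geometry")
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    scales = []
    for s in range(n_scales):
        fs = filter_size * (2 ** s)
        if fs % 2 == 0:
            fs += 1
        wavelength = fs / 2.0
        sigma = 0.56 * wavelength
        scales.append(tuple(_gabor_pair(fs, wavelength, th, sigma) for th in thetas))
    return FilterBank(filters=tuple(scales), orientations=thetas, pool_size=pool_size)


def _pool(resp: np.ndarray, p: int) -> np.ndarray:
    h, w = resp.shape
    hp, wp = h // p, w // p
    return resp[:hp * p, :wp * p].reshape(hp, p, wp, p).max(axis=(1, 3))


def v1_responses(img: np.ndarray, bank: FilterBank, gain: float = 2.0) -> list:
    """Pre-kWTA complex-cell responses, one (n_orient, H', W') map per
    scale, clipped to [0, 1].  Monotone in image contrast."""
    img = np.asarray(img, dtype=float)
    maps = []
    for scale in bank.filters:
        chans = []
        for pair in scale:
            even = correlate(img, pair[0], mode="nearest")
            odd = correlate(img, pair[1], mode="nearest")
            simple = np.maximum(np.abs(even), np.abs(odd))  # phase pooling
            chans.append(_pool(simple, bank.pool_size))
        maps.append(np.clip(gain * np.stack(chans), 0.0, 1.0))
    return maps


def _kwta_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask keeping the k largest strictly-positive entries
    (stable index order on ties)."""
    flat = values.ravel()
    mask = np.zeros(flat.shape, dtype=bool)
    if k >= flat.size:
        mask[flat > 0] = True
        return mask.reshape(values.shape)
    order = np.argsort(-flat, kind="stable")[:k]
    mask[order] = True
    mask &= flat > 0
    return mask.reshape(values.shape)


def v1_encode(img: np.ndarray, bank: FilterBank, kwta_pct: float = 0.15,
              gain: float = 2.0) -> V1Activation:
    """Encode an image: rectified/pooled responses sparsified per scale so
    the active fraction never exceeds ``kwta_pct``."""
    if not 0.0 < kwta_pct <= 1.0:
        raise ConfigurationError("kwta_pct must be in (0, 1]")
    maps = []
    active = 0
    total = 0
    for resp in v1_responses(img, bank, gain=gain):
        k = int(np.floor(kwta_pct * resp.size))
        out = np.where(_kwta_mask(resp, k), resp, 0.0)
        maps.append(out)
        active += int(np.count_nonzero(out))
        total += out.size
    return V1Activation(maps=maps, active_fraction=active / total)


def v1_dim(bank: FilterBank, image_size: int) -> int:
    """Length of the flattened encoding for a given image size."""
    p = bank.pool_size
    side = image_size // p
    return bank.n_scales * bank.n_orientations * side * side
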