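"""Sparse binary semantic category patterns shaped toward a target
similarity structure.

Category semantics enter the network as binary vectors with a fixed active
fraction (25% by default, matching the inhibitory activity regime of the
layers they feed).  Random initial patterns are "evolved" toward a target
category-by-category cosine-similarity matrix — in the original setting a
corpus-derived (latent semantic analysis) matrix, here a synthetic
block-structured surrogate or any user-supplied matrix — by a ratcheting
pair-flip procedure:

* for a pattern, a bit to switch ON is proposed by a softmax over
  ``sum_j target_sim[i, j] * patterns[j, bit]`` (bits shared with
  semantically close categories), and a bit to switch OFF by a softmax over
  the complementary weighting ``sum_j (1 - target_sim[i, j]) * patterns[j, bit]``;
* bits always flip in on/off pairs, so the active count is conserved;
* a proposed flip is kept only if the global mismatch between the pattern
  cosine matrix and the target strictly decreases ("ratcheting").

Mismatch is the mean absolute elementwise difference over off-diagonal
entries of the two cosine matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = ["DistanceMatrixTarget", "SemanticPatternSet", "make_target_dm",
           "init_patterns", "shape_patterns", "pattern_dm", "dm_mismatch"]


@dataclass(frozen=True)
class DistanceMatrixTarget:
    """Target pairwise cosine similarities (symmetric, unit diagonal)."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    clusters: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigurationError("target matrix must be square")
        if not np.allclose(m, m.T):
            raise ConfigurationError("target matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ConfigurationError("target matrix must have unit diagonal")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SemanticPatternSet:
    """Binary category patterns with fixed per-pattern activity."""

    patterns: np.ndarray               # (n, u) of {0, 1}
    active_count: int
    fit_trace: list = field(default_factory=list)
    stalled: bool = False

    @property
    def n(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    @property
    def pct_active(self) -> float:
        return self.active_count / self.n_units


def make_target_dm(n_categories: int, clusters: list | None = None,
                   within: float = 0.6, between: float = 0.2,
                   superordinate: list | None = None, super_sim: float = 0.35,
                   seed: int = 0) -> DistanceMatrixTarget:
    """Block-structured synthetic target: ``within`` similarity inside each
    cluster, ``between`` elsewhere, optionally an intermediate level for
    superordinate groups of clusters.  Deterministic (the seed is carried
    only for provenance)."""
    if clusters is None:
        clusters = [list(range(n_categories))]
    flat = sorted(i for cl in clusters for i in cl)
    if flat != list(range(n_categories)):
        raise ConfigurationError("clusters must partition range(n_categories)")
    m = np.full((n_categories, n_categories), float(between))
    if superordinate is not None:
        for group in superordinate:
            idx = [i for ci in group for i in clusters[ci]]
            m[np.ix_(idx, idx)] = super_sim
    for cl in clusters:
        m[np.ix_(cl, cl)] = within
    np.fill_diagonal(m, 1.0)
    labels = tuple(f"cat{i:03d}" for i in range(n_categories))
    return DistanceMatrixTarget(matrix=m, labels=labels,
                                clusters=tuple(tuple(cl) for cl in clusters))


def init_patterns(n: int, n_units: int = 100, pct_active: float = 0.25,
                  seed: int = 0) -> SemanticPatternSet:
    """``n`` distinct random binary vectors with exactly
    ``round(pct_active * n_units)`` bits on each."""
    a = int(round(pct_active * n_units))
    if a < 1:
        raise ConfigurationError("active count must be >= 1")
    if n > comb(n_units, a):
        raise ConfigurationError(
            f"cannot draw {n} distinct patterns with {a} of {n_units} bits on")
    rng = np.random.Generator(np.random.PCG64(seed))
    seen: set[bytes] = set()
    pats = np.zeros((n, n_units), dtype=np.int8)
    i = 0
    while i < n:
        v = np.zeros(n_units, dtype=np.int8)
        v[rng.choice(n_units, size=a, replace=False)] = 1
        key = v.tobytes()
        if key in seen:
            continue
        seen.add(key)
        pats[i] = v
        i += 1
    return SemanticPatternSet(patterns=pats, active_count=a)


def pattern_dm(patterns: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of pattern rows.  For equal activity
    ``a`` this is overlap / a."""
    p = np.asarray(patterns, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty pattern set")
    norms = np.linalg.norm(p, axis=1)
    norms[norms == 0] = 1.0
    return (p @ p.T) / np.outer(norms, norms)


def dm_mismatch(dm: np.ndarray, target: np.ndarray) -> float:
    """Mean |difference| over off-diagonal entries."""
    n = dm.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(np.mean(np.abs(dm[off] - target[off])))


def _softmax_choice(rng: np.random.Generator, candidates: np.ndarray,
                    scores: np.ndarray, temperature: float) -> int:
    z = scores / max(temperature, 1e-12)
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(candidates, p=p))


def shape_patterns(patterns: SemanticPatternSet, target: DistanceMatrixTarget,
                   max_iters: int = 1000, seed: int = 0,
                   temperature: float = 1.0) -> SemanticPatternSet:
    """Ratcheted pair-flip shaping of ``patterns`` toward ``target``.

    One iteration is a sweep proposing one on/off pair flip for every
    pattern (in seeded random order); each proposal is kept only if the
    global off-diagonal mismatch strictly decreases.  The fit trace records
    the mismatch at start and after every accepted flip, so it is strictly
    decreasing after the first entry.  If a full sweep accepts nothing the
    procedure stalls and terminates early (flagged, not an error).
    """
    if target.n != patterns.n:
        raise ConfigurationError("target dimension must match pattern count")
    if patterns.n < 2:
        return SemanticPatternSet(patterns=patterns.patterns.copy(),
                                  active_count=patterns.active_count,
                                  fit_trace=[0.0], stalled=True)
    rng = np.random.Generator(np.random.PCG64(seed))
    P = patterns.patterns.astype(np.int8).copy()
    n, u = P.shape
    a = patterns.active_count
    T = target.matrix
    Pf = P.astype(float)
    overlap = Pf @ Pf.T
    cos = overlap / a
    off_w = 1.0 / (n * (n - 1))                 # each ordered off-diag pair
    mismatch = dm_mismatch(cos, T)
    trace = [mismatch]

    for _ in range(max_iters):
        accepted = False
        for i in rng.permutation(n):
            row_p = P[i]
            on_bits = np.flatnonzero(row_p == 1)
            off_bits = np.flatnonzero(row_p == 0)
            others = np.arange(n) != i
            sim = T[i]                          # similarity weighting
            # bits shared with close categories are good candidates to gain,
            # bits shared with distant categories good candidates to lose
            gain_scores = (sim[others, None] * P[others][:, off_bits]).sum(axis=0)
            lose_scores = ((1.0 - sim[others, None]) * P[others][:, on_bits]).sum(axis=0)
            b_on = _softmax_choice(rng, off_bits, gain_scores, temperature)
            b_off = _softmax_choice(rng, on_bits, lose_scores, temperature)
            d_overlap = (P[:, b_on] - P[:, b_off]).astype(float)
            d_overlap[i] = 0.0
            new_row = (overlap[i] + d_overlap) / a
            new_row[i] = 1.0
            old_err = np.abs(cos[i, others] - T[i, others]).sum()
            new_err = np.abs(new_row[others] - T[i, others]).sum()
            new_mismatch = mismatch + 2.0 * off_w * (new_err - old_err)
            if new_mismatch < mismatch - 1e-15:
                P[i, b_on] = 1
                P[i, b_off] = 0
                overlap[i] += d_overlap
                overlap[:, i] = overlap[i]
                cos[i] = new_row
                cos[:, i] = new_row
                mismatch = new_mismatch
                trace.append(mismatch)
                accepted = True
        if not accepted:
            return SemanticPatternSet(patterns=P, active_count=a,
                                      fit_trace=trace, stalled=True)
    return SemanticPatternSet(patterns=P, active_count=a, fit_trace=trace)
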