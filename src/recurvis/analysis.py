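"""Measurement machinery: completion trajectories, two-tier majority
voting, occlusion sweeps, distance-matrix comparisons and semantic
inference.

All model-facing operations accept any object with a ``respond(image) ->
output activation`` method; the recurrent-specific analyses (trajectories,
layer distance matrices, semantic inference) additionally need the
:class:`~recurvis.learning.RecurrentModel` surface (``settle_on``,
``encode``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .images import AffineRanges, apply_affine, sample_affine
from .learning import RecurrentModel
from .network import OUTPUT, SEMANTICS
from .occlusion import BlobFilter, OcclusionSpec, occlude

logger = logging.getLogger(__name__)

__all__ = ["cosine", "completion_trajectory", "VoteResult", "vote",
           "second_order_vote", "EvalResult", "evaluate", "dm_correlation",
           "category_dm", "semantic_inference"]


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised inner product; defined as 0 when either vector is zero."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.debug("cosine of zero vector defined as 0")
        return 0.0
    return float(a @ b / (na * nb))


def completion_trajectory(model: RecurrentModel, image: np.ndarray,
                          blob: BlobFilter, spec: OcclusionSpec,
                          reference: dict | None = None) -> pd.DataFrame:
    """Per-cycle, per-layer cosine similarity between the settling
    trajectory on the occluded image and the settled reference state on the
    unoccluded image.

    Returns a long-format frame (layer, cycle, cosine).  The reference is
    computed here when not supplied.
    """
    if reference is None:
        reference = model.settle_on(image).acts
    occluded = occlude(image, blob, spec)
    result = model.settle_on(occluded, record=True)
    rows = []
    for cycle, snap in enumerate(result.snapshots, start=1):
        for layer, act in snap.items():
            rows.append({"layer": layer, "cycle": cycle,
                         "cosine": cosine(act, reference[layer])})
    return pd.DataFrame(rows)


@dataclass
class VoteResult:
    votes: list                     # per-presentation winning category index
    winner: int
    scores: np.ndarray              # summed output activation per category
    tied: bool = False


def _modal_winner(votes: list[int], scores: np.ndarray) -> tuple[int, bool]:
    counts = np.bincount(votes, minlength=len(scores))
    top = counts.max()
    contenders = np.flatnonzero(counts == top)
    if len(contenders) == 1:
        return int(contenders[0]), False
    # tie: highest summed activation, then lowest index
    best = contenders[np.argmax(scores[contenders])]
    return int(best), True


def vote(model, image: np.ndarray, n_presentations: int = 7,
         ranges: AffineRanges | None = None,
         rng: np.random.Generator | None = None,
         blob: BlobFilter | None = None,
         occlusion: OcclusionSpec | None = None) -> VoteResult:
    """First-order majority vote over affine-transformed presentations of a
    single image.  Any occlusion mask is applied once, before the
    transforms, so the occluded features are the same in every
    presentation."""
    if n_presentations < 1:
        raise ConfigurationError("n_presentations must be >= 1")
    rng = rng if rng is not None else np.random.Generator(np.random.PCG64(0))
    if occlusion is not None and occlusion.level > 0:
        if blob is None:
            raise ConfigurationError("occlusion requested without a blob filter")
        image = occlude(image, blob, occlusion)
    votes = []
    scores = None
    for _ in range(n_presentations):
        out = model.respond(apply_affine(image, sample_affine(rng, ranges)))
        votes.append(int(np.argmax(out)))
        scores = out if scores is None else scores + out
    winner, tied = _modal_winner(votes, scores)
    return VoteResult(votes=votes, winner=winner, scores=scores, tied=tied)


def second_order_vote(render_votes: list[VoteResult]) -> int:
    """Majority over first-order winners (one per render of an exemplar),
    same tie rule."""
    if not render_votes:
        raise InvalidInputError("no votes to aggregate")
    firsts = [v.winner for v in render_votes]
    scores = np.sum([v.scores for v in render_votes], axis=0)
    winner, _ = _modal_winner(firsts, scores)
    return winner


@dataclass
class EvalResult:
    accuracy: float                 # percent correct
    per_category: pd.DataFrame
    records: pd.DataFrame


def evaluate(model, manifest: pd.DataFrame, images: np.ndarray,
             vote_mode: str = "2d", n_presentations: int = 7,
             ranges: AffineRanges | None = None,
             blob: BlobFilter | None = None, occlusion_level: float = 0.0,
             seed: int = 0) -> EvalResult:
    """Accuracy of a model over a test manifest.

    ``vote_mode``: ``none`` (single presentation, no transform voting),
    ``2d`` (first-order vote over affine presentations), ``full``
    (second-order vote across all renders of each exemplar; scored per
    exemplar).  Occlusion draws a fresh mask seed per test item.
    """
    if len(manifest) == 0:
        raise InvalidInputError("empty test manifest")
    if vote_mode not in ("none", "2d", "full"):
        raise ConfigurationError(f"unknown vote_mode {vote_mode!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    cat_idx = {c: i for i, c in enumerate(model.categories)}
    n_pres = 1 if vote_mode == "none" else n_presentations

    def occ_spec() -> OcclusionSpec | None:
        if occlusion_level <= 0:
            return None
        return OcclusionSpec(level=occlusion_level,
                             seed=int(rng.integers(2 ** 31)))

    records = []
    if vote_mode == "full":
        for (cat, ex), grp in manifest.groupby(["category", "exemplar"], sort=True):
            rv = [vote(model, images[i], n_pres, ranges, rng, blob, occ_spec())
                  for i in grp.index]
            winner = second_order_vote(rv)
            records.append({"category": cat, "exemplar": ex,
                            "winner": model.categories[winner],
                            "correct": winner == cat_idx[cat]})
    else:
        for i, row in manifest.iterrows():
            res = vote(model, images[i], n_pres, ranges, rng, blob, occ_spec())
            records.append({"category": row.category, "exemplar": row.exemplar,
                            "winner": model.categories[res.winner],
                            "correct": res.winner == cat_idx[row.category]})
    rec = pd.DataFrame(records)
    per_cat = (rec.groupby("category")["correct"].mean() * 100.0
               ).rename("accuracy").reset_index()
    return EvalResult(accuracy=float(rec["correct"].mean() * 100.0),
                      per_category=per_cat, records=rec)


def dm_correlation(dm1: np.ndarray, dm2: np.ndarray) -> float:
    """Pearson correlation over the off-diagonal upper triangle of two
    same-shape similarity matrices."""
    dm1 = np.asarray(dm1, dtype=float)
    dm2 = np.asarray(dm2, dtype=float)
    if dm1.shape != dm2.shape or dm1.ndim != 2 or dm1.shape[0] != dm1.shape[1]:
        raise InvalidInputError("matrices must be square and same shape")
    n = dm1.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 categories")
    iu = np.triu_indices(n, k=1)
    a, b = dm1[iu], dm2[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidInputError("correlation undefined for constant matrix")
    return float(stats.pearsonr(a, b)[0])


def category_dm(model: RecurrentModel, manifest: pd.DataFrame,
                images: np.ndarray, layer: str = "IT") -> np.ndarray:
    """Pairwise cosine matrix between per-category mean settled activations
    at a named layer, over the manifest's images (no augmentation)."""
    means = []
    for cat in model.categories:
        idx = manifest.index[manifest["category"] == cat]
        if len(idx) == 0:
            raise InvalidInputError(f"category {cat!r} has no test items")
        acts = [model.settle_on(images[i]).acts[layer] for i in idx]
        means.append(np.mean(acts, axis=0))
    n = len(means)
    dm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = cosine(means[i], means[j])
    return dm


def semantic_inference(model: RecurrentModel, image: np.ndarray,
                       patterns: np.ndarray,
                       labels: list[str] | None = None) -> pd.DataFrame:
    """Trajectory of the free Semantics layer's similarity to every
    canonical category pattern while the network settles on an image.

    Returns a long-format frame (cycle, category, cosine); the final-cycle
    block carries the ranking.  The mean final similarity across categories
    is the chance baseline to compare individual categories against.
    """
    if SEMANTICS not in model.net.layers:
        raise ConfigurationError("model has no Semantics layer")
    labels = labels if labels is not None else [f"cat{i:03d}"
                                                for i in range(len(patterns))]
    result = model.settle_on(image, record=True)
    rows = []
    for cycle, snap in enumerate(result.snapshots, start=1):
        sem = snap[SEMANTICS]
        for c, lab in enumerate(labels):
            rows.append({"cycle": cycle, "category": lab,
                         "cosine": cosine(sem, patterns[c])})
    return pd.DataFrame(rows)


def final_ranking(trajectory: pd.DataFrame) -> list[str]:
    """Categories ordered by similarity at the last cycle (best first)."""
    last = trajectory[trajectory["cycle"] == trajectory["cycle"].max()]
    return list(last.sort_values("cosine", ascending=False)["category"])
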