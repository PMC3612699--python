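"""Error-driven learning: two-phase contrastive updates for the recurrent
network, and the two feedforward backpropagation comparison networks.

Recurrent learning contrasts a *minus* phase (input clamped, everything
else free) with a *plus* phase (input plus targets clamped: the one-hot
category unit and, when the semantics experiment is enabled, the category's
semantic pattern).  Each projection then moves by the contrastive Hebbian
rule with a small pure-Hebbian mix:

    dw = eps * [ (1 - m) * (x+ y+  -  x- y-)  +  m * y+ (x+ - w) ]

with soft weight bounding (increases scaled by ``1 - w``, decreases by
``w``) keeping every weight in [0, 1].  Feedback projections learn too.

The comparison networks are plain sigmoid MLPs with the same layer sizes,
trained by backpropagation on a cross-entropy loss with an error tolerance
(output units within tolerance of their target contribute no gradient), no
momentum and no weight decay.  The *sparse* variant starts from strongly
negative biases and consumes the kWTA-sparsified front-end code; the
*distributed* variant starts from zero biases, a lower learning rate, and
consumes the raw (non-kWTA) front-end responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InvalidInputError, SimulationError
from .images import AffineRanges, apply_affine, sample_affine
from .network import (IT, OUTPUT, SEMANTICS, V1, V2V4, Network, NetworkSpec,
                      build_network, settle, ventral_spec)
from .v1 import FilterBank, build_filter_bank, v1_encode, v1_responses

__all__ = ["TrainProtocol", "chl_update", "cross_entropy", "RecurrentModel",
           "train_trial", "train", "BpNetworkSpec", "bp_spec", "BpNetwork",
           "build_bp_network", "bp_train_trial", "bp_train", "BpModel"]


# ---------------------------------------------------------------------------
# contrastive rule


def chl_update(weights: np.ndarray, x_minus: np.ndarray, y_minus: np.ndarray,
               x_plus: np.ndarray, y_plus: np.ndarray,
               lrate: float, hebb_mix: float = 0.0) -> np.ndarray:
    """Weight delta for one projection from its phase activations.

    Identical phases with ``hebb_mix = 0`` give a null update; soft
    bounding rescales positive deltas by ``1 - w`` and negative ones by
    ``w`` so no sequence of updates can leave [0, 1].
    """
    err = np.outer(x_plus, y_plus) - np.outer(x_minus, y_minus)
    hebb = y_plus[None, :] * (x_plus[:, None] - weights)
    raw = lrate * ((1.0 - hebb_mix) * err + hebb_mix * hebb)
    return np.where(raw > 0, raw * (1.0 - weights), raw * weights)


@dataclass(frozen=True)
class TrainProtocol:
    """Training schedule and learning constants for the recurrent model."""

    epochs: int = 30
    images_per_epoch: int | None = None   # None: the full training set
    lrate: float = 0.03
    hebb_mix: float = 0.005
    minus_cycles: int = 30
    plus_cycles: int = 30
    tol: float = 0.005
    use_semantics: bool = False
    stop_at_train_acc: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lrate <= 0:
            raise ConfigurationError("learning rate must be > 0")
        if not 0.0 <= self.hebb_mix <= 1.0:
            raise ConfigurationError("hebb_mix must be in [0, 1]")


@dataclass
class RecurrentModel:
    """A recurrent network bundled with its front-end and category map —
    everything needed to turn an image into a settled response."""

    net: Network
    bank: FilterBank
    categories: list[str]
    kwta_pct: float = 0.15
    v1_gain: float = 2.0
    max_cycles: int = 60
    tol: float = 0.005
    semantic_patterns: np.ndarray | None = None

    def encode(self, img: np.ndarray) -> np.ndarray:
        return v1_encode(img, self.bank, kwta_pct=self.kwta_pct,
                         gain=self.v1_gain).flat()

    def settle_on(self, img: np.ndarray, record: bool = False,
                  max_cycles: int | None = None):
        self.net.reset_state()
        return settle(self.net, {V1: self.encode(img)},
                      max_cycles=max_cycles or self.max_cycles,
                      tol=self.tol, record=record)

    def respond(self, img: np.ndarray) -> np.ndarray:
        """Settled output-layer activation for one image."""
        return self.settle_on(img).acts[OUTPUT]


def train_trial(model: RecurrentModel, image: np.ndarray, category: str,
                protocol: TrainProtocol, rng: np.random.Generator,
                ranges: AffineRanges | None = None,
                semantics_pattern: np.ndarray | None = None) -> dict:
    """One two-phase trial: augment, encode, minus-phase settle, clamp
    targets, plus-phase settle, contrastive update on every projection."""
    if category not in model.categories:
        raise InvalidInputError(f"unknown category {category!r}")
    cat_idx = model.categories.index(category)
    img = apply_affine(image, sample_affine(rng, ranges))
    v1_act = v1_encode(img, model.bank, kwta_pct=model.kwta_pct,
                       gain=model.v1_gain).flat()

    net = model.net
    net.reset_state()
    minus = settle(net, {V1: v1_act}, max_cycles=protocol.minus_cycles,
                   tol=protocol.tol)
    out = minus.acts[OUTPUT]
    winner = int(np.argmax(out))
    correct = winner == cat_idx and out[winner] > 0

    target = np.zeros(len(model.categories))
    target[cat_idx] = 1.0
    clamps = {V1: v1_act, OUTPUT: target}
    if protocol.use_semantics:
        if semantics_pattern is None:
            if model.semantic_patterns is None:
                raise ConfigurationError("semantics enabled but no patterns given")
            semantics_pattern = model.semantic_patterns[cat_idx]
        clamps[SEMANTICS] = np.asarray(semantics_pattern, dtype=float)
    plus = settle(net, clamps, max_cycles=protocol.plus_cycles, tol=protocol.tol)

    for p in net.projections:
        dw = chl_update(p.weights,
                        minus.acts[p.sender], minus.acts[p.receiver],
                        plus.acts[p.sender], plus.acts[p.receiver],
                        protocol.lrate, protocol.hebb_mix)
        np.clip(p.weights + dw, 0.0, 1.0, out=p.weights)
    return {"correct": correct, "winner": winner, "target": cat_idx,
            "minus_cycles": minus.cycles}


def train(model: RecurrentModel, images: np.ndarray, labels: list[str],
          protocol: TrainProtocol, ranges: AffineRanges | None = None,
          ) -> pd.DataFrame:
    """Epoch loop over the training set (seeded order and augmentation
    streams kept separate).  Returns the per-epoch log."""
    order_rng = np.random.Generator(np.random.PCG64([protocol.seed, 1]))
    aug_rng = np.random.Generator(np.random.PCG64([protocol.seed, 2]))
    n = len(images)
    log = []
    for epoch in range(protocol.epochs):
        idx = order_rng.permutation(n)
        if protocol.images_per_epoch is not None:
            idx = idx[:protocol.images_per_epoch]
        hits = 0
        cycles = 0
        for i in idx:
            stats = train_trial(model, images[i], labels[i], protocol,
                                aug_rng, ranges)
            hits += stats["correct"]
            cycles += stats["minus_cycles"]
        acc = 100.0 * hits / len(idx)
        log.append({"epoch": epoch, "train_acc": acc,
                    "mean_minus_cycles": cycles / len(idx)})
        if protocol.stop_at_train_acc is not None and acc >= protocol.stop_at_train_acc:
            break
    return pd.DataFrame(log)


# ---------------------------------------------------------------------------
# cross-entropy with error tolerance


def cross_entropy(target: np.ndarray, output: np.ndarray,
                  tolerance: float = 0.05) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and its gradient w.r.t. the output, with units
    within ``tolerance`` of their target contributing zero gradient."""
    t = np.asarray(target, dtype=float)
    o = np.clip(np.asarray(output, dtype=float), 1e-12, 1.0 - 1e-12)
    ce = float(-np.sum(t * np.log(o) + (1.0 - t) * np.log(1.0 - o)))
    grad = (o - t) / (o * (1.0 - o))
    grad[np.abs(t - o) <= tolerance] = 0.0
    return ce, grad


# ---------------------------------------------------------------------------
# backpropagation comparison networks


@dataclass(frozen=True)
class BpNetworkSpec:
    """Feedforward comparison network: same layer sizes as the recurrent
    stack, no feedback projections."""

    layer_sizes: tuple[int, ...]          # input, hidden..., output
    variant: str = "sparse"
    bias_init: float = -3.0
    lrate: float = 0.2
    error_tolerance: float = 0.05
    kwta_input: bool = True


def bp_spec(variant: str, layer_sizes) -> BpNetworkSpec:
    """The two published parameter bundles."""
    sizes = tuple(int(s) for s in layer_sizes)
    if variant == "sparse":
        return BpNetworkSpec(sizes, "sparse", bias_init=-3.0, lrate=0.2,
                             kwta_input=True)
    if variant == "distrib":
        return BpNetworkSpec(sizes, "distrib", bias_init=0.0, lrate=0.01,
                             kwta_input=False)
    raise ConfigurationError(f"unknown bp variant {variant!r}")


class BpNetwork:
    """Sigmoid MLP with zero-mean +/-0.5 uniform initial weights."""

    def __init__(self, spec: BpNetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.Generator(np.random.PCG64(seed))
        self.weights = [rng.uniform(-0.5, 0.5, size=(a, b))
                        for a, b in zip(spec.layer_sizes, spec.layer_sizes[1:])]
        self.biases = [np.full(b, float(spec.bias_init))
                       for b in spec.layer_sizes[1:]]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [np.asarray(x, dtype=float)]
        for w, b in zip(self.weights, self.biases):
            acts.append(expit(acts[-1] @ w + b))
        return acts

    def respond(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[-1]


def build_bp_network(spec: BpNetworkSpec, seed: int = 0) -> BpNetwork:
    return BpNetwork(spec, seed)


def bp_train_trial(net: BpNetwork, x: np.ndarray, target: np.ndarray,
                   tolerance: float | None = None) -> dict:
    """Forward pass, tolerance-gated cross-entropy, backpropagated update."""
    tol = net.spec.error_tolerance if tolerance is None else tolerance
    acts = net.forward(x)
    out = acts[-1]
    ce, _ = cross_entropy(target, out, tol)
    if not np.isfinite(ce):
        raise SimulationError(f"non-finite loss {ce} (outputs {out})")
    # with sigmoid output, dCE/dz simplifies to (o - t); gate by tolerance
    delta = out - target
    delta[np.abs(target - out) <= tol] = 0.0
    deltas = [delta]
    for layer in range(len(net.weights) - 1, 0, -1):
        a = acts[layer]
        deltas.insert(0, (deltas[0] @ net.weights[layer].T) * a * (1.0 - a))
    for layer, d in enumerate(deltas):
        net.weights[layer] -= net.spec.lrate * np.outer(acts[layer], d)
        net.biases[layer] -= net.spec.lrate * d
    correct = int(np.argmax(out)) == int(np.argmax(target))
    return {"loss": ce, "correct": correct}


@dataclass
class BpModel:
    """A trained backpropagation network plus its front-end, mirroring
    :class:`RecurrentModel`'s image-in / output-activation-out surface."""

    net: BpNetwork
    bank: FilterBank
    categories: list[str]
    kwta_pct: float = 0.15
    v1_gain: float = 2.0

    def encode(self, img: np.ndarray) -> np.ndarray:
        if self.net.spec.kwta_input:
            return v1_encode(img, self.bank, kwta_pct=self.kwta_pct,
                             gain=self.v1_gain).flat()
        return np.concatenate([m.ravel() for m in
                               v1_responses(img, self.bank, gain=self.v1_gain)])

    def respond(self, img: np.ndarray) -> np.ndarray:
        return self.net.respond(self.encode(img))


def bp_train(model: BpModel, images: np.ndarray, labels: list[str],
             epochs: int, ranges: AffineRanges | None = None, seed: int = 0,
             stop_at_train_acc: float | None = None) -> pd.DataFrame:
    order_rng = np.random.Generator(np.random.PCG64([seed, 1]))
    aug_rng = np.random.Generator(np.random.PCG64([seed, 2]))
    n_cat = len(model.categories)
    log = []
    for epoch in range(epochs):
        hits = 0
        losses = 0.0
        idx = order_rng.permutation(len(images))
        for i in idx:
            img = apply_affine(images[i], sample_affine(aug_rng, ranges))
            x = model.encode(img)
            target = np.zeros(n_cat)
            target[model.categories.index(labels[i])] = 1.0
            stats = bp_train_trial(model.net, x, target)
            hits += stats["correct"]
            losses += stats["loss"]
        acc = 100.0 * hits / len(idx)
        log.append({"epoch": epoch, "train_acc": acc, "mean_ce": losses / len(idx)})
        if stop_at_train_acc is not None and acc >= stop_at_train_acc:
            break
    return pd.DataFrame(log)
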