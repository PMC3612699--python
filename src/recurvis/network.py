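"""Recurrent rate-code network: layers, bidirectional projections,
per-cycle membrane-potential updates, k-winners-take-all inhibition,
settling, clamping, and the feedback lesion.

Each unit is a point neuron with a normalised membrane potential ``V_m``
driven by three conductances toward their reversal potentials,

    dV_m = dt * [ g_e (E_e - V_m) + g_i g_bar_i (E_i - V_m)
                  + g_bar_l (E_l - V_m) ]

with excitatory reversal above threshold, leak below it, and inhibition
lowest (defaults E_e = 1.0, theta = 0.5, E_l = 0.3, E_i = 0.15).  The
excitatory conductance is the weighted sum of sender activations per
projection, normalised by the sender layer's expected active count, with
feedback projections scaled down (default 0.2) and gated by a ``fb_gain``
switch whose zero setting silences top-down transmission exactly.

Inhibition is a single conductance shared by all units of a layer, placed
by the kWTA rule between the threshold-equalising conductances of the k-th
and (k+1)-th most driven units, so at most k units can sit above threshold
at equilibrium.  Because the membrane potential is integrated (not jumped
to equilibrium), activations are additionally masked to the k units with
the highest ``V_m`` each cycle (stable index order on ties), which makes
the at-most-k-active guarantee hold at every cycle, not just at the fixed
point.  Activation of unmasked units is a logistic function of
``V_m - theta`` with high gain.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, SimulationError

logger = logging.getLogger(__name__)

#: Canonical layer names of the ventral-stack architecture.
V1, V2V4, IT, OUTPUT, SEMANTICS = "V1", "V2V4", "IT", "Output", "Semantics"


@dataclass(frozen=True)
class LayerSpec:
    name: str
    size: int
    k: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError(f"layer {self.name}: size must be >= 1")
        if self.k < 1 or self.k > self.size:
            raise ConfigurationError(
                f"layer {self.name}: k={self.k} outside [1, {self.size}]")


@dataclass(frozen=True)
class ProjectionSpec:
    sender: str
    receiver: str
    feedback: bool = False


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture plus all dynamics constants (normalised units)."""

    layers: tuple[LayerSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    dt: float = 0.3
    gain: float = 60.0
    theta: float = 0.5
    e_rev: float = 1.0
    l_rev: float = 0.3
    i_rev: float = 0.15
    g_bar_l: float = 0.1
    g_bar_i: float = 1.0
    fb_scale: float = 0.35
    kwta_q: float = 0.25
    init_mean: float = 0.5
    init_range: float = 0.25

    def layer(self, name: str) -> LayerSpec:
        for ls in self.layers:
            if ls.name == name:
                return ls
        raise KeyError(name)


def ventral_spec(n_input: int, n_categories: int, input_k: int,
                 v2_size: int = 100, v2_k: int = 15,
                 it_size: int = 60, it_k: int = 10,
                 semantics_units: int | None = None, semantics_k: int | None = None,
                 **kwargs) -> NetworkSpec:
    """The standard layer stack V1 -> V2/V4 -> IT -> Output with reciprocal
    connectivity between hidden layers (V1 receives no feedback) and an
    optional Semantics layer bidirectionally linked to IT."""
    layers = [LayerSpec(V1, n_input, input_k),
              LayerSpec(V2V4, v2_size, v2_k),
              LayerSpec(IT, it_size, it_k),
              LayerSpec(OUTPUT, n_categories, 1)]
    projections = [ProjectionSpec(V1, V2V4),
                   ProjectionSpec(V2V4, IT), ProjectionSpec(IT, V2V4, feedback=True),
                   ProjectionSpec(IT, OUTPUT), ProjectionSpec(OUTPUT, IT, feedback=True)]
    if semantics_units is not None:
        sk = semantics_k if semantics_k is not None else max(1, semantics_units // 4)
        layers.append(LayerSpec(SEMANTICS, semantics_units, sk))
        projections.append(ProjectionSpec(IT, SEMANTICS))
        projections.append(ProjectionSpec(SEMANTICS, IT, feedback=True))
    return NetworkSpec(layers=tuple(layers), projections=tuple(projections), **kwargs)


@dataclass
class Projection:
    sender: str
    receiver: str
    weights: np.ndarray            # (n_sender, n_receiver) in [0, 1]
    feedback: bool = False
    fb_gain: float = 1.0


@dataclass
class LayerState:
    v_m: np.ndarray
    act: np.ndarray
    g_e: np.ndarray
    rate: np.ndarray | None = None   # integrated firing rate, pre-mask
    g_i: float = 0.0


@dataclass
class SettleResult:
    acts: dict                     # final activation per layer
    cycles: int
    converged: bool
    snapshots: list | None = None  # per-cycle {layer: act} if recorded


class Network:
    """Mutable simulation state for one network instance."""

    def __init__(self, spec: NetworkSpec, projections: list[Projection]):
        self.spec = spec
        self.projections = projections
        self.layers: dict[str, LayerState] = {}
        self.reset_state()

    def reset_state(self) -> None:
        for ls in self.spec.layers:
            self.layers[ls.name] = LayerState(
                v_m=np.full(ls.size, self.spec.l_rev),
                act=np.zeros(ls.size),
                g_e=np.zeros(ls.size),
                rate=np.zeros(ls.size))

    def incoming(self, name: str) -> list[Projection]:
        return [p for p in self.projections if p.receiver == name]

    def copy(self) -> "Network":
        return copy.deepcopy(self)


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Initialise weights uniformly around ``init_mean`` (+/- ``init_range``
    before bounding into [0, 1]); deterministic given seed."""
    rng = np.random.Generator(np.random.PCG64(seed))
    sizes = {ls.name: ls.size for ls in spec.layers}
    projections = []
    for ps in spec.projections:
        w = rng.uniform(spec.init_mean - spec.init_range,
                        spec.init_mean + spec.init_range,
                        size=(sizes[ps.sender], sizes[ps.receiver]))
        projections.append(Projection(sender=ps.sender, receiver=ps.receiver,
                                      weights=np.clip(w, 0.0, 1.0),
                                      feedback=ps.feedback))
    return Network(spec, projections)


def _g_theta(g_e: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Inhibitory conductance at which each unit's equilibrium potential
    equals threshold."""
    num = g_e * (spec.e_rev - spec.theta) + spec.g_bar_l * (spec.l_rev - spec.theta)
    return num / (spec.g_bar_i * (spec.theta - spec.i_rev))


def kwta_inhibition(g_e: np.ndarray, k: int, spec: NetworkSpec | None = None,
                    q: float | None = None) -> float:
    """Shared inhibitory conductance for a layer given per-unit excitatory
    drive.

    Placed between the k-th and (k+1)-th largest threshold conductances:
    ``g_i = gtheta(k+1) + q * (gtheta(k) - gtheta(k+1))``.  With k >= n the
    conductance is set just below the weakest unit so all may be active
    (logged).  Never negative.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if spec is None:
        spec = NetworkSpec(layers=(), projections=())
    if q is None:
        q = spec.kwta_q
    gt = np.sort(_g_theta(np.asarray(g_e, dtype=float), spec))[::-1]
    n = gt.size
    if k >= n:
        logger.debug("kWTA with k=%d >= n=%d: inhibition below weakest unit", k, n)
        return float(max(0.0, gt[-1] - 0.1 * abs(gt[-1]) - 1e-9))
    g_i = gt[k] + q * (gt[k - 1] - gt[k])
    return float(max(0.0, g_i))


def _top_k_mask(v_m: np.ndarray, k: int) -> np.ndarray:
    if k >= v_m.size:
        return np.ones(v_m.size, dtype=bool)
    order = np.argsort(-v_m, kind="stable")[:k]
    mask = np.zeros(v_m.size, dtype=bool)
    mask[order] = True
    return mask


def update_cycle(net: Network, clamps: dict[str, np.ndarray] | None = None) -> Network:
    """One synchronous update of every free layer's conductances, membrane
    potentials and activations.  Clamped layers have their activations held
    at the clamp values and their dynamics skipped."""
    spec = net.spec
    clamps = clamps or {}
    for name, val in clamps.items():
        st = net.layers[name]
        st.act = np.asarray(val, dtype=float)
        st.v_m = spec.l_rev + st.act * (spec.e_rev - spec.l_rev)

    sender_k = {ls.name: ls.k for ls in spec.layers}
    new_ge: dict[str, np.ndarray] = {}
    for ls in spec.layers:
        if ls.name in clamps:
            continue
        g = np.zeros(ls.size)
        for p in net.incoming(ls.name):
            scale = (spec.fb_scale * p.fb_gain) if p.feedback else 1.0
            if scale == 0.0:
                continue
            g += (scale / sender_k[p.sender]) * (net.layers[p.sender].act @ p.weights)
        new_ge[ls.name] = g

    for ls in spec.layers:
        if ls.name in clamps:
            continue
        st = net.layers[ls.name]
        st.g_e = new_ge[ls.name]
        st.g_i = kwta_inhibition(st.g_e, ls.k, spec)
        dv = (st.g_e * (spec.e_rev - st.v_m)
              + st.g_i * spec.g_bar_i * (spec.i_rev - st.v_m)
              + spec.g_bar_l * (spec.l_rev - st.v_m))
        st.v_m = st.v_m + spec.dt * dv
        if not np.all(np.isfinite(st.v_m)):
            raise SimulationError(f"non-finite membrane potential in layer {ls.name}")
        # firing rate integrates toward the logistic drive with the membrane
        # time constant; the top-k mask on the emitted activation enforces
        # the at-most-k-active bound at every cycle, and the slow rate damps
        # the winner flip-flop a synchronous discrete update would produce
        drive = expit(spec.gain * (st.v_m - spec.theta))
        st.rate = st.rate + spec.dt * (drive - st.rate)
        st.act = np.where(_top_k_mask(st.v_m, ls.k), st.rate, 0.0)
    return net


def settle(net: Network, clamps: dict[str, np.ndarray] | None = None,
           max_cycles: int = 60, tol: float = 0.005,
           record: bool = False) -> SettleResult:
    """Run update cycles until the largest per-unit activation change drops
    below ``tol`` or ``max_cycles`` is reached.  Non-convergence is flagged,
    not fatal."""
    if max_cycles < 1:
        raise ConfigurationError("max_cycles must be >= 1")
    clamps = clamps or {}
    snapshots = [] if record else None

    def state():
        return {name: (st.act.copy(), st.v_m.copy())
                for name, st in net.layers.items()}

    prev = state()
    converged = False
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        update_cycle(net, clamps)
        if record:
            snapshots.append({name: st.act.copy() for name, st in net.layers.items()})
        # convergence needs both activations and membrane potentials quiet:
        # sub-threshold units can drift for many cycles with near-zero act
        delta = max(max(np.max(np.abs(net.layers[n].act - a)),
                        np.max(np.abs(net.layers[n].v_m - v)))
                    for n, (a, v) in prev.items())
        if delta < tol:
            converged = True
            break
        prev = state()
    return SettleResult(acts={name: st.act.copy() for name, st in net.layers.items()},
                        cycles=cycles, converged=converged, snapshots=snapshots)


def lesion_feedback(net: Network) -> Network:
    """Return a copy with ``fb_gain = 0`` on every feedback projection.
    Weights are untouched, so the lesion is restorable."""
    out = net.copy()
    for p in out.projections:
        if p.feedback:
            p.fb_gain = 0.0
    return out


def restore_feedback(net: Network, gain: float = 1.0) -> Network:
    for p in net.projections:
        if p.feedback:
            p.fb_gain = gain
    return net
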