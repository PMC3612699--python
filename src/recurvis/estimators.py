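"""scikit-learn style estimator facade over the simulator.

The trainable networks are classifiers over grayscale image stacks
(``X`` of shape (n_images, H, W), ``y`` of category labels), so they are
exposed with the standard ``fit`` / ``predict`` / ``get_params`` surface and
compose with sklearn model selection.  The semantic-pattern shaper is a
fit-only estimator whose fitted attribute is the shaped pattern set.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import InvalidInputError
from .images import AffineRanges
from .learning import (BpModel, RecurrentModel, TrainProtocol, bp_spec,
                       bp_train, build_bp_network, train)
from .network import SEMANTICS, build_network, lesion_feedback, ventral_spec
from .semantics import DistanceMatrixTarget, init_patterns, shape_patterns
from .v1 import build_filter_bank, v1_dim


def _check_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise InvalidInputError(
            f"X must be (n_images, size, size), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X contains non-finite values")
    return X


class _VisionClassifierBase(BaseEstimator, ClassifierMixin):

    def _bank(self):
        return build_filter_bank(self.n_orientations, self.n_scales,
                                 self.filter_size, self.pool_size)

    def decision_function(self, X) -> np.ndarray:
        X = _check_images(X)
        self._require_fitted()
        return np.stack([self.model_.respond(img) for img in X])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise InvalidInputError("estimator is not fitted")


class RecurrentVisualClassifier(_VisionClassifierBase):
    """Recurrent kWTA network trained by two-phase contrastive learning.

    Parameters mirror the simulator's knobs; fitted attributes are
    ``classes_``, ``model_`` (a :class:`~recurvis.learning.RecurrentModel`)
    and ``history_`` (the per-epoch training log).  Set ``feedback=False``
    to train the no-feedback comparison variant (top-down transmission
    zeroed throughout training and testing).
    """

    def __init__(self, *, n_orientations=4, n_scales=2, filter_size=7,
                 pool_size=4, kwta_pct=0.15, v1_gain=2.0,
                 v2_size=160, v2_k=40, it_size=100, it_k=20,
                 semantics_units=None, semantics_k=None,
                 epochs=30, lrate=0.03, hebb_mix=0.005,
                 minus_cycles=30, plus_cycles=30, max_cycles=60, tol=0.005,
                 fb_scale=0.35, dt=0.3, gain=60.0, feedback=True,
                 use_semantics=False, augment=True,
                 stop_at_train_acc=None, seed=0):
        self.n_orientations = n_orientations
        self.n_scales = n_scales
        self.filter_size = filter_size
        self.pool_size = pool_size
        self.kwta_pct = kwta_pct
        self.v1_gain = v1_gain
        self.v2_size = v2_size
        self.v2_k = v2_k
        self.it_size = it_size
        self.it_k = it_k
        self.semantics_units = semantics_units
        self.semantics_k = semantics_k
        self.epochs = epochs
        self.lrate = lrate
        self.hebb_mix = hebb_mix
        self.minus_cycles = minus_cycles
        self.plus_cycles = plus_cycles
        self.max_cycles = max_cycles
        self.tol = tol
        self.fb_scale = fb_scale
        self.dt = dt
        self.gain = gain
        self.feedback = feedback
        self.use_semantics = use_semantics
        self.augment = augment
        self.stop_at_train_acc = stop_at_train_acc
        self.seed = seed

    def fit(self, X, y, semantic_patterns=None):
        X = _check_images(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise InvalidInputError("X and y length mismatch")
        self.classes_ = np.unique(y)
        bank = self._bank()
        n_input = v1_dim(bank, X.shape[1])
        input_k = max(1, int(np.floor(self.kwta_pct * n_input)))
        spec = ventral_spec(n_input, len(self.classes_), input_k,
                            v2_size=self.v2_size, v2_k=self.v2_k,
                            it_size=self.it_size, it_k=self.it_k,
                            semantics_units=self.semantics_units,
                            semantics_k=self.semantics_k,
                            fb_scale=self.fb_scale, dt=self.dt, gain=self.gain)
        net = build_network(spec, seed=self.seed)
        if not self.feedback:
            net = lesion_feedback(net)
        self.model_ = RecurrentModel(
            net=net, bank=bank, categories=list(self.classes_),
            kwta_pct=self.kwta_pct, v1_gain=self.v1_gain,
            max_cycles=self.max_cycles, tol=self.tol,
            semantic_patterns=semantic_patterns)
        protocol = TrainProtocol(
            epochs=self.epochs, lrate=self.lrate, hebb_mix=self.hebb_mix,
            minus_cycles=self.minus_cycles, plus_cycles=self.plus_cycles,
            tol=self.tol, use_semantics=self.use_semantics,
            stop_at_train_acc=self.stop_at_train_acc, seed=self.seed)
        ranges = None if self.augment else AffineRanges.identity()
        self.history_ = train(self.model_, X, list(y), protocol, ranges)
        self.n_features_in_ = n_input
        return self


class BackpropVisualClassifier(_VisionClassifierBase):
    """Feedforward backpropagation comparison network (``variant`` is
    ``'sparse'`` or ``'distrib'``) over the same layer stack."""

    def __init__(self, *, variant="sparse", n_orientations=4, n_scales=2,
                 filter_size=7, pool_size=4, kwta_pct=0.15, v1_gain=2.0,
                 v2_size=160, it_size=100, epochs=30, augment=True,
                 stop_at_train_acc=None, seed=0):
        self.variant = variant
        self.n_orientations = n_orientations
        self.n_scales = n_scales
        self.filter_size = filter_size
        self.pool_size = pool_size
        self.kwta_pct = kwta_pct
        self.v1_gain = v1_gain
        self.v2_size = v2_size
        self.it_size = it_size
        self.epochs = epochs
        self.augment = augment
        self.stop_at_train_acc = stop_at_train_acc
        self.seed = seed

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        bank = self._bank()
        n_input = v1_dim(bank, X.shape[1])
        spec = bp_spec(self.variant,
                       (n_input, self.v2_size, self.it_size, len(self.classes_)))
        self.model_ = BpModel(net=build_bp_network(spec, seed=self.seed),
                              bank=bank, categories=list(self.classes_),
                              kwta_pct=self.kwta_pct, v1_gain=self.v1_gain)
        ranges = None if self.augment else AffineRanges.identity()
        self.history_ = bp_train(self.model_, X, list(y), self.epochs,
                                 ranges, seed=self.seed,
                                 stop_at_train_acc=self.stop_at_train_acc)
        self.n_features_in_ = n_input
        return self


class SemanticPatternShaper(BaseEstimator):
    """Shape sparse binary category patterns toward a target similarity
    matrix.  ``fit`` takes a :class:`DistanceMatrixTarget` (or a raw square
    similarity matrix); fitted attributes are ``patterns_``, ``trace_``,
    ``mismatch_`` and ``stalled_``."""

    def __init__(self, *, n_units=100, pct_active=0.25, max_iters=1000,
                 temperature=1.0, seed=0):
        self.n_units = n_units
        self.pct_active = pct_active
        self.max_iters = max_iters
        self.temperature = temperature
        self.seed = seed

    def fit(self, target, y=None):
        if not isinstance(target, DistanceMatrixTarget):
            m = np.asarray(target, dtype=float)
            target = DistanceMatrixTarget(
                matrix=m, labels=tuple(f"cat{i:03d}" for i in range(m.shape[0])))
        initial = init_patterns(target.n, self.n_units, self.pct_active,
                                seed=self.seed)
        shaped = shape_patterns(initial, target, max_iters=self.max_iters,
                                seed=self.seed, temperature=self.temperature)
        self.patterns_ = shaped.patterns
        self.active_count_ = shaped.active_count
        self.trace_ = shaped.fit_trace
        self.mismatch_ = shaped.fit_trace[-1]
        self.stalled_ = shaped.stalled
        return self
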