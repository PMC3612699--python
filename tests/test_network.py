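"""Recurrent network core: construction, kWTA inhibition, cycle updates,
settling, clamping and the feedback lesion."""

import numpy as np
import pytest

import recurvis as rv
from recurvis.checkpoint import load_network, save_network
from recurvis.errors import ConfigurationError
from recurvis.network import (IT, OUTPUT, SEMANTICS, V1, V2V4, LayerSpec,
                              NetworkSpec, _g_theta, settle, update_cycle,
                              ventral_spec)

SPEC_CONSTANTS = NetworkSpec(layers=(), projections=())


def small_spec(semantics=False, seed_sizes=(30, 20, 12, 4)):
    n_in, v2, it, n_out = seed_sizes
    return ventral_spec(n_in, n_out, input_k=6, v2_size=v2, v2_k=5,
                        it_size=it, it_k=3,
                        semantics_units=8 if semantics else None,
                        semantics_k=2 if semantics else None)


def equilibrium_above_threshold(g_e, g_i, spec=SPEC_CONSTANTS, cycles=3000):
    """Brute-force oracle: integrate the membrane equation for fixed
    conductances and count units ending above threshold."""
    v = np.full(g_e.shape, spec.l_rev)
    for _ in range(cycles):
        dv = (g_e * (spec.e_rev - v) + g_i * spec.g_bar_i * (spec.i_rev - v)
              + spec.g_bar_l * (spec.l_rev - v))
        v = v + 0.1 * dv
    return int(np.sum(v > spec.theta))


class TestBuild:

    def test_semantics_layer_optional(self):
        net = rv.build_network(small_spec(semantics=False), seed=0)
        assert SEMANTICS not in net.layers
        net2 = rv.build_network(small_spec(semantics=True), seed=0)
        assert SEMANTICS in net2.layers

    def test_weights_bounded_and_deterministic(self):
        a = rv.build_network(small_spec(), seed=3)
        b = rv.build_network(small_spec(), seed=3)
        for pa, pb in zip(a.projections, b.projections):
            assert np.array_equal(pa.weights, pb.weights)
            assert pa.weights.min() >= 0 and pa.weights.max() <= 1

    def test_k_larger_than_layer_rejected(self):
        with pytest.raises(ConfigurationError):
            LayerSpec("X", size=4, k=5)

    def test_hidden_layers_reciprocally_connected_v1_gets_no_feedback(self):
        spec = small_spec(semantics=True)
        pairs = {(p.sender, p.receiver) for p in spec.projections}
        for s, r in [(V2V4, IT), (IT, OUTPUT), (IT, SEMANTICS)]:
            assert (s, r) in pairs and (r, s) in pairs
        assert not any(r == V1 for _, r in pairs)


class TestKwta:

    def test_single_winner_from_graded_drives(self):
        g_e = np.array([0.9, 0.5, 0.1, 0.05])
        g_i = rv.kwta_inhibition(g_e, k=1)
        assert equilibrium_above_threshold(g_e, g_i) == 1
        # and it is the strongest unit that stays above
        gt = _g_theta(g_e, SPEC_CONSTANTS)
        assert np.argmax(gt) == 0 and gt[0] > g_i

    def test_oracle_agreement_on_random_layers(self):
        """1000 random 20-unit layers: the analytic count of units whose
        threshold conductance exceeds g_i equals min(k, excitable units),
        and a brute-force integration oracle confirms the count on a
        subsample."""
        rng = np.random.default_rng(0)
        for case in range(1000):
            g_e = rng.uniform(0, 1.2, size=20)
            k = int(rng.integers(1, 19))
            g_i = rv.kwta_inhibition(g_e, k)
            gt = _g_theta(g_e, SPEC_CONSTANTS)
            n_above = int(np.sum(gt > g_i))
            assert n_above <= k
            n_excitable = int(np.sum(gt > 0))
            assert n_above == min(k, n_excitable)
            if case % 100 == 0:
                assert equilibrium_above_threshold(g_e, g_i) == n_above

    def test_equal_drives_degenerate_tie(self):
        g_e = np.full(6, 0.5)
        g_i = rv.kwta_inhibition(g_e, k=2)
        gt = _g_theta(g_e, SPEC_CONSTANTS)
        # identical threshold conductances: the interpolated g_i equals
        # them, so the shared inhibition leaves all-or-none at equilibrium
        assert np.allclose(gt, gt[0])
        assert g_i == pytest.approx(gt[0])

    def test_k_equal_n_suppresses_nobody(self):
        g_e = np.array([0.6, 0.5, 0.4])
        g_i = rv.kwta_inhibition(g_e, k=3)
        assert equilibrium_above_threshold(g_e, g_i) == 3


class TestDynamics:

    def test_leak_only_fixed_point(self):
        spec = small_spec()
        net = rv.build_network(spec, seed=0)
        for p in net.projections:
            p.weights[:] = 0.0
        res = settle(net, {}, max_cycles=100)
        for name, st in net.layers.items():
            assert np.allclose(st.v_m, spec.l_rev, atol=1e-3)
            assert np.all(st.act < 1e-4)

    def test_activations_bounded_and_kwta_bound_every_cycle(self):
        spec = small_spec(semantics=True)
        net = rv.build_network(spec, seed=1)
        rng = np.random.default_rng(2)
        clamp = np.zeros(30)
        clamp[rng.choice(30, 6, replace=False)] = rng.uniform(0.5, 1, 6)
        ks = {ls.name: ls.k for ls in spec.layers}
        for _ in range(40):
            update_cycle(net, {V1: clamp})
            for name, st in net.layers.items():
                assert st.act.min() >= 0 and st.act.max() <= 1
                assert np.sum(st.act > 0.5) <= ks[name]
                assert np.sum(st.act > 0) <= ks[name] or name == V1

    def test_feedback_silencing_is_exact(self):
        """With fb_gain = 0 everywhere, lower-layer trajectories are
        invariant to arbitrary perturbation of higher layers."""
        spec = small_spec()
        rng = np.random.default_rng(3)
        clamp = rng.uniform(0, 1, 30) * (rng.random(30) < 0.2)
        traces = []
        for output_init in (0.0, 0.9):
            net = rv.lesion_feedback(rv.build_network(spec, seed=4))
            net.layers[OUTPUT].act[:] = output_init
            net.layers[OUTPUT].v_m[:] = 0.3 + output_init / 2
            for _ in range(20):
                update_cycle(net, {V1: clamp})
            traces.append((net.layers[V2V4].act.copy(), net.layers[IT].act.copy()))
        assert np.array_equal(traces[0][0], traces[1][0])
        assert np.array_equal(traces[0][1], traces[1][1])

    def test_settle_fixed_point_stability(self):
        spec = small_spec()
        net = rv.build_network(spec, seed=0)
        rng = np.random.default_rng(100)
        clamp = rng.uniform(0, 1, 30) * (rng.random(30) < 0.2)
        first = settle(net, {V1: clamp}, max_cycles=300, tol=0.005)
        assert first.converged
        again = settle(net, {V1: clamp}, max_cycles=60, tol=0.005)
        assert again.converged and again.cycles == 1
        for name in first.acts:
            assert np.allclose(first.acts[name], again.acts[name], atol=0.005)

    def test_nonconvergence_flagged_not_fatal(self):
        # some small random nets sustain a limit cycle; settle must report
        # that honestly instead of raising
        net = rv.build_network(small_spec(), seed=4)
        rng = np.random.default_rng(104)
        clamp = rng.uniform(0, 1, 30) * (rng.random(30) < 0.2)
        res = settle(net, {V1: clamp}, max_cycles=50, tol=0.005)
        assert res.cycles == 50
        assert isinstance(res.converged, bool)

    def test_input_renormalization_preserves_winner_set(self):
        """Halving the input activations leaves the downstream winner set
        (nearly) unchanged even though raw drive halves: the shared
        inhibition tracks the excitation level."""
        spec = small_spec()
        jaccards = []
        drive_ratios = []
        for seed in range(10):
            net = rv.build_network(spec, seed=seed)
            rng = np.random.default_rng(200 + seed)
            clamp = rng.uniform(0.4, 1, 30) * (rng.random(30) < 0.3)
            winners = []
            ge_means = []
            for scale in (1.0, 0.5):
                net.reset_state()
                settle(net, {V1: clamp * scale}, max_cycles=60)
                winners.append(frozenset(np.flatnonzero(net.layers[V2V4].act > 0)))
                ge_means.append(net.layers[V2V4].g_e.mean())
            jaccards.append(len(winners[0] & winners[1])
                            / len(winners[0] | winners[1]))
            drive_ratios.append(ge_means[1] / ge_means[0])
        assert np.mean(jaccards) >= 0.5
        assert np.mean(drive_ratios) < 0.75        # drive really did drop

    def test_lesion_and_restore_roundtrip(self):
        spec = small_spec()
        net = rv.build_network(spec, seed=9)
        rng = np.random.default_rng(10)
        clamp = rng.uniform(0, 1, 30) * (rng.random(30) < 0.2)
        ref = settle(net.copy(), {V1: clamp}, max_cycles=30).acts
        lesioned = rv.lesion_feedback(net)
        rv.restore_feedback(lesioned)
        back = settle(lesioned, {V1: clamp}, max_cycles=30).acts
        for name in ref:
            assert np.array_equal(ref[name], back[name])

    def test_checkpoint_roundtrip(self, tmp_path):
        net = rv.build_network(small_spec(semantics=True), seed=11)
        path = tmp_path / "net.h5"
        save_network(net, path)
        back = load_network(path)
        assert back.spec == net.spec
        for pa, pb in zip(net.projections, back.projections):
            assert np.array_equal(pa.weights, pb.weights)
            assert pa.feedback == pb.feedback
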