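"""Propagation, restriction accuracy, annealing and ensemble selection."""

import itertools
import math

import numpy as np
import pytest

from moanet import (
    AnnealSchedule,
    Edge,
    MoA,
    PropagationParams,
    RestrictionSet,
    SignedDirectedNetwork,
    Stimulus,
    accuracy,
    anneal,
    propagate,
    sample_ensemble,
    select_top,
)
from moanet.core import CompiledModel


class TestPropagation:
    def test_zero_weights_give_zero_signals(self, toy_instance):
        zero = {k: 0.0 for k in toy_instance.true_weights}
        signals = propagate(toy_instance.network, toy_instance.stimulus, weights=zero)
        for p, v in signals.items():
            if p in toy_instance.stimulus.states:
                assert v == toy_instance.stimulus.states[p]
            else:
                assert v == 0.0

    def test_two_step_chain_closed_form(self, chain):
        net, stim = chain
        signals = propagate(net, stim)
        assert signals["S"] == 1.0
        assert signals["A"] == pytest.approx(math.tanh(1.0), abs=1e-6)
        assert signals["B"] == pytest.approx(math.tanh(math.tanh(1.0)), abs=1e-6)

    def test_converged_state_is_a_fixed_point(self, toy_instance):
        params = PropagationParams()
        model = CompiledModel(toy_instance.network, toy_instance.stimulus, params)
        w = np.array([toy_instance.true_weights[(e.source, e.target)] for e in model.edges])
        x, converged, _ = model.propagate_array(w)
        assert converged
        # one plain synchronous update leaves the state unchanged within tol
        model._mat.data = w[model._perm]
        resync = np.tanh(model._mat @ x)
        resync[model.clamp_idx] = model.clamp_val
        assert np.max(np.abs(resync - x)) < params.convergence_tol

    def test_stimulus_stays_clamped(self, toy_instance):
        signals = propagate(
            toy_instance.network, toy_instance.stimulus, weights=toy_instance.true_weights
        )
        for p, s in toy_instance.stimulus.states.items():
            assert signals[p] == float(s)
        assert all(-1.0 <= v <= 1.0 for v in signals.values())

    def test_node_order_invariance(self, toy_instance):
        net = toy_instance.network
        rev = SignedDirectedNetwork(list(reversed(net.edges)), extra_nodes=net.nodes)
        a = propagate(net, toy_instance.stimulus)
        b = propagate(rev, toy_instance.stimulus)
        assert a == b

    def test_odd_symmetry_under_stimulus_negation(self, toy_instance):
        # tanh is odd: negating the clamped inputs negates every signal
        stim = toy_instance.stimulus
        neg = Stimulus({p: -s for p, s in stim.states.items()})
        a = propagate(toy_instance.network, stim, weights=toy_instance.true_weights)
        b = propagate(toy_instance.network, neg, weights=toy_instance.true_weights)
        for p in a:
            assert b[p] == pytest.approx(-a[p], abs=1e-5)

    def test_unreachable_nodes_are_neutral(self):
        net = SignedDirectedNetwork([Edge("S", "A", 1, 0.9)], extra_nodes=["Z"])
        signals = propagate(net, Stimulus({"S": 1}))
        assert signals["Z"] == 0.0

    def test_non_finite_weight_rejected(self, chain):
        net, stim = chain
        with pytest.raises(ValueError, match="finite"):
            propagate(net, stim, weights={("S", "A"): math.nan})


class TestAccuracy:
    def test_exact_match_is_one(self):
        r = RestrictionSet({"A": 1, "B": -1})
        assert accuracy({"A": 1.0, "B": -1.0}, r) == 1.0

    def test_all_zero_signals_score_zero(self):
        r = RestrictionSet({"A": 1, "B": -1})
        assert accuracy({"A": 0.0, "B": 0.0}, r, min_magnitude=0.05) == 0.0

    def test_hand_enumerated_toy(self):
        # 8 restrictions, 6 satisfied in sign and magnitude
        states = {f"P{i}": 1 for i in range(8)}
        signals = {f"P{i}": 0.5 for i in range(6)}
        signals["P6"] = -0.5      # wrong sign
        signals["P7"] = 0.01      # right sign, below magnitude floor
        assert accuracy(signals, RestrictionSet(states), min_magnitude=0.05) == 0.75

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            accuracy({"A": 1.0}, RestrictionSet({"B": 1}))


class TestAnneal:
    def test_deterministic_given_seed(self, toy_instance):
        short = AnnealSchedule(n_temperatures=5, steps_per_temperature=20)
        a = anneal(toy_instance.network, toy_instance.stimulus, toy_instance.restrictions,
                   schedule=short, seed=3)
        b = anneal(toy_instance.network, toy_instance.stimulus, toy_instance.restrictions,
                   schedule=short, seed=3)
        assert a.signals == b.signals and a.weights == b.weights
        assert a.accuracy == b.accuracy

    def test_degenerate_schedule_returns_initial_weights(self, toy_instance):
        sched = AnnealSchedule(n_temperatures=1, steps_per_temperature=0)
        moa, trace = anneal(
            toy_instance.network, toy_instance.stimulus, toy_instance.restrictions,
            schedule=sched, seed=5, return_trace=True,
        )
        assert trace == []  # no improvement step ran
        # reported accuracy is recomputable from the reported signals
        assert moa.accuracy == pytest.approx(
            accuracy(moa.signals, toy_instance.restrictions), abs=1e-12
        )

    def test_best_so_far_trace_non_decreasing(self, toy_instance):
        sched = AnnealSchedule(n_temperatures=4, steps_per_temperature=30)
        _, trace = anneal(
            toy_instance.network, toy_instance.stimulus, toy_instance.restrictions,
            schedule=sched, seed=2, return_trace=True,
        )
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_weights_respect_sign_intervals(self, toy_instance):
        sched = AnnealSchedule(n_temperatures=3, steps_per_temperature=30)
        moa = anneal(toy_instance.network, toy_instance.stimulus,
                     toy_instance.restrictions, schedule=sched, seed=1)
        signs = {(e.source, e.target): e.sign for e in toy_instance.network.edges}
        for pair, w in moa.weights.items():
            if signs[pair] > 0:
                assert 0.0 <= w <= 1.0
            else:
                assert -1.0 <= w <= 0.0

    def test_recovers_planted_solution(self, toy_instance):
        # noise-free instance: most seeds reach high restriction accuracy
        accs = [
            anneal(toy_instance.network, toy_instance.stimulus,
                   toy_instance.restrictions, seed=s).accuracy
            for s in range(5)
        ]
        assert np.mean(accs) > 0.8

    def test_brute_force_oracle_on_discrete_toy(self):
        # weights in {-1, 0, +1}: exhaustive enumeration vs a long anneal.
        # node U is unreachable, so its restriction is structurally
        # unsatisfiable and the optimum is 4/5.
        net = SignedDirectedNetwork(
            [Edge("S", "A", 1), Edge("A", "B", 1), Edge("S", "C", 1), Edge("C", "D", 1)],
            extra_nodes=["U"],
        )
        stim = Stimulus({"S": 1})
        restr = RestrictionSet({"A": 1, "B": -1, "C": -1, "D": 1, "U": 1})
        pairs = [(e.source, e.target) for e in net.edges]
        best = 0.0
        for combo in itertools.product([-1.0, 0.0, 1.0], repeat=len(pairs)):
            signals = propagate(net, stim, weights=dict(zip(pairs, combo)))
            best = max(best, accuracy(signals, restr))
        assert best == pytest.approx(0.8)
        moa = anneal(
            net, stim, restr,
            schedule=AnnealSchedule(n_temperatures=30, steps_per_temperature=50),
            seed=0, sign_constrained=False,
        )
        assert moa.accuracy == pytest.approx(best)


class TestEnsemble:
    def test_sample_ensemble_deterministic(self, toy_instance):
        short = AnnealSchedule(n_temperatures=3, steps_per_temperature=20)
        kw = dict(schedule=short, base_seed=100)
        a = sample_ensemble(toy_instance.network, toy_instance.stimulus,
                            toy_instance.restrictions, n_runs=4, **kw)
        b = sample_ensemble(toy_instance.network, toy_instance.stimulus,
                            toy_instance.restrictions, n_runs=4, **kw)
        assert [(m.seed, m.accuracy) for m in a] == [(m.seed, m.accuracy) for m in b]
        assert [m.signals for m in a] == [m.signals for m in b]

    def test_single_run_equals_anneal(self, toy_instance):
        short = AnnealSchedule(n_temperatures=3, steps_per_temperature=20)
        [m] = sample_ensemble(toy_instance.network, toy_instance.stimulus,
                              toy_instance.restrictions, n_runs=1,
                              schedule=short, base_seed=42)
        single = anneal(toy_instance.network, toy_instance.stimulus,
                        toy_instance.restrictions, schedule=short, seed=42)
        assert m.signals == single.signals and m.accuracy == single.accuracy

    def test_distinct_seeds_find_distinct_solutions(self):
        # two symmetric paths: either may carry the signal
        net = SignedDirectedNetwork(
            [Edge("S", "A", 1), Edge("S", "B", 1), Edge("A", "T", 1), Edge("B", "T", 1)]
        )
        stim = Stimulus({"S": 1})
        restr = RestrictionSet({"T": 1})
        short = AnnealSchedule(n_temperatures=5, steps_per_temperature=20)
        moas = sample_ensemble(net, stim, restr, n_runs=6, schedule=short, base_seed=0)
        vecs = {tuple(round(m.signals[p], 4) for p in sorted(m.signals)) for m in moas}
        assert len(vecs) >= 2

    def test_select_top_sorting_property(self):
        rng = np.random.default_rng(0)
        moas = [
            MoA(signals={}, weights={}, accuracy=float(a), seed=i)
            for i, a in enumerate(rng.uniform(0.65, 1.0, size=250))
        ]
        ens = select_top(moas, K=200, min_accuracy=0.6, allow_fewer=False)
        assert len(ens) == 200
        kept_min = min(m.accuracy for m in ens.moas)
        dropped = set(m.seed for m in moas if m.accuracy >= 0.6) - set(ens.ids())
        if dropped:
            dropped_max = max(m.accuracy for m in moas if m.seed in dropped)
            assert kept_min >= dropped_max
        accs = [m.accuracy for m in ens.moas]
        assert accs == sorted(accs, reverse=True)

    def test_select_top_errors(self):
        moas = [MoA(signals={}, weights={}, accuracy=0.5, seed=i) for i in range(10)]
        with pytest.raises(ValueError, match="min_accuracy"):
            select_top(moas, K=4, min_accuracy=0.9)
        with pytest.raises(ValueError, match=">= 4"):
            select_top(moas, K=3, min_accuracy=0.1)
        ens = select_top(moas, K=20, min_accuracy=0.1, allow_fewer=True)
        assert len(ens) == 10
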