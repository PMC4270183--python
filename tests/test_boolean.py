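import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import exhaustive_contextualize, majority_oracle
from conftest import random_signed_network
from nichegrn.errors import ContextualizationError, FormatError
from nichegrn.boolean import (BooleanState, ContextualizedNetwork, GAParams,
                              booleanize, consistency_score, contextualize,
                              contextualize_focused, is_fixed_point,
                              majority_update, simulate)
from nichegrn.io import (ACTIVATION, INHIBITION, TRANSCRIPTION, UNASSIGNED,
                         Edge, PriorNetwork)


def star(n_act, n_inh):
    """Activators A*, inhibitors I* all pointing at T."""
    edges = [Edge(f"A{i}", "T", TRANSCRIPTION, ACTIVATION) for i in range(n_act)]
    edges += [Edge(f"I{i}", "T", TRANSCRIPTION, INHIBITION) for i in range(n_inh)]
    return PriorNetwork(tuple(edges), frozenset({"T"}))


class TestBooleanize:
    def test_threshold_boundary(self):
        qe = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        st = booleanize(qe, on_threshold=3)
        assert st.values == {"a": 0, "b": 0, "c": 1, "d": 1}

    def test_missing_genes_listed(self):
        with pytest.raises(FormatError, match="ghost"):
            booleanize(pd.Series({"a": 4}), genes=["a", "ghost"])


class TestMajorityUpdate:
    def test_three_activators_beat_two_inhibitors(self):
        net = star(3, 2)
        state = BooleanState({"T": 0, **{f"A{i}": 1 for i in range(3)},
                              **{f"I{i}": 1 for i in range(2)}})
        assert majority_update(state, net).values["T"] == 1

    def test_tie_means_inhibition(self):
        net = star(2, 2)
        state = BooleanState({"T": 1, **{f"A{i}": 1 for i in range(2)},
                              **{f"I{i}": 1 for i in range(2)}})
        assert majority_update(state, net).values["T"] == 0

    def test_isolated_gene_holds(self):
        net = PriorNetwork((), frozenset({"X"}))
        assert majority_update(BooleanState({"X": 1}), net).values["X"] == 1
        assert majority_update(BooleanState({"X": 1}), net,
                               no_input="decay").values["X"] == 0

    def test_truth_table_vs_oracle_up_to_four_regulators(self):
        """Exhaustive check of the update semantics for <= 4 regulators."""
        for n_act in range(5):
            for n_inh in range(5 - n_act):
                net = star(n_act, n_inh)
                srcs = [f"A{i}" for i in range(n_act)] + \
                       [f"I{i}" for i in range(n_inh)]
                edges = [(e.source, e.target, e.sign) for e in net.edges]
                for bits in itertools.product((0, 1), repeat=len(srcs) + 1):
                    state = dict(zip(srcs + ["T"], bits))
                    got = majority_update(BooleanState(state), net).values
                    assert got == majority_oracle(state, edges)


class TestFixedPointsAndSimulation:
    def test_empty_edge_set_any_state_is_fixed(self):
        net = PriorNetwork((), frozenset({"A", "B"}))
        ok, v = is_fixed_point(BooleanState({"A": 1, "B": 0}), net)
        assert ok and v == []

    def test_single_activation_violator(self):
        net = PriorNetwork((Edge("A", "B", sign=ACTIVATION),))
        ok, v = is_fixed_point(BooleanState({"A": 1, "B": 0}), net)
        assert not ok and v == ["B"]

    def test_all_on_three_cycle_is_fixed(self):
        net = PriorNetwork(tuple(Edge(a, b, sign=ACTIVATION)
                                 for a, b in (("A", "B"), ("B", "C"), ("C", "A"))))
        ok, _ = is_fixed_point(BooleanState({"A": 1, "B": 1, "C": 1}), net)
        assert ok

    def test_start_at_fixed_point(self):
        net = PriorNetwork((Edge("A", "A", sign=ACTIVATION),))
        traj = simulate(BooleanState({"A": 1}), net, max_steps=10)
        assert traj.kind == "fixed_point" and len(traj.states) == 1

    def test_mutual_inhibition_matches_transition_graph(self):
        """Classification agrees with exhaustive enumeration of all 4 states."""
        net = PriorNetwork((Edge("A", "B", sign=INHIBITION),
                            Edge("B", "A", sign=INHIBITION)))
        edges = [(e.source, e.target, e.sign) for e in net.edges]
        for a, b in itertools.product((0, 1), repeat=2):
            start = {"A": a, "B": b}
            # brute-force trajectory on the 4-state transition graph
            seen, cur = [tuple(start.values())], dict(start)
            kind, period = None, None
            while True:
                cur = majority_oracle(cur, edges)
                key = tuple(cur.values())
                if key in seen:
                    period = len(seen) - seen.index(key)
                    kind = "fixed_point" if period == 1 else "limit_cycle"
                    break
                seen.append(key)
            traj = simulate(BooleanState(start), net, max_steps=16)
            assert (traj.kind, traj.period) == (kind, period)

    def test_trajectory_repeats_within_state_space_bound(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            net = random_signed_network(rng, 5, 8)
            start = BooleanState({n: int(rng.integers(2)) for n in net.nodes})
            traj = simulate(start, net, max_steps=2 ** 5)
            assert traj.kind in ("fixed_point", "limit_cycle")


class TestConsistencyScore:
    def test_fixed_points_score_one(self, two_cycle):
        st = BooleanState({"A": 1, "B": 1}, "on")
        rep = consistency_score(two_cycle, [st])
        assert rep.overall == 1.0 and rep.inconsistent["on"] == ()

    def test_one_forced_gene(self):
        net = PriorNetwork((Edge("A", "B", sign=INHIBITION),),
                           frozenset({"A", "B", "C"}))
        st = BooleanState({"A": 1, "B": 1, "C": 0}, "s")
        rep = consistency_score(net, [st])
        assert rep.per_state["s"] == pytest.approx(1 - 1 / 3)
        assert rep.inconsistent["s"] == ("B",)

    def test_matches_bruteforce_recount_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(25):
            net = random_signed_network(rng, 5, 7)
            states = [BooleanState({n: int(rng.integers(2)) for n in net.nodes},
                                   f"s{j}") for j in range(2)]
            rep = consistency_score(net, states)
            edges = [(e.source, e.target, e.sign) for e in net.edges]
            for j, st in enumerate(states):
                nxt = majority_oracle(st.values, edges)
                frac = sum(nxt[g] == st.values[g] for g in st.values) / len(st.values)
                assert rep.per_state[f"s{j}"] == pytest.approx(frac)


class TestContextualize:
    def test_consistent_prior_returned_unchanged(self, two_cycle):
        states = [BooleanState({"A": 1, "B": 1}, "on"),
                  BooleanState({"A": 0, "B": 0}, "off")]
        net, rep = contextualize(two_cycle, states, GAParams(seed=1, population=40,
                                                             generations=40))
        assert set(net.edges) == set(two_cycle.edges)
        assert rep.overall == 1.0 and net.removed_edges == ()

    def test_single_contradicting_edge_removed(self):
        """5-gene toy where exactly one edge breaks both states; verified
        against exhaustive enumeration of all subnetworks."""
        cyc = [Edge(a, b, sign=ACTIVATION) for a, b in
               (("A", "B"), ("B", "C"), ("C", "A"))]
        bad = Edge("D", "E", sign=ACTIVATION)  # D on, E off in both states
        prior = PriorNetwork(tuple(cyc) + (bad,))
        states = [BooleanState({"A": 1, "B": 1, "C": 1, "D": 1, "E": 0}, "s1"),
                  BooleanState({"A": 0, "B": 0, "C": 0, "D": 1, "E": 0}, "s2")]
        net, rep = contextualize(prior, states,
                                 GAParams(seed=2, population=60, generations=80))
        assert [e.key for e in net.removed_edges] == [bad.key]
        assert rep.overall == 1.0
        edges = [(e.source, e.target, e.sign) for e in prior.edges]
        best = exhaustive_contextualize(edges, [s.values for s in states])
        assert rep.overall - 0.1 * 1 / 4 == pytest.approx(best)

    def test_unassigned_sign_resolved_by_data(self):
        """Only inhibition makes the observed state a fixed point."""
        prior = PriorNetwork((Edge("A", "B", sign=UNASSIGNED),))
        states = [BooleanState({"A": 1, "B": 0}, "s")]
        net, rep = contextualize(prior, states,
                                 GAParams(seed=3, population=30, generations=30))
        assert net.edges[0].sign == INHIBITION
        assert net.assigned_signs == (("A", "B", TRANSCRIPTION),)
        assert rep.overall == 1.0 and net.removed_edges == ()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        prior = random_signed_network(rng, 6, 9, n_unassigned=2)
        states = [BooleanState({n: int(rng.integers(2)) for n in prior.nodes}, "s")]
        runs = [contextualize(prior, states, GAParams(seed=77, population=50,
                                                      generations=60))[0]
                for _ in range(2)]
        assert runs[0].edges == runs[1].edges
        assert runs[0].removed_edges == runs[1].removed_edges

    def test_restoring_removed_edges_never_helps(self):
        """Monotone feasibility: adding removed edges back cannot raise the score."""
        rng = np.random.default_rng(21)
        for trial in range(5):
            prior = random_signed_network(rng, 5, 8, n_unassigned=1)
            states = [BooleanState({n: int(rng.integers(2)) for n in prior.nodes},
                                   f"s{j}") for j in range(2)]
            net, rep = contextualize(prior, states,
                                     GAParams(seed=trial, population=60,
                                              generations=80))
            if not net.removed_edges:
                continue
            restored = ContextualizedNetwork(
                edges=net.edges + tuple(
                    e if e.sign != UNASSIGNED else
                    Edge(e.source, e.target, e.interaction, ACTIVATION)
                    for e in net.removed_edges),
                nodes=frozenset(prior.nodes))
            assert consistency_score(restored, states).overall <= rep.overall + 1e-12

    def test_invalid_params_rejected(self, two_cycle):
        with pytest.raises(ValueError):
            GAParams(seed=1, population=0)
        with pytest.raises(ValueError):
            GAParams(seed=1, generations=-1)


class TestContextualizeFocused:
    def test_already_consistent_focus_is_identity(self, two_cycle):
        states = [BooleanState({"A": 1, "B": 1}, "on")]
        net, rep = contextualize_focused(two_cycle, states, "A",
                                         GAParams(seed=1))
        assert set(net.edges) == set(two_cycle.edges) and rep.overall == 1.0

    def test_star_removal_matches_exhaustive(self):
        """Removing one incident edge fixes the focus neighborhood; the other
        (non-incident) edges pass through unchanged."""
        edges = (Edge("H", "X", sign=ACTIVATION),
                 Edge("X", "H", sign=ACTIVATION),
                 Edge("H", "Y", sign=ACTIVATION),   # breaks Y (observed OFF)
                 Edge("U", "V", sign=ACTIVATION))   # non-incident, also broken
        prior = PriorNetwork(edges)
        states = [BooleanState({"H": 1, "X": 1, "Y": 0, "U": 1, "V": 0}, "s")]
        net, rep = contextualize_focused(prior, states, "H", GAParams(seed=4))
        removed = {e.key for e in net.removed_edges}
        assert removed == {("H", "Y", TRANSCRIPTION)}
        assert ("U", "V", TRANSCRIPTION) in {e.key for e in net.edges}
        assert rep.inconsistent["s"] == ("V",)  # outside the neighborhood

    def test_infeasible_neighborhood_reports_error(self):
        # V is a first neighbor of the focus gene H, but V is broken by a
        # fixed non-incident edge (U ON forces V ON while V is observed OFF),
        # so no subset/sign choice of H's incident edges can fix the
        # neighborhood.
        prior = PriorNetwork((Edge("H", "V", sign=ACTIVATION),
                              Edge("U", "V", sign=ACTIVATION)))
        states = [BooleanState({"H": 0, "U": 1, "V": 0}, "s")]
        with pytest.raises(ContextualizationError, match="neighborhood") as exc:
            contextualize_focused(prior, states, "H", GAParams(seed=5))
        assert exc.value.report is not None

    def test_outside_unassigned_rejected(self):
        prior = PriorNetwork((Edge("A", "B", sign=ACTIVATION),
                              Edge("C", "D", sign=UNASSIGNED)))
        states = [BooleanState({"A": 1, "B": 1, "C": 0, "D": 0}, "s")]
        with pytest.raises(FormatError, match="unassigned"):
            contextualize_focused(prior, states, "A", GAParams(seed=6))
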