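"""Linear-framework engine: rate evaluation, cycle condition, steady states."""

import numpy as np
import pytest

from txduality.graphs import (
    Edge,
    GraphStructureError,
    RateDomainError,
    RateGraph,
    check_cycle_condition,
    evaluate_rate_matrix,
    laplacian,
    random_detailed_balance_graph,
    random_strongly_connected_graph,
    steady_state_equilibrium,
    steady_state_oracle,
    steady_state_spanning_tree,
    steady_state_sweep,
)
from txduality.recruitment import build_recruitment_graph, incoherent_reference_params

from conftest import relative_deviation


def two_state(a=1.0, b=1.0, a_coeff=0.0):
    return RateGraph(("1", "2"), (Edge("1", "2", a, a_coeff), Edge("2", "1", b, 0.0)))


def three_cycle(rate=1.0):
    edges = []
    for u, v in (("1", "2"), ("2", "3"), ("3", "1")):
        edges.append(Edge(u, v, rate, 0.0))
        edges.append(Edge(v, u, rate, 0.0))
    return RateGraph(("1", "2", "3"), tuple(edges))


class TestStructure:
    def test_duplicate_edge_rejected(self):
        with pytest.raises(GraphStructureError):
            RateGraph(("1", "2"), (Edge("1", "2", 1.0), Edge("1", "2", 2.0)))

    def test_unknown_vertex_rejected(self):
        with pytest.raises(GraphStructureError):
            RateGraph(("1",), (Edge("1", "9", 1.0),))

    def test_strong_connectivity_reported(self):
        g = RateGraph(("1", "2", "3"), (Edge("1", "2", 1.0), Edge("2", "1", 1.0), Edge("2", "3", 1.0)))
        with pytest.raises(GraphStructureError, match="3"):
            g.require_strongly_connected()

    def test_json_round_trip(self, rng):
        g = random_strongly_connected_graph(rng, 5)
        g2 = RateGraph.from_json(g.to_json())
        assert g2 == RateGraph(g.vertices, g.edges, dict(g.transcription_weights))


class TestRateEvaluation:
    def test_affine_evaluation(self):
        g = two_state(a=0.0, a_coeff=0.01)
        m = evaluate_rate_matrix(g, 5.0)
        assert m[0, 1] == pytest.approx(0.05)

    def test_binding_edges_vanish_at_zero_concentration(self):
        g = build_recruitment_graph(incoherent_reference_params())
        m = evaluate_rate_matrix(g, 0.0)
        # TF binding 1->2 and 3->4 carry only the concentration term
        assert m[0, 1] == 0.0 and m[2, 3] == 0.0
        assert m[0, 2] == pytest.approx(0.01)  # Pol binding unaffected

    def test_reference_parameters_at_x10(self):
        # printed incoherent set: aT = aT_p = 0.01 /nM/s, so binding rates
        # are 0.1 /s at 10 nM while Pol edges stay fixed
        g = build_recruitment_graph(incoherent_reference_params(bT=0.1))
        m = evaluate_rate_matrix(g, 10.0)
        assert m[0, 1] == pytest.approx(0.1)
        assert m[2, 3] == pytest.approx(0.1)
        assert m[1, 3] == pytest.approx(0.1)  # ap_T
        assert m[2, 0] == pytest.approx(0.1)  # bp

    def test_negative_rate_rejected(self):
        g = RateGraph(("1", "2"), (Edge("1", "2", 1.0, -1.0), Edge("2", "1", 1.0)))
        with pytest.raises(RateDomainError, match="1->2"):
            evaluate_rate_matrix(g, 2.0)


class TestCycleCondition:
    def test_balanced_by_construction(self, rng):
        g = random_detailed_balance_graph(rng, 6)
        assert check_cycle_condition(g, 0.0).holds

    def test_reference_nonequilibrium_set_violates(self):
        # the printed incoherent set models a nonequilibrium steady state
        g = build_recruitment_graph(incoherent_reference_params(bT=0.1))
        report = check_cycle_condition(g, 1.0)
        assert not report.holds
        (cycle, fwd, back) = report.cycles[0]
        assert fwd != pytest.approx(back)

    def test_irreversible_edge_reported(self):
        g = RateGraph(
            ("1", "2", "3"),
            (Edge("1", "2", 1.0), Edge("2", "1", 1.0), Edge("2", "3", 1.0), Edge("3", "1", 1.0), Edge("1", "3", 1.0)),
        )
        report = check_cycle_condition(g, 0.0)
        assert not report.holds
        assert ("2", "3") in report.missing_reverse


class TestEquilibriumSolver:
    def test_symmetric_two_state(self):
        ss = steady_state_equilibrium(two_state(1.0, 1.0), 0.0)
        assert ss.probabilities["1"] == pytest.approx(0.5)

    def test_matches_spanning_tree_on_balanced_graphs(self, rng):
        for _ in range(25):
            g = random_detailed_balance_graph(rng, int(rng.integers(3, 7)))
            eq = steady_state_equilibrium(g, 0.0).as_array(g.vertices)
            st = steady_state_spanning_tree(g, 0.0).as_array(g.vertices)
            assert np.max(np.abs(eq - st)) < 1e-9

    def test_refuses_nonequilibrium_graph(self):
        g = build_recruitment_graph(incoherent_reference_params(bT=0.1))
        with pytest.raises(ValueError, match="spanning_tree"):
            steady_state_equilibrium(g, 1.0)


class TestSpanningTreeSolver:
    def test_uniform_on_symmetric_cycle(self):
        ss = steady_state_spanning_tree(three_cycle(), 0.0)
        assert all(p == pytest.approx(1 / 3) for p in ss.probabilities.values())

    def test_rho_normalization(self):
        ss = steady_state_spanning_tree(three_cycle(2.0), 0.0)
        total = sum(ss.rho.values())
        for v, p in ss.probabilities.items():
            assert p == pytest.approx(ss.rho[v] / total)

    def test_agrees_with_ode_oracle_on_reference_graph(self):
        g = build_recruitment_graph(incoherent_reference_params(bT=0.1))
        st = steady_state_spanning_tree(g, 10.0).as_array(g.vertices)
        od = steady_state_oracle(g, 10.0, "ode").as_array(g.vertices)
        assert np.max(np.abs(st - od)) < 1e-8

    def test_high_precision_backend_matches_doubles(self, rng):
        g = random_strongly_connected_graph(rng, 6)
        a = steady_state_spanning_tree(g, 0.0).as_array(g.vertices)
        b = steady_state_spanning_tree(g, 0.0, precision=100).as_array(g.vertices)
        assert relative_deviation(a, b) < 1e-12

    def test_scale_invariance(self, rng):
        g = random_strongly_connected_graph(rng, 5)
        scaled = RateGraph(
            g.vertices,
            tuple(Edge(e.source, e.target, 7.5 * e.rate, 7.5 * e.x_coeff) for e in g.edges),
        )
        a = steady_state_spanning_tree(g, 0.0).as_array(g.vertices)
        b = steady_state_spanning_tree(scaled, 0.0).as_array(g.vertices)
        assert np.max(np.abs(a - b)) < 1e-13

    def test_sweep_matches_scalar(self):
        g = build_recruitment_graph(incoherent_reference_params(bT=0.5))
        xs = np.array([0.0, 0.3, 2.0, 40.0])
        sweep = steady_state_sweep(g, xs)
        for i, x in enumerate(xs):
            scalar = steady_state_spanning_tree(g, float(x)).as_array(g.vertices)
            assert np.max(np.abs(sweep[i] - scalar)) < 1e-12


class TestOracles:
    def test_two_state_birth_death_balance(self):
        ss = steady_state_oracle(two_state(3.0, 1.0), 0.0, "nullspace")
        assert ss.probabilities["2"] == pytest.approx(3.0 / 4.0)
        ss = steady_state_oracle(two_state(3.0, 1.0), 0.0, "ode")
        assert ss.probabilities["2"] == pytest.approx(3.0 / 4.0, rel=1e-8)

    def test_uniform_on_symmetric_cycle(self):
        for method in ("nullspace", "ode"):
            ss = steady_state_oracle(three_cycle(), 0.0, method)
            assert all(p == pytest.approx(1 / 3) for p in ss.probabilities.values())

    @pytest.mark.parametrize("method", ["nullspace", "ode"])
    def test_normalization_and_agreement(self, rng, method):
        # the double-precision ODE path resolves tiny stationary
        # probabilities only to its absolute error floor, so the ODE leg
        # runs through the extended-precision propagator
        kwargs = {"precision": 30} if method == "ode" else {}
        for _ in range(20):
            g = random_strongly_connected_graph(rng, int(rng.integers(3, 9)))
            st = steady_state_spanning_tree(g, 0.0).as_array(g.vertices)
            orc = steady_state_oracle(g, 0.0, method, **kwargs).as_array(g.vertices)
            assert abs(orc.sum() - 1.0) < 1e-10
            assert relative_deviation(st, orc, floor=1e-9) < 1e-6
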