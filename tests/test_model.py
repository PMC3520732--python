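"""License-allocation model: eligibility, conflict graph, solvers, verification."""

import numpy as np
import pytest

from conftest import (
    brute_max_weight_independent_set,
    graph_from_edges,
    random_geometric_graph,
    square_block,
)
from outletplan import (
    City,
    ConflictGraph,
    Facility,
    ModelConfig,
    Outlet,
    Parcel,
    Rule,
    Solution,
    SolutionStatus,
    SolverKind,
    ValidationError,
    build_conflict_graph,
    eligible_parcels,
    generate_city,
    solve,
    solve_exact,
    solve_greedy,
    verify_solution,
)
from outletplan.synth import SynthConfig


def _city(parcels, facilities=()):
    return City(parcels=list(parcels), facilities=list(facilities))


def _commercial(pid, x, y, benefit=1.0):
    return Parcel(id=pid, x=float(x), y=float(y), land_use="commercial",
                  benefit=benefit)


class TestEligibility:
    def test_commercial_parcel_too_close_to_church_excluded(self):
        city = _city([_commercial("p1", 0, 0)],
                     [Facility(id="f1", x=250.0, y=0.0, kind="church")])
        assert eligible_parcels(city, ModelConfig()) == []

    def test_exactly_300_ft_included(self):
        city = _city([_commercial("p1", 0, 0)],
                     [Facility(id="f1", x=300.0, y=0.0, kind="school")])
        assert eligible_parcels(city, ModelConfig()) == ["p1"]

    def test_residential_parcel_never_eligible(self):
        city = _city([Parcel(id="p1", x=0.0, y=0.0, land_use="residential")])
        assert eligible_parcels(city, ModelConfig()) == []

    def test_unprotected_kind_ignored(self):
        city = _city([_commercial("p1", 0, 0)],
                     [Facility(id="f1", x=100.0, y=0.0, kind="park")])
        cfg = ModelConfig(facility_kinds=frozenset({"school", "church"}))
        assert eligible_parcels(city, cfg) == ["p1"]


class TestConflictGraph:
    def test_small_line_graph(self):
        city = _city([_commercial("a", 0, 0), _commercial("b", 150, 0),
                      _commercial("c", 400, 0)])
        g = build_conflict_graph(city, ["a", "b", "c"], ModelConfig())
        assert g.adjacency == {"a": {"b"}, "b": {"a"}, "c": set()}

    def test_exact_gamma_distance_is_no_edge(self):
        city = _city([_commercial("a", 0, 0), _commercial("b", 200, 0)])
        g = build_conflict_graph(city, ["a", "b"], ModelConfig())
        assert g.n_edges == 0

    def test_empty_eligible_list(self):
        g = build_conflict_graph(_city([]), [], ModelConfig())
        assert g.nodes == [] and g.n_edges == 0

    def test_symmetry_validation(self):
        with pytest.raises(ValidationError):
            ConflictGraph(nodes=["a", "b"], adjacency={"a": {"b"}, "b": set()},
                          benefits={"a": 1.0, "b": 1.0})


class TestExactSolver:
    def test_triangle_objective_one(self):
        g = graph_from_edges([1, 1, 1], {(0, 1), (1, 2), (0, 2)})
        sol = solve_exact(g)
        assert sol.objective == 1.0 and sol.status is SolutionStatus.OPTIMAL

    def test_five_cycle_objective_two(self):
        g = graph_from_edges([1] * 5, {(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)})
        assert solve_exact(g).objective == 2.0

    def test_weighted_path_prefers_heavy_middle(self):
        g = graph_from_edges([1, 5, 1], {(0, 1), (1, 2)})
        sol = solve_exact(g)
        assert sol.selected == {"n01"} and sol.objective == 5.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        weights, edges = random_geometric_graph(
            rng, n, radius=float(rng.uniform(150, 500)),
            unit_weights=bool(rng.integers(2)))
        want_w, _ = brute_max_weight_independent_set(weights, edges)
        g = graph_from_edges(weights, edges)
        sol = solve_exact(g)
        assert sol.objective == pytest.approx(want_w)
        # witness is independent with matching recomputed weight
        for a in sol.selected:
            assert not (g.adjacency[a] & sol.selected)
        assert sum(g.benefits[v] for v in sol.selected) == pytest.approx(sol.objective)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        weights, edges = random_geometric_graph(rng, 14, 300, unit_weights=False)
        g = graph_from_edges(weights, edges)
        assert solve_exact(g).selected == solve_exact(g).selected


class TestGreedySolver:
    def test_edgeless_graph_selects_everything(self):
        g = graph_from_edges([1] * 7, set())
        sol = solve_greedy(g)
        assert sol.objective == 7.0
        assert sol.status is SolutionStatus.FEASIBLE_HEURISTIC

    def test_triangle(self):
        g = graph_from_edges([1, 1, 1], {(0, 1), (1, 2), (0, 2)})
        assert solve_greedy(g).objective == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_greedy_at_most_exact_and_maximal(self, seed):
        rng = np.random.default_rng(100 + seed)
        weights, edges = random_geometric_graph(
            rng, int(rng.integers(5, 16)), float(rng.uniform(150, 450)),
            unit_weights=bool(rng.integers(2)))
        g = graph_from_edges(weights, edges)
        greedy = solve_greedy(g)
        exact = solve_exact(g)
        assert greedy.objective <= exact.objective + 1e-9
        # maximality: no excluded node can be added
        for v in g.nodes:
            if v not in greedy.selected:
                assert g.adjacency[v] & greedy.selected


class TestSolvePipeline:
    def test_no_eligible_parcels_empty_solution(self):
        city = _city([Parcel(id="p", x=0.0, y=0.0, land_use="residential")])
        sol = solve(city, ModelConfig())
        assert sol.selected == set() and sol.objective == 0.0

    def test_grandfathered_parcel_blocks_neighbors(self):
        parcels = [_commercial("g", 0, 0), _commercial("a", 100, 0),
                   _commercial("b", 0, 150), _commercial("c", 120, 120),
                   _commercial("far", 1000, 1000)]
        cfg = ModelConfig(grandfathered_parcel_ids=frozenset({"g"}))
        sol = solve(_city(parcels), cfg)
        assert "g" in sol.selected
        assert sol.selected.isdisjoint({"a", "b", "c"})
        assert "far" in sol.selected

    def test_conflicting_grandfathered_parcels_both_kept_with_warning(self):
        parcels = [_commercial("g1", 0, 0), _commercial("g2", 50, 0)]
        cfg = ModelConfig(grandfathered_parcel_ids=frozenset({"g1", "g2"}))
        sol = solve(_city(parcels), cfg)
        assert {"g1", "g2"} <= sol.selected
        assert sol.solver_log["warnings"]

    def test_solution_dominates_observed_compliant_pattern(self):
        # the generator's compliant outlets are a feasible allocation, so the
        # optimizer over all commercial parcels placed at those points must
        # reach at least that count
        cfg = SynthConfig(n_parcels=50, n_outlets=40, n_violating_outlets=0,
                          facility_counts={}, extent_ft=(8000.0, 8000.0),
                          n_blocks=(2, 2), population_total=1000, seed=8)
        city, _ = generate_city(cfg)
        parcels = list(city.parcels) + [
            _commercial(f"q{o.id}", o.x, o.y) for o in city.outlets]
        augmented = City(parcels=parcels, outlets=city.outlets,
                         facilities=city.facilities, blocks=city.blocks)
        sol = solve(augmented, ModelConfig(solver=SolverKind.GREEDY))
        assert len(sol.selected) >= len(city.outlets)


class TestVerification:
    def test_hand_built_infeasible_selection_flagged(self):
        city = _city([_commercial("a", 0, 0), _commercial("b", 100, 0)])
        bad = Solution(selected={"a", "b"}, objective=2.0,
                       status=SolutionStatus.FEASIBLE_HEURISTIC)
        report = verify_solution(city, bad, ModelConfig())
        assert [r.rule for r in report.ledger] == [Rule.OUTLET_SEPARATION]

    @pytest.mark.parametrize("solver", [SolverKind.EXACT, SolverKind.GREEDY])
    def test_solver_outputs_always_verify_clean(self, solver):
        for seed in range(8):
            cfg = SynthConfig(n_parcels=300, n_outlets=20,
                              facility_counts={"school": 6, "church": 12},
                              extent_ft=(10_000.0, 10_000.0), n_blocks=(2, 2),
                              population_total=5000, seed=seed)
            city, _ = generate_city(cfg)
            sol = solve(city, ModelConfig(solver=solver))
            report = verify_solution(city, sol, ModelConfig())
            assert report.ledger == []
            assert report.variance_fraction in (0.0, None)
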