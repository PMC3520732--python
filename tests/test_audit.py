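"""Compliance audit engine: distances, pair searches, ledgers, statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_cross_pairs, brute_pairs, square_block
from outletplan import (
    City,
    Facility,
    InsufficientDataError,
    Outlet,
    Rule,
    audit_facility_buffer,
    audit_outlet_separation,
    density_stats,
    euclidean_distance,
    fixed_radius_pairs,
    mean_nearest_neighbor,
    quota_allocation,
    run_audit,
    variance_set,
)

coord = st.floats(min_value=-50_000, max_value=50_000, allow_nan=False)
points_strategy = st.lists(st.tuples(coord, coord), min_size=0, max_size=40)


def _outlets(pts):
    return [Outlet(id=f"o{i}", x=float(x), y=float(y), license_type="club")
            for i, (x, y) in enumerate(pts)]


class TestDistanceKernels:
    @pytest.mark.parametrize("p,q,d", [
        ((0, 0), (3, 4), 5.0),
        ((2, 2), (2, 2), 0.0),
        ((0, 0), (150, 0), 150.0),
    ])
    def test_euclidean_distance(self, p, q, d):
        assert euclidean_distance(p, q) == d
        assert euclidean_distance(q, p) == d

    def test_fixed_radius_pairs_small_example(self):
        # distances: 150, 400, 250 -> only the first pair is under 200
        assert fixed_radius_pairs([(0, 0), (150, 0), (400, 0)], 200) == {(0, 1)}

    def test_single_point_no_pairs(self):
        assert fixed_radius_pairs([(5, 5)], 100) == set()

    def test_exact_threshold_is_compliant(self):
        # "at least 300 feet" is satisfied at exactly 300: strict inequality
        assert fixed_radius_pairs([(0, 0), (300, 0)], 300) == set()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(points_strategy, st.floats(min_value=1, max_value=5000))
    def test_index_equals_brute_force(self, pts, radius):
        assert fixed_radius_pairs(pts, radius) == brute_pairs(pts, radius)


class TestSeparationAudit:
    def test_three_close_outlets_three_pairs(self):
        records = audit_outlet_separation(_outlets([(0, 0), (100, 0), (190, 0)]), 200)
        got = {(r.subject_outlet_id, r.counterpart_id, r.distance_ft) for r in records}
        assert got == {("o0", "o1", 100.0), ("o1", "o2", 90.0), ("o0", "o2", 190.0)}
        distinct = {r.subject_outlet_id for r in records} | {r.counterpart_id for r in records}
        assert len(distinct) == 3

    def test_all_records_below_threshold(self):
        rng = np.random.default_rng(5)
        outlets = _outlets(rng.uniform(0, 2000, size=(60, 2)))
        for r in audit_outlet_separation(outlets, 200):
            assert r.distance_ft < 200
            assert r.rule is Rule.OUTLET_SEPARATION
            assert r.subject_outlet_id != r.counterpart_id


class TestFacilityBufferAudit:
    def test_single_church_violation(self):
        outlets = _outlets([(0, 0)])
        facilities = [Facility(id="c", x=250.0, y=0.0, kind="church"),
                      Facility(id="s", x=600.0, y=0.0, kind="school")]
        records = audit_facility_buffer(outlets, facilities, 300)
        assert len(records) == 1
        assert (records[0].counterpart_id, records[0].counterpart_kind,
                records[0].distance_ft) == ("c", "church", 250.0)

    def test_exactly_300_ft_school_is_compliant(self):
        outlets = _outlets([(0, 0)])
        facilities = [Facility(id="s", x=300.0, y=0.0, kind="school")]
        assert audit_facility_buffer(outlets, facilities, 300) == []

    def test_kind_filter_excludes_unprotected_kinds(self):
        outlets = _outlets([(0, 0)])
        facilities = [Facility(id="p", x=100.0, y=0.0, kind="park")]
        assert audit_facility_buffer(outlets, facilities, 300, kinds=["school"]) == []
        assert len(audit_facility_buffer(outlets, facilities, 300)) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(points_strategy, points_strategy)
    def test_cross_pairs_equal_brute_force(self, opts, fpts):
        outlets = _outlets(opts)
        facilities = [Facility(id=f"f{j}", x=float(x), y=float(y), kind="church")
                      for j, (x, y) in enumerate(fpts)]
        got = {(r.subject_outlet_id, r.counterpart_id)
               for r in audit_facility_buffer(outlets, facilities, 300)}
        want = {(f"o{i}", f"f{j}") for i, j in brute_cross_pairs(opts, fpts, 300)}
        assert got == want


class TestVarianceSet:
    def test_union_and_fraction(self):
        sep = audit_outlet_separation(_outlets([(0, 0), (50, 0)]), 200)  # o0, o1
        facilities = [Facility(id="c", x=0.0, y=100.0, kind="church")]
        buf = audit_facility_buffer(
            _outlets([(0, 0), (50, 0), (9999, 0), (0, 150)]), facilities, 300)
        ids, frac = variance_set(sep, buf, n_outlets=5)
        assert ids == {"o0", "o1", "o3"}
        assert frac == pytest.approx(0.6)

    def test_empty_ledgers(self):
        ids, frac = variance_set([], [], 10)
        assert ids == set() and frac == 0.0

    def test_zero_outlets_undefined(self):
        with pytest.raises(InsufficientDataError):
            variance_set([], [], 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_inclusion_exclusion_identity_on_random_audits(self, seed):
        # |variance set| = |near outlet| + |near facility| − |overlap|, exactly
        rng = np.random.default_rng(seed)
        outlets = _outlets(rng.uniform(0, 3000, size=(40, 2)))
        facilities = [Facility(id=f"f{j}", x=float(x), y=float(y), kind="school")
                      for j, (x, y) in enumerate(rng.uniform(0, 3000, size=(15, 2)))]
        sep = audit_outlet_separation(outlets, 200)
        buf = audit_facility_buffer(outlets, facilities, 300)
        ids, _ = variance_set(sep, buf, len(outlets))
        a = {r.subject_outlet_id for r in sep} | {r.counterpart_id for r in sep}
        b = {r.subject_outlet_id for r in buf}
        assert len(ids) == len(a) + len(b) - len(a & b)


class TestNearestNeighbor:
    def test_three_point_line(self):
        # neighbors: 300, 300, 700 -> mean 433.33...
        got = mean_nearest_neighbor([(0, 0), (300, 0), (1000, 0)])
        assert got == pytest.approx(1300 / 3)

    def test_two_points(self):
        assert mean_nearest_neighbor([(0, 0), (0, 123.5)]) == pytest.approx(123.5)

    def test_duplicate_point_zero(self):
        assert mean_nearest_neighbor([(7, 7), (7, 7)]) == 0.0

    def test_fewer_than_two_points_error(self):
        with pytest.raises(InsufficientDataError):
            mean_nearest_neighbor([(0, 0)])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(coord, coord), min_size=2, max_size=25),
           st.floats(-1e4, 1e4), st.floats(-1e4, 1e4),
           st.floats(0, 2 * math.pi), st.floats(0.1, 10))
    def test_rigid_motion_invariance_and_scaling(self, pts, dx, dy, theta, scale):
        base = mean_nearest_neighbor(pts)
        c, s = math.cos(theta), math.sin(theta)
        moved = [(c * x - s * y + dx, s * x + c * y + dy) for x, y in pts]
        assert mean_nearest_neighbor(moved) == pytest.approx(base, rel=1e-8, abs=1e-7)
        scaled = [(scale * x, scale * y) for x, y in pts]
        assert mean_nearest_neighbor(scaled) == pytest.approx(
            scale * base, rel=1e-8, abs=1e-7)


class TestDensityAndQuota:
    def test_citywide_densities(self):
        blocks = [square_block("b1", 0, 0, 2640.0, roadway_ft=30_000),
                  square_block("b2", 2640.0, 0, 2640.0, roadway_ft=20_000)]
        # each block is a quarter square mile
        outlets = _outlets([(100 + 50 * i, 100) for i in range(10)])
        per_sqmi, per_kft, counts, _ = density_stats(outlets, blocks)
        assert per_sqmi == pytest.approx(20.0)
        assert per_kft == pytest.approx(0.2)
        assert sum(counts.values()) == 10

    def test_boundary_point_goes_to_lowest_block_id(self):
        blocks = [square_block("b1", 0, 0, 1000.0), square_block("b2", 1000.0, 0, 1000.0)]
        outlets = _outlets([(1000.0, 500.0)])  # exactly on the shared edge
        _, _, counts, _ = density_stats(outlets, blocks)
        assert counts == {"b1": 1, "b2": 0}

    def test_zero_roadway_reports_absent_density(self):
        blocks = [square_block("b1", 0, 0, 1000.0, roadway_ft=0.0)]
        _, per_kft, _, _ = density_stats(_outlets([(10, 10)]), blocks)
        assert per_kft is None

    @pytest.mark.parametrize("population,per,expected", [
        (1_500_000, 3_000, 500),
        (2_999, 3_000, 0),
        (1_526_006, 3_000, 508),
        (1_526_006, 30_000, 50),
    ])
    def test_quota_allocation(self, population, per, expected):
        assert quota_allocation(population, per) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000_000), st.integers(1, 50_000))
    def test_quota_recurrence_and_monotonicity(self, population, per):
        q = quota_allocation(population, per)
        assert quota_allocation(population + per, per) == q + 1
        assert quota_allocation(population + 1, per) >= q


class TestRunAudit:
    def test_report_assembles_consistently(self, tiny_city):
        report = run_audit(tiny_city)
        # o1-o2 are 100 ft apart; o2 is 150 ft from church f1; o1 is 250 ft from f1
        assert report.n_outlet_pairs_violating == 1
        assert report.n_outlets_near_outlet == 2
        assert {r.counterpart_id for r in report.ledger
                if r.rule is Rule.FACILITY_BUFFER} == {"f1"}
        assert report.variance_outlets == {"o1", "o2"}
        assert report.variance_fraction == pytest.approx(2 / 3)
        assert report.facilities_near_outlet == {"church": 1}
        assert report.quota["retail"] == 0  # 1000 residents
        assert sum(report.per_block_counts.values()) == 3  # o3 is outside b1? no: inside
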