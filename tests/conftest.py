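"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's spatial indexes and
solvers: pair searches are O(n^2) scans and the independent-set oracle is
full subset enumeration, so they can adjudicate the optimized paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from outletplan import (
    Block,
    City,
    ConflictGraph,
    Facility,
    Outlet,
    Parcel,
    SynthConfig,
)


def brute_pairs(points, radius: float) -> set[tuple[int, int]]:
    """All unordered index pairs at strict distance < radius, by full scan."""
    pts = [(float(x), float(y)) for x, y in points]
    out = set()
    for i, j in itertools.combinations(range(len(pts)), 2):
        if math.dist(pts[i], pts[j]) < radius:
            out.add((i, j))
    return out


def brute_cross_pairs(a, b, radius: float) -> set[tuple[int, int]]:
    return {
        (i, j)
        for i, p in enumerate(a)
        for j, q in enumerate(b)
        if math.dist((p[0], p[1]), (q[0], q[1])) < radius
    }


def brute_max_weight_independent_set(
    weights: list[float], edges: set[tuple[int, int]]
) -> tuple[float, set[int]]:
    """Exhaustive subset enumeration (first-found witness of maximum weight).

    Uses the lowest-bit recurrence: S is independent iff S minus its lowest
    bit is independent and that vertex has no neighbor in the remainder.
    Still enumerates all 2^n subsets.
    """
    n = len(weights)
    adj = [0] * n
    for i, j in edges:
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    indep = np.zeros(1 << n, dtype=bool)
    wsum = np.zeros(1 << n, dtype=float)
    indep[0] = True
    best_w, best_s = 0.0, 0
    for s in range(1, 1 << n):
        low = s & -s
        v = low.bit_length() - 1
        rest = s ^ low
        if indep[rest] and not (adj[v] & rest):
            indep[s] = True
            wsum[s] = wsum[rest] + weights[v]
            if wsum[s] > best_w:
                best_w, best_s = float(wsum[s]), s
    return best_w, {v for v in range(n) if best_s & (1 << v)}


def graph_from_edges(weights: list[float], edges: set[tuple[int, int]]) -> ConflictGraph:
    nodes = [f"n{i:02d}" for i in range(len(weights))]
    adjacency = {v: set() for v in nodes}
    for i, j in edges:
        adjacency[nodes[i]].add(nodes[j])
        adjacency[nodes[j]].add(nodes[i])
    return ConflictGraph(nodes=nodes, adjacency=adjacency,
                         benefits=dict(zip(nodes, map(float, weights))))


def random_geometric_graph(rng: np.random.Generator, n: int, radius: float,
                           extent: float = 1000.0, unit_weights: bool = True):
    pts = rng.uniform(0, extent, size=(n, 2))
    edges = brute_pairs(pts, radius)
    weights = [1.0] * n if unit_weights else list(rng.uniform(0.5, 3.0, n))
    return weights, edges


def random_er_graph(rng: np.random.Generator, n: int, p: float,
                    unit_weights: bool = True):
    edges = {(i, j) for i, j in itertools.combinations(range(n), 2)
             if rng.uniform() < p}
    weights = [1.0] * n if unit_weights else list(rng.uniform(0.5, 3.0, n))
    return weights, edges


def square_block(bid: str, x0: float, y0: float, side: float,
                 roadway_ft: float = 10_000.0, population: int = 1000) -> Block:
    return Block(
        id=bid,
        boundary=[(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
        land_area_sqmi=side * side / 5280.0 ** 2,
        roadway_ft=roadway_ft,
        population=population,
    )


@pytest.fixture
def tiny_city() -> City:
    """2 parcels, 3 outlets, 2 facilities, 1 block — hand-checkable."""
    return City(
        parcels=[
            Parcel(id="p1", x=500.0, y=500.0, land_use="commercial", block_id="b1"),
            Parcel(id="p2", x=2500.0, y=500.0, land_use="residential", block_id="b1"),
        ],
        outlets=[
            Outlet(id="o1", x=1000.0, y=1000.0, license_type="restaurant_bar"),
            Outlet(id="o2", x=1100.0, y=1000.0, license_type="club"),
            Outlet(id="o3", x=4000.0, y=4000.0, license_type="distributor"),
        ],
        facilities=[
            Facility(id="f1", x=1250.0, y=1000.0, kind="church"),
            Facility(id="f2", x=4900.0, y=4000.0, kind="school"),
        ],
        blocks=[square_block("b1", 0.0, 0.0, 5280.0)],
    )


@pytest.fixture
def small_synth_config() -> SynthConfig:
    return SynthConfig(
        extent_ft=(20_000.0, 20_000.0),
        n_blocks=(4, 4),
        n_parcels=800,
        n_outlets=80,
        facility_counts={"school": 8, "church": 30, "hospital": 2,
                         "park": 3, "playground": 3},
        n_violating_outlets=8,
        population_total=60_000,
        seed=11,
    )
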