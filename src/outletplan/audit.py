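"""Ordinance-compliance auditing and descriptive spatial statistics.

Pennsylvania's dispersion rules say a licensed premise may not sit within
200 ft of another licensed site and must be at least 300 ft from schools,
churches, hospitals, parks and playgrounds.  The audit flags every strict
violation (d < threshold; a pair at exactly the threshold complies, since
"at least 300 feet" is satisfied at 300), assembles the variance set —
the distinct outlets that would need an exception under either rule — and
computes nearest-neighbor, density, per-block and quota statistics.

All pair searches go through a k-d tree but are contractually equal to the
exhaustive O(n^2) scan; the index is an optimization, never a semantics
change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.strtree import STRtree

from .city import Block, City, Facility, FacilityKind, Outlet, coords
from .errors import InsufficientDataError, ValidationError

DEFAULT_OUTLET_SEPARATION_FT = 200.0
DEFAULT_FACILITY_BUFFER_FT = 300.0
RETAIL_QUOTA_PER_RESIDENTS = 3_000
WHOLESALE_QUOTA_PER_RESIDENTS = 30_000

ALL_FACILITY_KINDS = frozenset(FacilityKind)


class Rule(str, Enum):
    OUTLET_SEPARATION = "outlet_separation"
    FACILITY_BUFFER = "facility_buffer"


@dataclass(frozen=True)
class ViolationRecord:
    rule: Rule
    subject_outlet_id: str
    counterpart_id: str
    counterpart_kind: str  # "outlet" or a facility kind
    distance_ft: float

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.value,
            "subject_outlet_id": self.subject_outlet_id,
            "counterpart_id": self.counterpart_id,
            "counterpart_kind": self.counterpart_kind,
            "distance_ft": self.distance_ft,
        }


@dataclass
class AuditParams:
    gamma_outlet_ft: float = DEFAULT_OUTLET_SEPARATION_FT
    gamma_facility_ft: float = DEFAULT_FACILITY_BUFFER_FT
    facility_kinds: frozenset[FacilityKind] = ALL_FACILITY_KINDS

    def __post_init__(self) -> None:
        if self.gamma_outlet_ft <= 0 or self.gamma_facility_ft <= 0:
            raise ValidationError("audit thresholds must be positive")
        self.facility_kinds = frozenset(FacilityKind(k) for k in self.facility_kinds)


@dataclass
class AuditReport:
    """Everything the compliance audit measures on one city snapshot."""

    params: AuditParams
    ledger: list[ViolationRecord]
    n_outlets: int
    n_outlet_pairs_violating: int
    n_outlet_facility_pairs_violating: int
    n_outlets_near_outlet: int
    n_outlets_near_facility: int
    variance_outlets: set[str]
    variance_fraction: Optional[float]
    facilities_near_outlet: dict[str, int]
    mean_nn_ft: dict[str, float]
    density_per_sqmi: Optional[float]
    density_per_sqmi_block_mean: Optional[float]
    density_per_kft_road: Optional[float]
    per_block_counts: dict[str, int]
    quota: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "params": {
                "gamma_outlet_ft": self.params.gamma_outlet_ft,
                "gamma_facility_ft": self.params.gamma_facility_ft,
                "facility_kinds": sorted(k.value for k in self.params.facility_kinds),
            },
            "counts": {
                "n_outlets": self.n_outlets,
                "n_outlet_pairs_violating": self.n_outlet_pairs_violating,
                "n_outlet_facility_pairs_violating": self.n_outlet_facility_pairs_violating,
                "n_outlets_near_outlet": self.n_outlets_near_outlet,
                "n_outlets_near_facility": self.n_outlets_near_facility,
                "n_variance_outlets": len(self.variance_outlets),
                "facilities_near_outlet": dict(sorted(self.facilities_near_outlet.items())),
            },
            "ledgers": {
                "violations": [r.to_dict() for r in sorted(
                    self.ledger,
                    key=lambda r: (r.rule.value, r.subject_outlet_id, r.counterpart_id),
                )],
                "variance_outlets": sorted(self.variance_outlets),
            },
            "statistics": {
                "variance_fraction": self.variance_fraction,
                "mean_nn_ft": dict(sorted(self.mean_nn_ft.items())),
                "density_per_sqmi": self.density_per_sqmi,
                "density_per_sqmi_block_mean": self.density_per_sqmi_block_mean,
                "density_per_kft_road": self.density_per_kft_road,
                "per_block_counts": dict(sorted(self.per_block_counts.items())),
                "quota": dict(self.quota),
            },
        }


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Planar Euclidean distance in feet."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def fixed_radius_pairs(points: np.ndarray | Sequence, radius: float) -> set[tuple[int, int]]:
    """All unordered index pairs at strict distance < ``radius``.

    Backed by a k-d tree; pairs the tree reports at exactly the radius are
    filtered out so the result equals the brute-force strict-inequality scan.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return set()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius)  # d <= radius, possibly including == radius
    out = set()
    for i, j in pairs:
        if euclidean_distance(pts[i], pts[j]) < radius:
            out.add((min(i, j), max(i, j)))
    return out


def cross_radius_pairs(
    a: np.ndarray | Sequence, b: np.ndarray | Sequence, radius: float
) -> set[tuple[int, int]]:
    """Index pairs (i, j) with a[i] strictly closer than ``radius`` to b[j]."""
    if radius <= 0:
        raise ValidationError("radius must be positive")
    pa = np.asarray(a, dtype=float).reshape(-1, 2)
    pb = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(pa) == 0 or len(pb) == 0:
        return set()
    tree_b = cKDTree(pb)
    out = set()
    for i, neighbors in enumerate(cKDTree(pa).query_ball_tree(tree_b, radius)):
        for j in neighbors:
            if euclidean_distance(pa[i], pb[j]) < radius:
                out.add((i, j))
    return out


def audit_outlet_separation(
    outlets: Sequence[Outlet], gamma: float = DEFAULT_OUTLET_SEPARATION_FT
) -> list[ViolationRecord]:
    """One record per unordered outlet pair closer than ``gamma`` feet."""
    pts = coords(outlets)
    records = []
    for i, j in sorted(fixed_radius_pairs(pts, gamma)):
        a, b = outlets[i], outlets[j]
        if a.id > b.id:
            a, b = b, a
        records.append(ViolationRecord(
            rule=Rule.OUTLET_SEPARATION,
            subject_outlet_id=a.id,
            counterpart_id=b.id,
            counterpart_kind="outlet",
            distance_ft=euclidean_distance((a.x, a.y), (b.x, b.y)),
        ))
    return records


def audit_facility_buffer(
    outlets: Sequence[Outlet],
    facilities: Sequence[Facility],
    buffer: float = DEFAULT_FACILITY_BUFFER_FT,
    kinds: Iterable[FacilityKind] = ALL_FACILITY_KINDS,
) -> list[ViolationRecord]:
    """One record per (outlet, facility) pair closer than ``buffer`` feet."""
    kinds = frozenset(FacilityKind(k) for k in kinds)
    facs = [f for f in facilities if f.kind in kinds]
    records = []
    for i, j in sorted(cross_radius_pairs(coords(outlets), coords(facs), buffer)):
        o, f = outlets[i], facs[j]
        records.append(ViolationRecord(
            rule=Rule.FACILITY_BUFFER,
            subject_outlet_id=o.id,
            counterpart_id=f.id,
            counterpart_kind=f.kind.value,
            distance_ft=euclidean_distance((o.x, o.y), (f.x, f.y)),
        ))
    return records


def variance_set(
    sep_records: Sequence[ViolationRecord],
    buf_records: Sequence[ViolationRecord],
    n_outlets: int,
) -> tuple[set[str], float]:
    """Distinct outlets needing an exception under either rule, and their share.

    An outlet-separation record implicates both outlets of the pair; a
    facility-buffer record implicates its subject outlet.
    """
    if n_outlets == 0:
        raise InsufficientDataError("variance fraction undefined for zero outlets")
    ids: set[str] = set()
    for r in sep_records:
        ids.add(r.subject_outlet_id)
        ids.add(r.counterpart_id)
    for r in buf_records:
        ids.add(r.subject_outlet_id)
    return ids, len(ids) / n_outlets


def mean_nearest_neighbor(points: np.ndarray | Sequence) -> float:
    """Mean distance from each point to its nearest other point, in feet."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise InsufficientDataError("nearest-neighbor mean needs at least 2 points")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(dists[:, 1].mean())


def assign_blocks(points: np.ndarray | Sequence, blocks: Sequence[Block]) -> list[Optional[str]]:
    """Containing block id for each point; boundary ties go to the lowest id.

    Points outside every block map to None.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(blocks) == 0 or len(pts) == 0:
        return [None] * len(pts)
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].id)
    polys = [blocks[i].polygon() for i in order]
    ids = [blocks[i].id for i in order]
    tree = STRtree(polys)
    assigned: list[Optional[str]] = []
    for x, y in pts:
        hits = [int(h) for h in tree.query(Point(x, y), predicate="covered_by")]
        assigned.append(ids[min(hits)] if hits else None)
    return assigned


def density_stats(
    outlets: Sequence[Outlet], blocks: Sequence[Block]
) -> tuple[Optional[float], Optional[float], dict[str, int], Optional[float]]:
    """Citywide outlet densities and per-block outlet counts.

    Returns ``(per_sqmi, per_kft_road, per_block_counts, per_sqmi_block_mean)``.
    ``per_sqmi`` is total outlets over total block land area; the block-mean
    variant averages each block's own count/area density.  Zero total roadway
    yields an absent (None) roadway density rather than infinity.
    """
    total_area = sum(b.land_area_sqmi for b in blocks)
    if not total_area > 0:
        raise ValidationError("total block land area must be positive")
    n = len(outlets)
    per_sqmi = n / total_area
    total_road = sum(b.roadway_ft for b in blocks)
    per_kft = n / (total_road / 1000.0) if total_road > 0 else None
    counts = {b.id: 0 for b in blocks}
    for bid in assign_blocks(coords(outlets), blocks):
        if bid is not None:
            counts[bid] += 1
    block_mean = float(np.mean([counts[b.id] / b.land_area_sqmi for b in blocks]))
    return per_sqmi, per_kft, counts, block_mean


def quota_allocation(population: int, per_residents: int) -> int:
    """Licenses allowed under a quota of one per ``per_residents`` inhabitants."""
    if per_residents < 1:
        raise ValidationError("per_residents must be >= 1")
    if population < 0:
        raise ValidationError("population must be non-negative")
    return population // per_residents


def run_audit(city: City, params: AuditParams | None = None) -> AuditReport:
    """Full compliance audit of a city's observed outlet layer."""
    params = params or AuditParams()
    sep = audit_outlet_separation(city.outlets, params.gamma_outlet_ft)
    buf = audit_facility_buffer(
        city.outlets, city.facilities, params.gamma_facility_ft, params.facility_kinds
    )
    n = len(city.outlets)
    if n > 0:
        var_ids, var_frac = variance_set(sep, buf, n)
    else:
        var_ids, var_frac = set(), None

    near_outlet = {r.subject_outlet_id for r in sep} | {r.counterpart_id for r in sep}
    near_facility = {r.subject_outlet_id for r in buf}
    fac_kind_of = {f.id: f.kind.value for f in city.facilities}
    facs_hit: dict[str, set[str]] = {}
    for r in buf:
        facs_hit.setdefault(fac_kind_of[r.counterpart_id], set()).add(r.counterpart_id)

    mean_nn: dict[str, float] = {}
    if n >= 2:
        mean_nn["outlets"] = mean_nearest_neighbor(coords(city.outlets))
    for kind in FacilityKind:
        pts = coords([f for f in city.facilities if f.kind == kind])
        if len(pts) >= 2:
            mean_nn[kind.value] = mean_nearest_neighbor(pts)

    if city.blocks:
        per_sqmi, per_kft, per_block, block_mean = density_stats(city.outlets, city.blocks)
    else:
        per_sqmi = per_kft = block_mean = None
        per_block = {}

    population = sum(b.population for b in city.blocks)
    quota = {
        "retail": quota_allocation(population, RETAIL_QUOTA_PER_RESIDENTS),
        "wholesale": quota_allocation(population, WHOLESALE_QUOTA_PER_RESIDENTS),
    }

    return AuditReport(
        params=params,
        ledger=sep + buf,
        n_outlets=n,
        n_outlet_pairs_violating=len(sep),
        n_outlet_facility_pairs_violating=len(buf),
        n_outlets_near_outlet=len(near_outlet),
        n_outlets_near_facility=len(near_facility),
        variance_outlets=var_ids,
        variance_fraction=var_frac,
        facilities_near_outlet={k: len(v) for k, v in facs_hit.items()},
        mean_nn_ft=mean_nn,
        density_per_sqmi=per_sqmi,
        density_per_sqmi_block_mean=block_mean,
        density_per_kft_road=per_kft,
        per_block_counts=per_block,
        quota=quota,
    )
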