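"""Synthetic city generator with a brute-force compliance ground truth.

The real study inputs (Philadelphia parcels, PLCB outlet records, facility
layers) are proprietary, so every downstream stage is exercised on
synthetic cities that reproduce their statistical structure: ~2,000
outlets in four license types, facility layers at realistic counts, a
dense central entertainment district holding ~12% of outlets on well under
1% of the land, census blocks carrying population and roadway totals, and
a controllable number of deliberately ordinance-violating outlets.

Compliant outlets come from a sequential hard-core (Matern-II-style)
rejection sampler: mutual separation >= 200 ft and >= 300 ft from every
facility.  Violators are planted strictly inside the separation buffer of
a host outlet.  At generation time an exhaustive O(n^2) scan records every
sub-threshold pair into a :class:`GroundTruth` ledger — the independent
oracle against which the indexed audit engine is tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.spatial import cKDTree

from .city import Block, City, Facility, FacilityKind, LandUse, LicenseType, Outlet, Parcel
from .errors import CapacityError, ValidationError

SQFT_PER_SQMI = 5280.0 * 5280.0

_LICENSE_ORDER = (
    LicenseType.CLUB,
    LicenseType.DISTRIBUTOR,
    LicenseType.EATING_PLACE,
    LicenseType.RESTAURANT_BAR,
)

# Land-use split for non-commercial parcels (residential-heavy, mild mix).
_NONCOMMERCIAL_USES = (
    LandUse.RESIDENTIAL,
    LandUse.INDUSTRIAL,
    LandUse.CIVIC,
    LandUse.PARK_OPEN_SPACE,
)
_NONCOMMERCIAL_PROBS = (0.78, 0.10, 0.08, 0.04)


@dataclass
class SynthConfig:
    extent_ft: tuple[float, float] = (30_000.0, 30_000.0)
    n_blocks: tuple[int, int] = (10, 10)
    n_parcels: int = 5_000
    n_outlets: int = 300
    commercial_fraction: float = 0.08
    facility_counts: Mapping[str, int] = field(
        default_factory=lambda: {"school": 30, "church": 120, "hospital": 4,
                                 "park": 10, "playground": 10})
    outlet_type_mix: tuple[float, float, float, float] = (0.059, 0.056, 0.065, 0.75)
    cluster_fraction: float = 0.12
    cluster_area_fraction: float = 0.006
    n_violating_outlets: int = 0
    population_total: int = 250_000
    roadway_ft_per_block_mean: float = 20_000.0
    outlet_separation_ft: float = 200.0
    facility_buffer_ft: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.outlet_type_mix = tuple(float(p) for p in self.outlet_type_mix)
        s = sum(self.outlet_type_mix)
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            # permissive: renormalize an off-by-rounding mix, reject junk
            if not 0.5 < s < 2.0:
                raise ValidationError(f"outlet_type_mix sums to {s}, not 1")
            self.outlet_type_mix = tuple(p / s for p in self.outlet_type_mix)
        if len(self.outlet_type_mix) != 4 or any(p < 0 for p in self.outlet_type_mix):
            raise ValidationError("outlet_type_mix must be 4 non-negative probabilities")
        if not (0 < self.commercial_fraction <= 1):
            raise ValidationError("commercial_fraction must be in (0, 1]")
        if not (0 <= self.cluster_fraction < 1):
            raise ValidationError("cluster_fraction must be in [0, 1)")
        if not (0 < self.cluster_area_fraction < 1):
            raise ValidationError("cluster_area_fraction must be in (0, 1)")
        if self.n_violating_outlets > self.n_outlets:
            raise ValidationError("n_violating_outlets exceeds n_outlets")
        for name in ("n_parcels", "n_outlets", "n_violating_outlets", "population_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        self.facility_counts = {FacilityKind(k).value: int(v)
                                for k, v in dict(self.facility_counts).items()}
        if any(v < 0 for v in self.facility_counts.values()):
            raise ValidationError("facility counts must be non-negative")


@dataclass
class GroundTruth:
    """Exhaustive-scan ledger of every sub-threshold proximity at generation time."""

    outlet_pairs_lt_200: set[frozenset[str]]
    outlet_facility_lt_300: set[tuple[str, str]]
    outlet_separation_ft: float = 200.0
    facility_buffer_ft: float = 300.0

    def to_dict(self) -> dict:
        return {
            "outlet_separation_ft": self.outlet_separation_ft,
            "facility_buffer_ft": self.facility_buffer_ft,
            "outlet_pairs": sorted(sorted(p) for p in self.outlet_pairs_lt_200),
            "outlet_facility_pairs": sorted(list(p) for p in self.outlet_facility_lt_300),
        }


def default_philadelphia_like() -> SynthConfig:
    """Desk-scale stand-in for the Philadelphia study inputs.

    1,964 outlets in the observed license-type mix, facility layers at the
    study's counts (376 schools, 1,798 churches, 39 hospitals, 122 parks and
    playgrounds split evenly), a central district holding 12% of outlets on
    0.6% of the land, ~134 sq mi of extent, the 2010 census population, and
    50,000 parcels standing in for the city's 569,928.  472 outlets are
    planted as separation violators with distinct hosts, so roughly 944
    outlets — about 48% — need a variance, as observed.
    """
    return SynthConfig(
        extent_ft=(61_160.0, 61_160.0),  # ~134.2 sq mi, Philadelphia's land area
        n_blocks=(24, 24),
        n_parcels=50_000,
        n_outlets=1_964,
        commercial_fraction=0.08,
        facility_counts={"school": 376, "church": 1_798, "hospital": 39,
                         "park": 61, "playground": 61},
        outlet_type_mix=(0.059, 0.056, 0.065, 0.75),
        cluster_fraction=0.12,
        cluster_area_fraction=0.006,
        n_violating_outlets=472,
        population_total=1_526_006,
        roadway_ft_per_block_mean=32_000.0,
        seed=0,
    )


def hard_core_thinning(points, gamma: float):
    """Keep each point only if it is >= ``gamma`` from every earlier kept point.

    Earlier points win conflicts, so the result depends on input order; the
    returned subset has all pairwise distances >= gamma.
    """
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    kept: list[tuple[float, float]] = []
    grid = _HardCoreGrid(gamma)
    for p in points:
        x, y = float(p[0]), float(p[1])
        if grid.admissible(x, y):
            grid.add(x, y)
            kept.append((x, y))
    return kept


class _HardCoreGrid:
    """Uniform grid for O(1) hard-core admissibility checks at radius gamma."""

    def __init__(self, gamma: float):
        self.gamma = gamma
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(math.floor(x / self.gamma)), int(math.floor(y / self.gamma)))

    def admissible(self, x: float, y: float) -> bool:
        ci, cj = self._key(x, y)
        g2 = self.gamma * self.gamma
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for px, py in self.cells.get((ci + di, cj + dj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < g2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.cells.setdefault(self._key(x, y), []).append((x, y))


def _exhaustive_pairs_lt(points: np.ndarray, r: float, chunk: int = 512) -> set[tuple[int, int]]:
    """All index pairs with strict distance < r, by chunked full pairwise scan."""
    n = len(points)
    out: set[tuple[int, int]] = set()
    r2 = r * r
    for start in range(0, n, chunk):
        block = points[start:start + chunk]
        rest = points[start:]
        d2 = ((block[:, None, :] - rest[None, :, :]) ** 2).sum(axis=2)
        ii, jj = np.nonzero(d2 < r2)
        for i, j in zip(ii.tolist(), jj.tolist()):
            a, b = start + i, start + j
            if a < b:
                out.add((a, b))
    return out


def _exhaustive_cross_lt(a: np.ndarray, b: np.ndarray, r: float,
                         chunk: int = 512) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    if len(a) == 0 or len(b) == 0:
        return out
    r2 = r * r
    for start in range(0, len(a), chunk):
        block = a[start:start + chunk]
        d2 = ((block[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        ii, jj = np.nonzero(d2 < r2)
        for i, j in zip(ii.tolist(), jj.tolist()):
            out.add((start + i, j))
    return out


def _make_blocks(cfg: SynthConfig, rng: np.random.Generator) -> list[Block]:
    nx, ny = cfg.n_blocks
    w, h = cfg.extent_ft
    cw, ch = w / nx, h / ny
    n = nx * ny
    road = rng.gamma(shape=4.0, scale=cfg.roadway_ft_per_block_mean / 4.0, size=n)
    pops = rng.multinomial(cfg.population_total, np.full(n, 1.0 / n))
    blocks = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            x0, y0 = i * cw, j * ch
            blocks.append(Block(
                id=f"b{k:04d}",
                boundary=[(x0, y0), (x0 + cw, y0), (x0 + cw, y0 + ch), (x0, y0 + ch)],
                land_area_sqmi=cw * ch / SQFT_PER_SQMI,
                roadway_ft=float(road[k]),
                population=int(pops[k]),
            ))
            k += 1
    return blocks


def _district_rect(cfg: SynthConfig) -> tuple[float, float, float, float]:
    """Central entertainment-district rectangle (x0, y0, dx, dy)."""
    w, h = cfg.extent_ft
    s = math.sqrt(cfg.cluster_area_fraction)
    dw, dh = w * s, h * s
    return ((w - dw) / 2.0, (h - dh) / 2.0, dw, dh)


def _block_id_of(cfg: SynthConfig, x: float, y: float) -> str:
    nx, ny = cfg.n_blocks
    w, h = cfg.extent_ft
    i = min(int(x / (w / nx)), nx - 1)
    j = min(int(y / (h / ny)), ny - 1)
    return f"b{j * nx + i:04d}"


def _make_parcels(cfg: SynthConfig, rng: np.random.Generator) -> list[Parcel]:
    w, h = cfg.extent_ft
    xs = rng.uniform(0, w, cfg.n_parcels)
    ys = rng.uniform(0, h, cfg.n_parcels)
    dx0, dy0, dw, dh = _district_rect(cfg)
    in_district = (xs >= dx0) & (xs < dx0 + dw) & (ys >= dy0) & (ys < dy0 + dh)
    # commercial zoning concentrates in the district: 3x oversampling, capped
    p_comm = np.where(in_district, min(3 * cfg.commercial_fraction, 1.0),
                      cfg.commercial_fraction)
    is_comm = rng.uniform(size=cfg.n_parcels) < p_comm
    other = rng.choice(len(_NONCOMMERCIAL_USES), size=cfg.n_parcels,
                       p=_NONCOMMERCIAL_PROBS)
    parcels = []
    for k in range(cfg.n_parcels):
        use = LandUse.COMMERCIAL if is_comm[k] else _NONCOMMERCIAL_USES[other[k]]
        parcels.append(Parcel(
            id=f"p{k:06d}", x=float(xs[k]), y=float(ys[k]),
            land_use=use, block_id=_block_id_of(cfg, xs[k], ys[k]),
        ))
    return parcels


def _make_facilities(cfg: SynthConfig, rng: np.random.Generator) -> list[Facility]:
    w, h = cfg.extent_ft
    facilities = []
    k = 0
    for kind in sorted(cfg.facility_counts):
        for _ in range(cfg.facility_counts[kind]):
            facilities.append(Facility(
                id=f"f{k:05d}", x=float(rng.uniform(0, w)), y=float(rng.uniform(0, h)),
                kind=FacilityKind(kind),
            ))
            k += 1
    return facilities


def _place_compliant(
    cfg: SynthConfig,
    rng: np.random.Generator,
    facility_xy: np.ndarray,
    max_attempts_per_point: int = 2_000,
) -> list[tuple[float, float]]:
    """Sequential hard-core placement: >= separation apart, >= buffer from facilities."""
    n_compliant = cfg.n_outlets - cfg.n_violating_outlets
    n_cluster = round(cfg.cluster_fraction * n_compliant)
    dx0, dy0, dw, dh = _district_rect(cfg)
    w, h = cfg.extent_ft
    fac_tree = cKDTree(facility_xy) if len(facility_xy) else None
    grid = _HardCoreGrid(cfg.outlet_separation_ft)
    buf2 = cfg.facility_buffer_ft ** 2
    placed: list[tuple[float, float]] = []
    for idx in range(n_compliant):
        in_cluster = idx < n_cluster
        for attempt in range(max_attempts_per_point):
            if in_cluster:
                x = rng.uniform(dx0, dx0 + dw)
                y = rng.uniform(dy0, dy0 + dh)
            else:
                x = rng.uniform(0, w)
                y = rng.uniform(0, h)
            if not grid.admissible(x, y):
                continue
            if fac_tree is not None:
                d, _ = fac_tree.query((x, y))
                if d * d < buf2:
                    continue
            grid.add(x, y)
            placed.append((x, y))
            break
        else:
            raise CapacityError(placed=len(placed), requested=n_compliant)
    return placed


def _place_violators(
    cfg: SynthConfig, rng: np.random.Generator, hosts: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Plant each violator at radius [0.25, 0.95]*Gamma from a distinct host."""
    n = cfg.n_violating_outlets
    if n == 0:
        return []
    w, h = cfg.extent_ft
    gamma = cfg.outlet_separation_ft
    if len(hosts) >= n:
        host_idx = rng.choice(len(hosts), size=n, replace=False)
    else:  # fewer hosts than violators: reuse hosts
        host_idx = rng.choice(max(len(hosts), 1), size=n, replace=True)
    out = []
    for hi in host_idx:
        hx, hy = hosts[int(hi)] if hosts else (w / 2, h / 2)
        for _ in range(200):
            r = rng.uniform(0.25 * gamma, 0.95 * gamma)
            theta = rng.uniform(0, 2 * math.pi)
            x, y = hx + r * math.cos(theta), hy + r * math.sin(theta)
            if 0 <= x < w and 0 <= y < h:
                out.append((x, y))
                break
        else:  # host hugs a corner; clamp inside
            out.append((min(max(hx, 0.0), w - 1.0), min(max(hy, 0.0), h - 1.0)))
    return out


def generate_city(config: SynthConfig) -> tuple[City, GroundTruth]:
    """Generate a synthetic city plus its exhaustive-scan ground-truth ledger.

    Layer counts equal the configured counts exactly; blocks tile the extent
    as a grid and their populations sum to ``population_total``; all but the
    ``n_violating_outlets`` planted violators are mutually >= 200 ft apart
    and >= 300 ft from every facility.  Identical config and seed give
    bit-identical output.

    Raises :class:`CapacityError` when the compliant pattern cannot be packed
    into the extent.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_blocks, rng_parcels, rng_fac, rng_out, rng_viol, rng_types = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    blocks = _make_blocks(config, rng_blocks)
    facilities = _make_facilities(config, rng_fac)
    parcels = _make_parcels(config, rng_parcels)

    fac_xy = np.array([(f.x, f.y) for f in facilities], dtype=float).reshape(-1, 2)
    compliant = _place_compliant(config, rng_out, fac_xy)
    violators = _place_violators(config, rng_viol, compliant)
    xy = compliant + violators

    types = rng_types.choice(4, size=config.n_outlets, p=config.outlet_type_mix)
    outlets = [
        Outlet(id=f"o{k:05d}", x=x, y=y, license_type=_LICENSE_ORDER[types[k]])
        for k, (x, y) in enumerate(xy)
    ]

    city = City(parcels=parcels, outlets=outlets, facilities=facilities, blocks=blocks)

    out_xy = np.array(xy, dtype=float).reshape(-1, 2)
    pair_idx = _exhaustive_pairs_lt(out_xy, config.outlet_separation_ft)
    cross_idx = _exhaustive_cross_lt(out_xy, fac_xy, config.facility_buffer_ft)
    gt = GroundTruth(
        outlet_pairs_lt_200={
            frozenset((outlets[i].id, outlets[j].id)) for i, j in pair_idx
        },
        outlet_facility_lt_300={
            (outlets[i].id, facilities[j].id) for i, j in cross_idx
        },
        outlet_separation_ft=config.outlet_separation_ft,
        facility_buffer_ft=config.facility_buffer_ft,
    )
    return city, gt
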