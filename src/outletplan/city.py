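"""Domain model for a city's spatial layers.

All coordinates are projected planar feet.  A :class:`City` bundles four
point/polygon layers — land parcels, licensed alcohol outlets, sensitive
community facilities (schools, churches, hospitals, parks, playgrounds)
and census blocks — and is the common currency of every other module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from .errors import ValidationError


class LandUse(str, Enum):
    COMMERCIAL = "commercial"
    RESIDENTIAL = "residential"
    INDUSTRIAL = "industrial"
    CIVIC = "civic"
    PARK_OPEN_SPACE = "park_open_space"


class LicenseType(str, Enum):
    CLUB = "club"
    DISTRIBUTOR = "distributor"
    EATING_PLACE = "eating_place"
    RESTAURANT_BAR = "restaurant_bar"


class FacilityKind(str, Enum):
    SCHOOL = "school"
    CHURCH = "church"
    HOSPITAL = "hospital"
    PARK = "park"
    PLAYGROUND = "playground"


#: Declared planar unit for every City; GeoJSON output records it in the manifest.
UNIT_DECLARATION = "feet, projected planar"


def _check_finite(x: float, y: float, what: str, id_: str) -> None:
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValidationError(f"{what} {id_!r} has non-finite coordinates ({x}, {y})")


@dataclass
class Parcel:
    """A land parcel represented by its centroid.

    ``benefit`` is the per-parcel license benefit (α_k); the default of 1.0
    makes the allocation objective a plain outlet count.
    """

    id: str
    x: float
    y: float
    land_use: LandUse
    block_id: Optional[str] = None
    benefit: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y, "parcel", self.id)
        self.land_use = LandUse(self.land_use)
        if not (math.isfinite(self.benefit) and self.benefit >= 0):
            raise ValidationError(f"parcel {self.id!r} has negative benefit {self.benefit}")


@dataclass
class Outlet:
    """A licensed alcohol outlet (point location, one of four license types)."""

    id: str
    x: float
    y: float
    license_type: LicenseType
    parcel_id: Optional[str] = None

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y, "outlet", self.id)
        self.license_type = LicenseType(self.license_type)


@dataclass
class Facility:
    """A sensitive community facility protected by the 300-ft buffer rule."""

    id: str
    x: float
    y: float
    kind: FacilityKind

    def __post_init__(self) -> None:
        _check_finite(self.x, self.y, "facility", self.id)
        self.kind = FacilityKind(self.kind)


@dataclass
class Block:
    """A census block: polygon boundary plus population, land area, roadway."""

    id: str
    boundary: Sequence[tuple[float, float]]
    land_area_sqmi: float
    roadway_ft: float
    population: int

    def __post_init__(self) -> None:
        ring = [(float(x), float(y)) for x, y in self.boundary]
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        self.boundary = ring
        for x, y in ring:
            _check_finite(x, y, "block", self.id)
        if len(ring) < 4:
            raise ValidationError(f"block {self.id!r} boundary has fewer than 3 vertices")
        if not self.polygon().is_simple:
            raise ValidationError(f"block {self.id!r} boundary is self-intersecting")
        if not self.land_area_sqmi > 0:
            raise ValidationError(f"block {self.id!r} land_area_sqmi must be positive")
        if self.roadway_ft < 0:
            raise ValidationError(f"block {self.id!r} roadway_ft must be non-negative")
        if self.population < 0:
            raise ValidationError(f"block {self.id!r} population must be non-negative")

    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


def coords(items: Iterable) -> np.ndarray:
    """(n, 2) array of x/y coordinates for any point-layer collection."""
    arr = np.array([(o.x, o.y) for o in items], dtype=float)
    return arr.reshape(-1, 2)


@dataclass
class City:
    """Container for the four layers with a fixed planar-feet unit declaration."""

    parcels: list[Parcel] = field(default_factory=list)
    outlets: list[Outlet] = field(default_factory=list)
    facilities: list[Facility] = field(default_factory=list)
    blocks: list[Block] = field(default_factory=list)
    unit: str = UNIT_DECLARATION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, check_block_overlap: bool = False) -> None:
        """Raise :class:`ValidationError` on duplicate ids or dangling block refs.

        Pairwise block-overlap checking is opt-in: it is O(n log n) with
        geometry predicates and only worth running on untrusted input.
        """
        for name, layer in (
            ("parcels", self.parcels),
            ("outlets", self.outlets),
            ("facilities", self.facilities),
            ("blocks", self.blocks),
        ):
            ids = [item.id for item in layer]
            if len(ids) != len(set(ids)):
                seen: set[str] = set()
                dups = sorted({i for i in ids if i in seen or seen.add(i)})
                raise ValidationError(f"duplicate ids in layer {name}: {dups}")
        block_ids = {b.id for b in self.blocks}
        for p in self.parcels:
            if p.block_id is not None and p.block_id not in block_ids:
                raise ValidationError(
                    f"parcel {p.id!r} references unknown block {p.block_id!r}"
                )
        if check_block_overlap and len(self.blocks) > 1:
            polys = [b.polygon() for b in self.blocks]
            tree = STRtree(polys)
            for i, poly in enumerate(polys):
                for j in tree.query(poly, predicate="intersects"):
                    j = int(j)
                    if j > i and polys[i].intersection(polys[j]).area > 1e-6:
                        raise ValidationError(
                            f"blocks {self.blocks[i].id!r} and {self.blocks[j].id!r} overlap"
                        )

    def parcel_by_id(self) -> dict[str, Parcel]:
        return {p.id: p for p in self.parcels}

    def layer_sizes(self) -> tuple[int, int, int, int]:
        return (len(self.parcels), len(self.outlets), len(self.facilities), len(self.blocks))
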