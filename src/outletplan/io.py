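"""Reading and writing city layers and reports.

Layers travel as GeoJSON FeatureCollections (Point features for parcels,
outlets and facilities; Polygon features for blocks) with coordinates in
projected planar feet — the unit is declared in the write manifest because
GeoJSON's own convention is lon/lat.  A CSV alternative with columns
``id,x,y,...`` is accepted for the point layers.

Feature order in every output file is ascending by id, so repeated writes
of the same City are byte-identical.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .city import UNIT_DECLARATION, Block, City, Facility, Outlet, Parcel
from .errors import InputError, UnitError, ValidationError

LAYER_NAMES = ("parcels", "outlets", "facilities", "blocks")

_POINT_BUILDERS = {
    "parcels": lambda i, x, y, props: Parcel(
        id=i, x=x, y=y,
        land_use=props["land_use"],
        block_id=props.get("block_id"),
        benefit=float(props.get("benefit", 1.0)),
    ),
    "outlets": lambda i, x, y, props: Outlet(
        id=i, x=x, y=y,
        license_type=props["license_type"],
        parcel_id=props.get("parcel_id"),
    ),
    "facilities": lambda i, x, y, props: Facility(id=i, x=x, y=y, kind=props["kind"]),
}


def _looks_geographic(xy: list[tuple[float, float]]) -> bool:
    # A layer whose every coordinate fits in lon/lat ranges was almost
    # certainly not projected to feet.
    return bool(xy) and all(abs(x) <= 180.0 and abs(y) <= 90.0 for x, y in xy)


def _read_geojson_features(path: Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection" or "features" not in data:
        raise InputError(f"{path} is not a GeoJSON FeatureCollection")
    return data["features"]


def _point_records_from_geojson(features: list[dict]) -> list[tuple[str, float, float, dict]]:
    records = []
    for feat in features:
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise InputError(f"expected Point geometry, got {geom.get('type')}")
        x, y = float(geom["coordinates"][0]), float(geom["coordinates"][1])
        props = dict(feat.get("properties") or {})
        fid = str(props.pop("id"))
        records.append((fid, x, y, props))
    return records


def _point_records_from_csv(path: Path) -> list[tuple[str, float, float, dict]]:
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise InputError(f"{path} lacks required column {col!r}")
    records = []
    extra = [c for c in df.columns if c not in ("id", "x", "y")]
    for row in df.itertuples(index=False):
        props = {c: getattr(row, c) for c in extra}
        props = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                 for k, v in props.items()}
        records.append((str(row.id), float(row.x), float(row.y), props))
    return records


def read_city(layer_paths: Mapping[str, str | Path]) -> City:
    """Load a :class:`City` from per-layer GeoJSON or CSV files.

    ``layer_paths`` maps layer names (any subset of ``parcels``, ``outlets``,
    ``facilities``, ``blocks``) to paths; omitted layers are empty.

    Raises
    ------
    InputError
        If a named file is missing or malformed.
    UnitError
        If every coordinate of a layer fits in |x| <= 180, |y| <= 90 —
        evidence of lon/lat degrees rather than planar feet.
    ValidationError
        On duplicate ids or unknown enumeration values.
    """
    unknown = set(layer_paths) - set(LAYER_NAMES)
    if unknown:
        raise InputError(f"unknown layer names: {sorted(unknown)}")
    layers: dict[str, list] = {name: [] for name in LAYER_NAMES}

    for name, raw_path in layer_paths.items():
        path = Path(raw_path)
        if not path.exists():
            raise InputError(f"layer {name!r}: file not found: {path}")
        if name == "blocks":
            feats = _read_geojson_features(path)
            blocks = []
            all_xy: list[tuple[float, float]] = []
            for feat in feats:
                geom = feat.get("geometry") or {}
                if geom.get("type") != "Polygon":
                    raise InputError(f"blocks layer: expected Polygon, got {geom.get('type')}")
                ring = [(float(x), float(y)) for x, y in geom["coordinates"][0]]
                all_xy.extend(ring)
                props = dict(feat.get("properties") or {})
                blocks.append(Block(
                    id=str(props["id"]),
                    boundary=ring,
                    land_area_sqmi=float(props["land_area_sqmi"]),
                    roadway_ft=float(props["roadway_ft"]),
                    population=int(props["population"]),
                ))
            if _looks_geographic(all_xy):
                raise UnitError(
                    "layer 'blocks' looks geographic (all coordinates within "
                    "lon/lat ranges); expected planar feet"
                )
            layers[name] = blocks
        else:
            if path.suffix.lower() == ".csv":
                records = _point_records_from_csv(path)
            else:
                records = _point_records_from_geojson(_read_geojson_features(path))
            if _looks_geographic([(x, y) for _, x, y, _ in records]):
                raise UnitError(
                    f"layer {name!r} looks geographic (all coordinates within "
                    "lon/lat ranges); expected planar feet"
                )
            try:
                layers[name] = [_POINT_BUILDERS[name](i, x, y, p) for i, x, y, p in records]
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"layer {name!r}: {exc}") from exc

    return City(**layers)


def _feature(geom: dict, props: dict) -> dict:
    return {"type": "Feature", "geometry": geom, "properties": props}


def _point(x: float, y: float) -> dict:
    return {"type": "Point", "coordinates": [x, y]}


def _layer_features(name: str, city: City) -> list[dict]:
    if name == "parcels":
        return [
            _feature(_point(p.x, p.y), {
                "id": p.id, "land_use": p.land_use.value,
                "block_id": p.block_id, "benefit": p.benefit,
            })
            for p in sorted(city.parcels, key=lambda p: p.id)
        ]
    if name == "outlets":
        return [
            _feature(_point(o.x, o.y), {
                "id": o.id, "license_type": o.license_type.value,
                "parcel_id": o.parcel_id,
            })
            for o in sorted(city.outlets, key=lambda o: o.id)
        ]
    if name == "facilities":
        return [
            _feature(_point(f.x, f.y), {"id": f.id, "kind": f.kind.value})
            for f in sorted(city.facilities, key=lambda f: f.id)
        ]
    return [
        _feature(
            {"type": "Polygon", "coordinates": [[list(xy) for xy in b.boundary]]},
            {"id": b.id, "land_area_sqmi": b.land_area_sqmi,
             "roadway_ft": b.roadway_ft, "population": b.population},
        )
        for b in sorted(city.blocks, key=lambda b: b.id)
    ]


def write_city(city: City, out_dir: str | Path) -> dict:
    """Write one GeoJSON file per layer plus ``manifest.json``.

    Returns the manifest: per-layer file name and feature count, and the
    planar unit declaration.  Output is deterministic (ascending-id order,
    sorted JSON keys), so identical Cities produce byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    city.validate()
    manifest: dict[str, Any] = {"unit": UNIT_DECLARATION, "layers": {}}
    for name in LAYER_NAMES:
        features = _layer_features(name, city)
        fc = {"type": "FeatureCollection", "features": features}
        path = out / f"{name}.geojson"
        _dump_json(fc, path)
        manifest["layers"][name] = {"file": path.name, "count": len(features)}
    _dump_json(manifest, out / "manifest.json")
    return manifest


def read_city_dir(city_dir: str | Path) -> City:
    """Load a City from a directory previously written by :func:`write_city`."""
    d = Path(city_dir)
    paths = {name: d / f"{name}.geojson" for name in LAYER_NAMES
             if (d / f"{name}.geojson").exists()}
    if not paths:
        raise InputError(f"no layer files found in {d}")
    return read_city(paths)


def jsonify(obj: Any) -> Any:
    """Recursively convert report objects to plain JSON-serializable types."""
    import numpy as np

    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(jsonify(k)): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(jsonify(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if hasattr(obj, "to_dict"):
        return jsonify(obj.to_dict())
    return obj


def _dump_json(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(jsonify(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_report(report: Any, out_dir: str | Path, stem: str = "report") -> dict:
    """Serialize an AuditReport or ComparisonReport to JSON plus flat CSVs.

    Emits ``<stem>.json`` with top-level keys {params, counts, ledgers,
    statistics}, a ``ledger.csv`` of violation records, and a
    ``per_block_counts.csv`` (columns ``block_id,count``) suitable for
    external choropleth mapping.  Returns a manifest of files written.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc
    d = report.to_dict()
    json_path = out / f"{stem}.json"
    _dump_json(d, json_path)
    manifest = {"json": json_path.name}

    ledger = d.get("ledgers", {}).get("violations")
    if ledger is None and "observed" in d:  # comparison report: observed ledger
        ledger = d["observed"].get("ledgers", {}).get("violations", [])
    cols = ["rule", "subject_outlet_id", "counterpart_id", "counterpart_kind", "distance_ft"]
    ledger_df = pd.DataFrame(ledger or [], columns=cols)
    ledger_path = out / "ledger.csv"
    ledger_df.to_csv(ledger_path, index=False)
    manifest["ledger"] = ledger_path.name

    counts = d.get("statistics", {}).get("per_block_counts")
    if counts is None and "observed" in d:
        counts = d["observed"].get("statistics", {}).get("per_block_counts", {})
    counts_df = pd.DataFrame(
        sorted((counts or {}).items()), columns=["block_id", "count"]
    )
    counts_path = out / "per_block_counts.csv"
    counts_df.to_csv(counts_path, index=False)
    manifest["per_block_counts"] = counts_path.name
    return manifest
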