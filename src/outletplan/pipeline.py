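"""End-to-end scenario pipeline: generate/load -> audit -> optimize -> compare.

The observed scenario audits the outlet layer exactly as it stands,
variances and all; the modeled scenario solves the license-allocation
model and is always re-verified, mirroring the contrast between a
variance-riddled reality and a fully compliant modeled distribution.
The pipeline is static — one-shot optimization, no outlet turnover
dynamics — and deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from .audit import AuditParams, AuditReport, run_audit
from .city import City
from .errors import ConfigError
from .io import _dump_json, read_city_dir, write_city, write_report
from .model import ModelConfig, Solution, solution_as_outlets, solve, verify_solution
from .synth import SynthConfig, generate_city


@dataclass
class ComparisonReport:
    """Observed-vs-modeled contrast: counts, densities, quota gap."""

    observed: AuditReport
    modeled: AuditReport
    solution_summary: dict
    n_observed: int
    n_modeled: int
    absolute_change: int
    percent_change: Optional[float]
    density_change: dict[str, tuple[Optional[float], Optional[float]]]
    quota_gap: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.to_dict(),
            "modeled": self.modeled.to_dict(),
            "solution": self.solution_summary,
            "counts": {
                "n_observed": self.n_observed,
                "n_modeled": self.n_modeled,
                "absolute_change": self.absolute_change,
                "percent_change": self.percent_change,
                "quota_gap": self.quota_gap,
            },
            "statistics": {"density_change": {
                k: list(v) for k, v in self.density_change.items()
            }},
        }


def compare_scenarios(
    observed_report: AuditReport,
    modeled_solution: Solution,
    city: City,
    config: ModelConfig | None = None,
) -> ComparisonReport:
    """Contrast the audited observed pattern with the modeled allocation.

    Modeled densities come from re-running the audit engine on the selected
    parcels treated as outlets.  ``percent_change`` is reported exactly (one
    decimal is a presentation choice left to the caller) and is absent when
    there are no observed outlets.
    """
    config = config or ModelConfig()
    modeled_report = verify_solution(city, modeled_solution, config)
    n_obs = observed_report.n_outlets
    n_mod = len(modeled_solution.selected)
    pct = 100.0 * (n_mod - n_obs) / n_obs if n_obs > 0 else None
    log = dict(modeled_solution.solver_log)
    log.pop("elapsed_s", None)  # timings vary run to run; keep reports reproducible
    return ComparisonReport(
        observed=observed_report,
        modeled=modeled_report,
        solution_summary={
            "objective": modeled_solution.objective,
            "status": modeled_solution.status.value,
            "solver_log": log,
        },
        n_observed=n_obs,
        n_modeled=n_mod,
        absolute_change=n_mod - n_obs,
        percent_change=pct,
        density_change={
            "per_sqmi": (observed_report.density_per_sqmi,
                         modeled_report.density_per_sqmi),
            "per_kft_road": (observed_report.density_per_kft_road,
                             modeled_report.density_per_kft_road),
        },
        quota_gap=n_obs - observed_report.quota["retail"],
    )


def _build_dataclass(cls, mapping: Mapping[str, Any], section: str):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"section {section!r}: unknown keys {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("extent_ft", "n_blocks", "outlet_type_mix"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Normalize a YAML path or mapping into pipeline settings.

    Sections: exactly one of ``synth`` (SynthConfig fields) or ``city``
    (a directory written by :func:`outletplan.io.write_city`), plus optional
    ``audit`` (AuditParams fields), ``model`` (ModelConfig fields) and
    ``output`` ({dir: path}).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(config)
    known = {"synth", "city", "audit", "model", "output"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    if ("synth" in raw) == ("city" in raw):
        raise ConfigError("config must name exactly one of 'synth' or 'city'")
    settings: dict[str, Any] = {
        "synth": _build_dataclass(SynthConfig, raw["synth"], "synth")
        if "synth" in raw else None,
        "city_dir": raw.get("city"),
        "audit": _build_dataclass(AuditParams, raw.get("audit", {}), "audit"),
        "model": _build_dataclass(ModelConfig, raw.get("model", {}), "model"),
        "out_dir": (raw.get("output") or {}).get("dir"),
    }
    return settings


def run_pipeline(config: str | Path | Mapping[str, Any],
                 out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run generate/load -> audit -> model -> verify -> compare; write artifacts.

    Returns a result dict with the city, reports, solution and the artifact
    manifest.  When an output directory is configured (or passed), writes
    city layers (if generated), ``groundtruth.json``, the audit report, the
    solution, the verification report, ``comparison.json`` and a run log.
    A second run with the same config and seed produces byte-identical
    report files (the run log's timings aside).
    """
    t_start = time.monotonic()
    settings = load_config(config)
    out = Path(out_dir) if out_dir is not None else (
        Path(settings["out_dir"]) if settings["out_dir"] else None)
    timings: dict[str, float] = {}
    manifest: dict[str, Any] = {}

    t0 = time.monotonic()
    if settings["synth"] is not None:
        city, ground_truth = generate_city(settings["synth"])
    else:
        city, ground_truth = read_city_dir(settings["city_dir"]), None
    timings["generate_or_load_s"] = time.monotonic() - t0

    t0 = time.monotonic()
    observed = run_audit(city, settings["audit"])
    timings["audit_s"] = time.monotonic() - t0

    t0 = time.monotonic()
    solution = solve(city, settings["model"])
    timings["model_s"] = time.monotonic() - t0

    t0 = time.monotonic()
    comparison = compare_scenarios(observed, solution, city, settings["model"])
    timings["compare_s"] = time.monotonic() - t0

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if settings["synth"] is not None:
            manifest["city"] = write_city(city, out / "city")
            _dump_json(ground_truth.to_dict(), out / "groundtruth.json")
            manifest["groundtruth"] = "groundtruth.json"
        manifest["audit"] = write_report(observed, out / "audit", stem="report")
        sol_dict = solution.to_dict()
        sol_dict["solver_log"] = {k: v for k, v in sol_dict["solver_log"].items()
                                  if k != "elapsed_s"}  # keep files reproducible
        _dump_json(sol_dict, out / "solution.json")
        sol_city = City(outlets=solution_as_outlets(city, solution))
        manifest["solution_outlets"] = write_city(sol_city, out / "solution_outlets")
        manifest["verification"] = write_report(
            comparison.modeled, out / "verification", stem="report")
        _dump_json(comparison.to_dict(), out / "comparison.json")
        run_log = {
            "package_version": __version__,
            "python": platform.python_version(),
            "config": {
                "synth": None if settings["synth"] is None
                else {f.name: getattr(settings["synth"], f.name)
                      for f in fields(SynthConfig)},
                "city_dir": settings["city_dir"],
                "audit": {f.name: getattr(settings["audit"], f.name)
                          for f in fields(AuditParams)},
                "model": {f.name: getattr(settings["model"], f.name)
                          for f in fields(ModelConfig)},
            },
            "graph": {k: v for k, v in solution.solver_log.items()
                      if k in ("n_nodes", "n_edges", "n_eligible", "solver")},
            "timings_s": timings,
            "total_s": time.monotonic() - t_start,
        }
        _dump_json(run_log, out / "run_log.json")

    return {
        "city": city,
        "ground_truth": ground_truth,
        "observed_report": observed,
        "solution": solution,
        "comparison": comparison,
        "manifest": manifest,
        "timings": timings,
    }
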