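"""Output writers, summary statistics, and the synthetic-landscape generator.

The step log is plain CSV (one row per animal per time-step) and the
per-season home-range and perception-corridor layers are GeoJSON, so every
output is diffable — the determinism contract (same config + seed => byte-
identical outputs) is checked by literal file comparison.

The synthetic-landscape generator builds tessellated polygon maps (regular
grid or clipped Voronoi) whose patches draw attribute classes from a seeded
stream. It stands in for field-digitized GIS layers in tests and worked
examples, and can emit paired map variants (e.g. scarce/superabundant food,
day/night risk) for swap schedules.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, box, mapping

from .engine import LOG_COLUMNS, SimulationResult
from .errors import ConfigurationError, DispersimError, MapValidationError
from .landscape import _RANGES, _check_range

# ---------------------------------------------------------------------------
# writers


def write_step_log(rows: Sequence[Sequence], path: str) -> None:
    """Write the per-animal per-step log as CSV with a header row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_COLUMNS)
        for row in rows:
            w.writerow(row)


def read_step_log(path: str) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "properties": props, "geometry": mapping(geom)}


def write_geojson(features: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True, separators=(",", ":"))


def read_geojson(path: str) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    return data.get("features", [])


def write_vector_outputs(result: SimulationResult, out_dir: str) -> list[str]:
    """Per-season home-range and perception-corridor GeoJSON layers.

    A season with no settlers still produces a valid, empty layer.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for year in sorted(result.home_ranges):
        feats = []
        for hr in result.home_ranges[year]:
            try:
                feats.append(_feature(hr.polygon, {
                    "owner": hr.owner_id, "sex": hr.sex, "year": year}))
            except Exception as exc:  # pragma: no cover - defensive
                raise DispersimError(
                    f"failed to write home range of animal {hr.owner_id}: {exc}"
                ) from exc
        p = os.path.join(out_dir, f"home_ranges_year{year}.geojson")
        write_geojson(feats, p)
        written.append(p)

        feats = []
        for animal_id, seg in result.perception.get(year, []):
            line = seg.line()
            geom = line if not line.is_empty else Point(seg.origin)
            feats.append(_feature(geom, {"animal": animal_id, "year": year}))
        p = os.path.join(out_dir, f"perception_year{year}.geojson")
        write_geojson(feats, p)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# summaries


def summarize(result: SimulationResult) -> dict:
    """Population summaries per year and overall.

    Mortality rates are fractions of that season's dispersers; cause-specific
    rates partition the overall rate. Energy change, settlement time (active
    steps to settlement) and straight-line dispersal distance (natal origin to
    range center) are reported for settlers only.
    """
    out: dict = {"years": {}}
    totals = {"n": 0, "dead": 0, "predation": 0, "starvation": 0,
              "season_end": 0, "settled": 0}
    all_changes: list[float] = []
    all_steps: list[float] = []
    all_dists: list[float] = []
    for year, animals in sorted(result.animals.items()):
        n = len(animals)
        dead = [a for a in animals if a.status == "dead"]
        settled = [a for a in animals if a.status == "settled"]
        causes = {c: sum(1 for a in dead if a.death_cause == c)
                  for c in ("predation", "starvation", "season_end")}
        ranges = {hr.owner_id: hr for hr in result.home_ranges.get(year, [])}
        changes = [a.energy - a.e_init for a in settled]
        steps = [float(a.settle_step) for a in settled if a.settle_step is not None]
        dists = [math.dist((a.natal_x, a.natal_y), ranges[a.id].center)
                 for a in settled if a.id in ranges]
        yr = {
            "n_dispersers": n,
            "mortality_overall": (len(dead) / n) if n else 0.0,
            "mortality_predation": (causes["predation"] / n) if n else 0.0,
            "mortality_starvation": (causes["starvation"] / n) if n else 0.0,
            "mortality_season_end": (causes["season_end"] / n) if n else 0.0,
            "n_settled": len(settled),
            "energy_change_mean": float(np.mean(changes)) if changes else float("nan"),
            "energy_change_sd": float(np.std(changes, ddof=1)) if len(changes) > 1 else 0.0,
            "settlement_steps_mean": float(np.mean(steps)) if steps else float("nan"),
            "dispersal_distance_mean": float(np.mean(dists)) if dists else float("nan"),
        }
        out["years"][year] = yr
        totals["n"] += n
        totals["dead"] += len(dead)
        totals["settled"] += len(settled)
        for c in ("predation", "starvation", "season_end"):
            totals[c] += causes[c]
        all_changes += changes
        all_steps += steps
        all_dists += dists
    n = totals["n"]
    out["overall"] = {
        "n_dispersers": n,
        "mortality_overall": (totals["dead"] / n) if n else 0.0,
        "mortality_predation": (totals["predation"] / n) if n else 0.0,
        "mortality_starvation": (totals["starvation"] / n) if n else 0.0,
        "mortality_season_end": (totals["season_end"] / n) if n else 0.0,
        "n_settled": totals["settled"],
        "energy_change_mean": float(np.mean(all_changes)) if all_changes else float("nan"),
        "energy_change_sd": float(np.std(all_changes, ddof=1)) if len(all_changes) > 1 else 0.0,
        "settlement_steps_mean": float(np.mean(all_steps)) if all_steps else float("nan"),
        "dispersal_distance_mean": float(np.mean(all_dists)) if all_dists else float("nan"),
    }
    return out


# ---------------------------------------------------------------------------
# synthetic landscapes


@dataclass
class PatchClass:
    """One landscape class with its per-role attributes and sampling weight."""

    name: str
    movement: dict
    food: dict
    risk: dict
    suitability: dict
    weight: float = 1.0
    # optional attribute overrides keyed by variant name, per role, e.g.
    # {"abundant": {"food": {"p_capture": 0.9, "size_mean": 80}}}
    variants: dict = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    extent: tuple[float, float, float, float]  # minx, miny, maxx, maxy
    classes: list[PatchClass]
    tessellation: str = "grid"   # 'grid' | 'voronoi'
    nx: int = 10
    ny: int = 10
    n_patches: int = 50          # voronoi only
    release_points: list = field(default_factory=list)  # (x, y, count, sex|None)


_ROLE_DEFAULTS = {
    "movement": {"step_sd": 0.0, "perception_mod": 1.0},
    "food": {"size_sd": 0.0},
    "risk": {},
    "suitability": {"occupied_male": 0, "occupied_female": 0},
}


def _validate_class(pc: PatchClass) -> None:
    for role in ("movement", "food", "risk", "suitability"):
        attrs = {**_ROLE_DEFAULTS[role], **getattr(pc, role)}
        for name in _RANGES[role]:
            if name not in attrs:
                raise ConfigurationError(
                    f"class {pc.name!r}: missing {role} attribute '{name}'")
            _check_range(role, name, attrs[name], -1)


def _tessellate(spec: SyntheticSpec, rng: np.random.Generator) -> list[Polygon]:
    minx, miny, maxx, maxy = spec.extent
    if spec.tessellation == "grid":
        dx = (maxx - minx) / spec.nx
        dy = (maxy - miny) / spec.ny
        polys = []
        for j in range(spec.ny):
            for i in range(spec.nx):
                polys.append(box(minx + i * dx, miny + j * dy,
                                 minx + (i + 1) * dx, miny + (j + 1) * dy))
        return polys
    if spec.tessellation == "voronoi":
        from shapely.ops import voronoi_diagram
        from shapely.geometry import MultiPoint
        ext = box(*spec.extent)
        pts = MultiPoint([Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
                          for _ in range(spec.n_patches)])
        cells = voronoi_diagram(pts, envelope=ext)
        polys = []
        for cell in cells.geoms:
            clipped = cell.intersection(ext)
            if clipped.is_empty:
                continue
            if isinstance(clipped, MultiPolygon):
                polys.extend(p for p in clipped.geoms if p.area > 0)
            elif clipped.area > 0:
                polys.append(clipped.buffer(0))
        return polys
    raise ConfigurationError(f"unknown tessellation {spec.tessellation!r}")


def generate_synthetic_landscape(spec: SyntheticSpec, seed: int, out_dir: str,
                                 variants: Sequence[str] = ()) -> dict:
    """Write the four parameter maps + release layer for a synthetic landscape.

    Patches are assigned classes by a seeded weighted draw, so the same spec
    and seed always produce byte-identical files. ``variants`` names extra
    per-role map files to emit with class-level attribute overrides applied —
    the inputs of a swap schedule (e.g. a superabundant-food food map).
    Returns {role: path} plus '<role>:<variant>' entries.
    """
    for pc in spec.classes:
        _validate_class(pc)
    rng = np.random.default_rng(seed)
    polys = _tessellate(spec, rng)
    weights = np.array([pc.weight for pc in spec.classes], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(spec.classes), size=len(polys), p=weights)

    os.makedirs(out_dir, exist_ok=True)
    paths: dict = {}

    def emit(role: str, variant: Optional[str]) -> None:
        feats = []
        for poly, ci in zip(polys, assignment):
            pc = spec.classes[ci]
            attrs = {**_ROLE_DEFAULTS[role], **getattr(pc, role)}
            if variant is not None:
                attrs.update((pc.variants.get(variant) or {}).get(role, {}))
            props = {"class": pc.name, **attrs}
            feats.append(_feature(poly, props))
        name = f"{role}.geojson" if variant is None else f"{role}_{variant}.geojson"
        p = os.path.join(out_dir, name)
        write_geojson(feats, p)
        paths[role if variant is None else f"{role}:{variant}"] = p

    for role in ("movement", "food", "risk", "suitability"):
        emit(role, None)
        for v in variants:
            if any(v in pc.variants and role in pc.variants[v]
                   for pc in spec.classes):
                emit(role, v)

    feats = []
    for rp in spec.release_points:
        x, y, count, sex = rp
        props = {"count": count}
        if sex is not None:
            props["sex"] = sex
        feats.append(_feature(Point(x, y), props))
    p = os.path.join(out_dir, "release.geojson")
    write_geojson(feats, p)
    paths["release"] = p
    return paths


def identity_field_maps() -> dict:
    """Field maps for synthetic layers (canonical names used as-is)."""
    return {role: {name: name for name in _RANGES[role]}
            for role in ("movement", "food", "risk", "suitability")}
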