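"""Vector-polygon parameter maps and the time-varying landscape.

Animals respond to four polygon maps — movement, food, risk, suitability —
plus a point map of release locations. Each map is a tessellation of the
landscape extent whose features carry role-specific attributes (wrapped-Cauchy
tortuosity and step lengths on the movement map, prey-capture probability and
prey size on the food map, per-step depredation probability on the risk map,
and suitability/occupancy flags on the suitability map). Any map may be
replaced at scheduled times during a run (map swapping), which is how seasonal
food pulses or day/night predation regimes are represented.

Coordinates are planar meters; layers are assumed pre-projected and no CRS
math is performed. All vector I/O is GeoJSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

from shapely.geometry import Point, Polygon, box, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import (
    ConfigurationError,
    FormatError,
    GeometryError,
    MapValidationError,
    OutOfBoundsError,
)
from .simtime import SimTime

ROLES = ("movement", "food", "risk", "suitability")

# Per-role attribute schema: canonical name -> (lower bound, upper bound).
# None means unbounded on that side. Suitability fields must be exactly 0 or 1.
_RANGES = {
    "movement": {
        "tortuosity": (0.0, 1.0),
        "step_mean": (0.0, None),
        "step_sd": (0.0, None),
        "energy_cost": (0.0, None),
        "crossing": (0.0, None),
        "perception_mod": (0.0, None),
    },
    "food": {
        "p_capture": (0.0, 1.0),
        "size_mean": (0.0, None),
        "size_sd": (0.0, None),
    },
    "risk": {
        "p_mortality": (0.0, 1.0),
    },
    "suitability": {
        "suitable": (0, 1),
        "occupied_male": (0, 1),
        "occupied_female": (0, 1),
    },
}

_FLAG_FIELDS = {"suitable", "occupied_male", "occupied_female"}

COVERAGE_RTOL = 1e-6  # gap tolerance relative to extent area


@dataclass
class MovementAttrs:
    tortuosity: float
    step_mean: float
    step_sd: float
    energy_cost: float
    crossing: float
    perception_mod: float


@dataclass
class FoodAttrs:
    p_capture: float
    size_mean: float
    size_sd: float


@dataclass
class RiskAttrs:
    p_mortality: float


@dataclass
class SuitabilityAttrs:
    suitable: int
    occupied_male: int
    occupied_female: int

    def occupied_by(self, sex: str) -> int:
        return self.occupied_male if sex == "male" else self.occupied_female

    def set_occupied(self, sex: str, value: int) -> None:
        if sex == "male":
            self.occupied_male = value
        else:
            self.occupied_female = value


_ATTR_CLASSES = {
    "movement": MovementAttrs,
    "food": FoodAttrs,
    "risk": RiskAttrs,
    "suitability": SuitabilityAttrs,
}


@dataclass
class ReleasePoint:
    x: float
    y: float
    count: int = 1
    sex: Optional[str] = None  # None -> alternate male/female


def _check_range(role: str, name: str, value: float, feature_id: int) -> None:
    lo, hi = _RANGES[role][name]
    if name in _FLAG_FIELDS:
        if value not in (0, 1):
            raise MapValidationError(
                f"{role} map feature {feature_id}: field '{name}' must be 0 or 1, got {value!r}"
            )
        return
    if not math.isfinite(value):
        raise MapValidationError(
            f"{role} map feature {feature_id}: field '{name}' is not finite"
        )
    if lo is not None and value < lo:
        raise MapValidationError(
            f"{role} map feature {feature_id}: field '{name}' = {value} below {lo}"
        )
    if hi is not None and value > hi:
        raise MapValidationError(
            f"{role} map feature {feature_id}: field '{name}' = {value} above {hi}"
        )


class ParameterMap:
    """A validated polygon tessellation carrying one role's attributes.

    Features are indexed 0..n-1 in file order; that index is the feature id
    used for the shared-edge tie-break (smallest id wins) so that point
    queries are deterministic.
    """

    def __init__(self, role: str, geoms: Sequence[Polygon], attrs: Sequence, *,
                 validate: bool = True) -> None:
        if role not in ROLES:
            raise ConfigurationError(f"unknown map role {role!r}")
        self.role = role
        self.geoms = list(geoms)
        self.attrs = list(attrs)
        minx = min(g.bounds[0] for g in self.geoms)
        miny = min(g.bounds[1] for g in self.geoms)
        maxx = max(g.bounds[2] for g in self.geoms)
        maxy = max(g.bounds[3] for g in self.geoms)
        self.extent = box(minx, miny, maxx, maxy)
        self._tree = STRtree(self.geoms)
        if validate:
            self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Range-check every attribute and verify gap-free coverage.

        Idempotent: validating an already-valid map raises nothing.
        """
        for i, (g, a) in enumerate(zip(self.geoms, self.attrs)):
            if not isinstance(g, Polygon):
                raise FormatError(
                    f"{self.role} map feature {i}: geometry is {g.geom_type}, expected Polygon"
                )
            if not g.is_valid or g.area <= 0:
                raise GeometryError(f"{self.role} map feature {i}: invalid polygon")
            for f in dc_fields(a):
                _check_range(self.role, f.name, getattr(a, f.name), i)
        from shapely.ops import unary_union

        union = unary_union(self.geoms)
        gap = self.extent.area - union.area
        if gap > COVERAGE_RTOL * self.extent.area:
            raise MapValidationError(
                f"{self.role} map does not tessellate its extent: uncovered area {gap:.6g} m^2"
            )

    # -- queries ------------------------------------------------------------

    def feature_at(self, x: float, y: float) -> int:
        """Feature id of the polygon covering (x, y); smallest id on shared edges."""
        p = Point(x, y)
        if not self.extent.covers(p):
            raise OutOfBoundsError(f"point ({x}, {y}) outside {self.role} map extent")
        cand = sorted(self._tree.query(p))
        for i in cand:
            if self.geoms[i].covers(p):
                return int(i)
        # Numerical sliver between polygons: fall back to nearest feature.
        dists = [(self.geoms[i].distance(p), int(i)) for i in cand] or [
            (self.geoms[i].distance(p), int(i)) for i in range(len(self.geoms))
        ]
        return min(dists)[1]

    def attrs_at(self, x: float, y: float):
        return self.attrs[self.feature_at(x, y)]

    def query_intersecting(self, geom: BaseGeometry) -> list[int]:
        return sorted(int(i) for i in self._tree.query(geom)
                      if self.geoms[i].intersects(geom))

    def region_status(self, region: BaseGeometry) -> tuple[float, float, float]:
        """(suitable, male-occupied, female-occupied) areas of ``region`` in m^2.

        Only meaningful for suitability maps.
        """
        if self.role != "suitability":
            raise ConfigurationError("region_status requires a suitability map")
        if not region.is_valid:
            raise GeometryError("region_status: invalid region geometry")
        if region.is_empty:
            return (0.0, 0.0, 0.0)
        suit = occ_m = occ_f = 0.0
        for i in self._tree.query(region):
            inter = self.geoms[i].intersection(region)
            if inter.is_empty:
                continue
            a = self.attrs[i]
            if a.suitable:
                suit += inter.area
            if a.occupied_male:
                occ_m += inter.area
            if a.occupied_female:
                occ_f += inter.area
        return (suit, occ_m, occ_f)


@dataclass(frozen=True)
class SwapEvent:
    at: SimTime
    role: str
    replacement: ParameterMap


@dataclass
class Landscape:
    """Initial maps by role, the swap schedule, and the release points."""

    maps: dict[str, ParameterMap]
    swaps: list[SwapEvent] = field(default_factory=list)
    release_points: list[ReleasePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.swaps = sorted(self.swaps, key=lambda e: (e.at, e.role))
        ext = None
        for role in ROLES:
            if role not in self.maps:
                raise ConfigurationError(f"landscape is missing the {role} map")
            b = self.maps[role].extent.bounds
            if ext is None:
                ext = b
            elif any(abs(a - c) > 1e-6 for a, c in zip(ext, b)):
                raise ConfigurationError(
                    f"{role} map extent {b} differs from {ext}; all maps must share one frame"
                )
        self.extent = self.maps["movement"].extent

    def active_map(self, role: str, t: SimTime) -> ParameterMap:
        """Map in force for ``role`` at time ``t``.

        Piecewise constant and right-continuous: an event applies from exactly
        its timestamp onward.
        """
        current = self.maps[role]
        for ev in self.swaps:
            if ev.role == role and ev.at <= t:
                current = ev.replacement
        return current


# ---------------------------------------------------------------------------
# GeoJSON loading


def _read_feature_collection(path: str) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    return data.get("features", [])


def load_parameter_map(path: str, role: str, field_map: dict[str, str]) -> ParameterMap:
    """Load and validate one polygon parameter map from a GeoJSON file.

    ``field_map`` binds the role's canonical attribute names to the layer's
    property names, so arbitrary user schemas can be used.
    """
    if role not in ROLES:
        raise ConfigurationError(f"unknown map role {role!r}")
    required = list(_RANGES[role])
    for name in required:
        if name not in field_map:
            raise ConfigurationError(
                f"{role} map field mapping is missing required field '{name}'"
            )
    cls = _ATTR_CLASSES[role]
    geoms: list[Polygon] = []
    attrs = []
    for i, feat in enumerate(_read_feature_collection(path)):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise FormatError(
                f"{path} feature {i}: geometry type {geom.geom_type} is not Polygon"
            )
        props = feat.get("properties") or {}
        values = {}
        for name in required:
            src = field_map[name]
            if src not in props:
                raise ConfigurationError(
                    f"{path} feature {i}: missing attribute field '{src}' (bound to '{name}')"
                )
            raw = props[src]
            values[name] = int(raw) if name in _FLAG_FIELDS else float(raw)
            _check_range(role, name, values[name], i)
        geoms.append(geom)
        attrs.append(cls(**values))
    if not geoms:
        raise FormatError(f"{path}: no polygon features")
    return ParameterMap(role, geoms, attrs)


def load_release_points(path: str, field_map: Optional[dict[str, str]] = None
                        ) -> list[ReleasePoint]:
    """Load the release point layer. ``count`` and ``sex`` fields are optional."""
    field_map = field_map or {}
    count_f = field_map.get("count", "count")
    sex_f = field_map.get("sex", "sex")
    out = []
    for i, feat in enumerate(_read_feature_collection(path)):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Point":
            raise FormatError(f"{path} feature {i}: release layer must contain Points")
        props = feat.get("properties") or {}
        count = int(props.get(count_f, 1))
        if count < 1:
            raise ConfigurationError(f"{path} feature {i}: release count must be >= 1")
        sex = props.get(sex_f)
        if sex is not None and sex not in ("male", "female"):
            raise ConfigurationError(f"{path} feature {i}: sex must be 'male' or 'female'")
        out.append(ReleasePoint(geom.x, geom.y, count, sex))
    return out
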