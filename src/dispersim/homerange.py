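"""Home-range establishment: the settlement trigger, candidate-site scoring
under the four selection criteria, stochastic range-polygon generation, and
settlement with same-sex exclusion.

Once a disperser has taken enough active steps (or visited enough suitable,
unoccupied sites), it samples candidate centers from its memory map and
chooses one stochastically, weighting sites by proximity and — depending on
the criterion — food availability (p_capture x prey size) and safety
(1 - p_mortality). The range polygon is a 12-gon with randomly oriented,
Normal-jittered radii sized so the regular polygon attains exactly the
sex-specific minimum area. Settlement succeeds only if the polygon, clipped
to suitable habitat not occupied by the same sex, still covers the center and
holds at least the minimum area — which enforces strictly non-overlapping
home ranges within a sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import DispersimError
from .simtime import SimTime

K_VERTICES = 12
RADIUS_CV = 0.15        # sd of vertex radii as a fraction of the nominal radius
MAX_POLYGON_TRIES = 100
OVERLAP_TOL = 1e-6      # m^2; numeric tolerance on the zero-overlap invariant
CRITERIA = ("closest", "food", "risk", "integrated")


@dataclass
class HomeRange:
    owner_id: int
    sex: str
    center: tuple[float, float]
    polygon: BaseGeometry
    established_at: Optional[SimTime] = None


@dataclass
class CandidateSite:
    x: float
    y: float
    distance: float        # from the animal's current location, m
    food_quality: float    # expected gain p_capture * size_mean at the point
    risk_quality: float    # 1 - p_mortality at the point


class RangeRegistry:
    """Live registry of established ranges; authoritative for same-sex exclusion."""

    def __init__(self) -> None:
        self.ranges: list[HomeRange] = []

    def same_sex_union(self, sex: str) -> BaseGeometry:
        polys = [hr.polygon for hr in self.ranges if hr.sex == sex]
        return unary_union(polys) if polys else Point()

    def add(self, hr: HomeRange, suitability_map) -> None:
        self.ranges.append(hr)
        _mark_occupancy(hr, suitability_map, 1)

    def remove(self, hr: HomeRange, suitability_map) -> None:
        self.remove_many([hr], suitability_map)

    def remove_many(self, dead: Sequence[HomeRange], suitability_map) -> None:
        """Batched removal: clear the dead ranges' occupancy, then re-flag
        surviving same-sex ranges that still cover the cleared features."""
        if not dead:
            return
        dead_ids = {id(h) for h in dead}
        self.ranges = [h for h in self.ranges if id(h) not in dead_ids]
        sexes = set()
        for hr in dead:
            _mark_occupancy(hr, suitability_map, 0)
            sexes.add(hr.sex)
        dead_bounds = [h.polygon.bounds for h in dead]
        for other in self.ranges:
            if other.sex in sexes and _bbox_overlaps_any(other.polygon.bounds,
                                                         dead_bounds):
                _mark_occupancy(other, suitability_map, 1)

    def remark(self, suitability_map) -> None:
        """Re-apply occupancy flags (used after a suitability-map swap)."""
        for hr in self.ranges:
            _mark_occupancy(hr, suitability_map, 1)


def _bbox_overlaps_any(b, others) -> bool:
    minx, miny, maxx, maxy = b
    return any(not (maxx < o[0] or o[2] < minx or maxy < o[1] or o[3] < miny)
               for o in others)


def _mark_occupancy(hr: HomeRange, suitability_map, value: int) -> None:
    for i in suitability_map.query_intersecting(hr.polygon):
        inter = suitability_map.geoms[i].intersection(hr.polygon)
        if inter.area > OVERLAP_TOL:
            suitability_map.attrs[i].set_occupied(hr.sex, value)


def trigger_reached(animal, mode: str, threshold: int) -> bool:
    """Has the animal earned the right to start choosing home-range centers?

    'steps' mode counts active steps since dispersal began; 'sites' mode
    counts distinct suitability polygons entered that were suitable and not
    same-sex-occupied at entry.
    """
    if threshold < 1:
        raise ValueError("trigger threshold must be >= 1")
    if mode == "steps":
        return animal.steps_taken >= threshold
    if mode == "sites":
        return animal.sites_visited >= threshold
    raise ValueError(f"unknown trigger mode {mode!r}")


def score_candidates(candidates: Sequence[CandidateSite], criterion: str,
                     w: float, rng: np.random.Generator) -> Optional[CandidateSite]:
    """Choose a home-range center from the candidate set.

    Each site gets weight W = Q * exp(-d / w): proximity always discounts
    exponentially with the distance-weighting factor w (a very large w
    negates proximity entirely), and Q carries the criterion — 1 for
    'closest', max-normalized food quality for 'food', max-normalized safety
    for 'risk', or their product for 'integrated'. The site is SAMPLED with
    probability proportional to W, so selection is weighted toward better
    sites but stochastic. Returns None for an empty candidate set (the animal
    keeps dispersing).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if w <= 0:
        raise ValueError("distance weighting factor must be > 0")
    if not candidates:
        return None
    food_max = max((c.food_quality for c in candidates), default=0.0)
    risk_max = max((c.risk_quality for c in candidates), default=0.0)
    weights = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        q = 1.0
        if criterion in ("food", "integrated"):
            q *= (c.food_quality / food_max) if food_max > 0 else 1.0
        if criterion in ("risk", "integrated"):
            q *= (c.risk_quality / risk_max) if risk_max > 0 else 1.0
        weights[i] = q * math.exp(-c.distance / w)
    total = weights.sum()
    if total <= 0:
        idx = int(rng.integers(len(candidates)))
    else:
        idx = int(rng.choice(len(candidates), p=weights / total))
    return candidates[idx]


def nominal_radius(a_min: float, k: int = K_VERTICES) -> float:
    """Radius at which a regular k-gon attains exactly area ``a_min``."""
    return math.sqrt(2.0 * a_min / (k * math.sin(2.0 * math.pi / k)))


def generate_polygon(center: tuple[float, float], a_min: float,
                     rng: np.random.Generator, radius_cv: float = RADIUS_CV) -> Polygon:
    """Stochastic home-range polygon around ``center``.

    12 vertices at a uniformly rotated equal angular spacing, radii drawn
    Normal(r0, cv*r0) truncated positive, with r0 chosen so the regular
    polygon has exactly ``a_min`` area. Regenerated (<= 100 tries) until the
    polygon is simple and at least ``a_min`` in area.
    """
    if a_min <= 0:
        raise ValueError("minimum home-range area must be > 0")
    r0 = nominal_radius(a_min)
    cx, cy = center
    for _ in range(MAX_POLYGON_TRIES):
        offset = rng.uniform(0.0, 2.0 * math.pi)
        angles = np.sort((offset + 2.0 * math.pi * np.arange(K_VERTICES) / K_VERTICES)
                         % (2.0 * math.pi))
        if radius_cv > 0:
            radii = rng.normal(r0, radius_cv * r0, size=K_VERTICES)
            for j in range(K_VERTICES):  # truncate strictly positive by redraw
                while radii[j] <= 0:
                    radii[j] = rng.normal(r0, radius_cv * r0)
        else:
            radii = np.full(K_VERTICES, r0)
        pts = [(cx + r * math.cos(a), cy + r * math.sin(a))
               for r, a in zip(radii, angles)]
        poly = Polygon(pts)
        if poly.is_valid and poly.area >= a_min * (1.0 - 1e-9):
            return poly
    raise DispersimError("home-range polygon generation failed after 100 tries")


def attempt_settlement(animal, site: CandidateSite, suitability_map,
                       registry: RangeRegistry, a_min: float,
                       rng: np.random.Generator, t: Optional[SimTime] = None
                       ) -> Optional[HomeRange]:
    """Try to establish a home range centered at ``site``.

    A polygon is generated at the site and clipped to suitable habitat not
    occupied by the same sex (per the live registry). Settlement succeeds iff
    the usable region still covers the center and holds >= a_min; the range
    then enters the registry and flags occupancy on the suitability map.
    Returns the HomeRange, or None on rejection (the caller resumes
    dispersal and marks the site ineligible in memory).
    """
    center = (site.x, site.y)
    poly = generate_polygon(center, a_min, rng)
    suitable_ids = [i for i in suitability_map.query_intersecting(poly)
                    if suitability_map.attrs[i].suitable]
    if not suitable_ids:
        return None
    usable = poly.intersection(
        unary_union([suitability_map.geoms[i] for i in suitable_ids]))
    occupied = registry.same_sex_union(animal.sex)
    if not occupied.is_empty:
        usable = usable.difference(occupied)
    if usable.is_empty or usable.area < a_min - OVERLAP_TOL:
        return None
    if not usable.covers(Point(center)):
        return None
    hr = HomeRange(owner_id=animal.id, sex=animal.sex, center=center,
                   polygon=usable, established_at=t)
    registry.add(hr, suitability_map)
    return hr


def establish_resident_range(center: tuple[float, float], sex: str, a_min: float,
                             suitability_map, registry: RangeRegistry,
                             rng: np.random.Generator, owner_id: int) -> HomeRange:
    """Generate a resident's range at a roster center during initialization.

    Residents are assumed already established, so the polygon is clipped only
    against previously placed same-sex residents (not against suitability) to
    keep roster-driven setups robust on arbitrary landscapes.
    """
    poly = generate_polygon(center, a_min, rng)
    occupied = registry.same_sex_union(sex)
    usable = poly if occupied.is_empty else poly.difference(occupied)
    hr = HomeRange(owner_id=owner_id, sex=sex, center=center, polygon=usable)
    registry.add(hr, suitability_map)
    return hr


def end_of_season(animals: Sequence, t: SimTime) -> None:
    """Every animal still dispersing when the season closes dies (season_end)."""
    from .agents import DISPERSING, SEASON_END

    for a in animals:
        if a.status == DISPERSING:
            a.die(SEASON_END, t)
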