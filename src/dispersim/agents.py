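"""Agent state: dispersers, residents, the perception memory map, and
population initialization under the three starting scenarios.

A disperser is a juvenile searching for a home range. It carries an energy
ledger (initial/floor/ceiling), a correlated-random-walk heading, two
behavioural axes (activity mode searching/foraging, vigilance risky/safe), an
activity/rest bout schedule, and a memory map — the cumulative, time-stamped
record of every region it has perceived, with latest-observation-wins
semantics. Memory is what the animal consults when it starts choosing
home-range centers: candidate points are drawn only from remembered regions
whose most recent status was suitable and not occupied by the same sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigurationError, GeometryError, SchedulingError
from .simtime import SimTime

MALE = "male"
FEMALE = "female"

DISPERSING = "dispersing"
SETTLED = "settled"
DEAD = "dead"

STARVATION = "starvation"
PREDATION = "predation"
SEASON_END = "season_end"

REJECTION_CAP = 10_000  # rejection-sampling tries per candidate point


@dataclass
class MemoryRecord:
    t: SimTime
    region: BaseGeometry
    suitable: bool
    occupied_male: bool
    occupied_female: bool


class MemoryMap:
    """Append-only, time-ordered record of perceived regions.

    The effective status at a point is the status of the LATEST record whose
    region covers that point; revisits overwrite earlier perception.
    """

    def __init__(self) -> None:
        self.records: list[MemoryRecord] = []
        # Incrementally maintained eligible-region cache per sex. Latest-wins
        # makes the update exact: the new record's region first masks the old
        # eligible region, then rejoins it if its status qualifies.
        self._eligible_cache: dict[str, BaseGeometry] = {MALE: Point(),
                                                         FEMALE: Point()}

    def remember(self, region: BaseGeometry, *, suitable: bool, occupied_male: bool,
                 occupied_female: bool, t: SimTime) -> None:
        if region.is_empty:
            return
        if not region.is_valid:
            raise GeometryError("memory region is invalid")
        if self.records and t < self.records[-1].t:
            raise SchedulingError(
                f"memory record at {t} precedes last record at {self.records[-1].t}"
            )
        self.records.append(
            MemoryRecord(t, region, bool(suitable), bool(occupied_male), bool(occupied_female))
        )
        for sex, geom in self._eligible_cache.items():
            occupied = occupied_male if sex == MALE else occupied_female
            masked = geom.difference(region)
            if suitable and not occupied:
                masked = masked.union(region)
            self._eligible_cache[sex] = masked

    def status_at(self, x: float, y: float) -> Optional[MemoryRecord]:
        """Latest record covering (x, y), or None if the point was never seen."""
        p = Point(x, y)
        for rec in reversed(self.records):
            if rec.region.covers(p):
                return rec
        return None

    def eligible_region(self, sex: str) -> BaseGeometry:
        """Union of remembered area whose EFFECTIVE status is suitable and not
        occupied by ``sex``.

        Built by sweeping records newest-first and masking each region by
        everything recorded later, which realises latest-wins exactly. The
        result is cached per sex and maintained incrementally by remember().
        """
        if sex in self._eligible_cache:
            return self._eligible_cache[sex]
        eligible = []
        covered = None
        for rec in reversed(self.records):
            fresh = rec.region if covered is None else rec.region.difference(covered)
            if not fresh.is_empty:
                occupied = rec.occupied_male if sex == MALE else rec.occupied_female
                if rec.suitable and not occupied:
                    eligible.append(fresh)
            covered = rec.region if covered is None else covered.union(rec.region)
        result = unary_union(eligible) if eligible else Point()
        self._eligible_cache[sex] = result
        return result

    def candidate_points(self, sex: str, n: int, rng: np.random.Generator
                         ) -> list[tuple[float, float]]:
        """Up to ``n`` points uniform on the eligible remembered region.

        Rejection-sampled from the region's bounding box; a point whose draw
        budget is exhausted is skipped, so fewer than ``n`` points may return.
        Empty eligible region -> empty list.
        """
        import shapely

        region = self.eligible_region(sex)
        if region.is_empty or region.area <= 0:
            return []
        minx, miny, maxx, maxy = region.bounds
        pts: list[tuple[float, float]] = []
        batch = max(4 * n, 64)
        draws = 0
        while len(pts) < n and draws < n * REJECTION_CAP:
            xs = rng.uniform(minx, maxx, size=batch)
            ys = rng.uniform(miny, maxy, size=batch)
            draws += batch
            inside = shapely.intersects_xy(region, xs, ys)
            for x, y in zip(xs[inside], ys[inside]):
                pts.append((float(x), float(y)))
                if len(pts) == n:
                    break
        return pts


@dataclass
class Disperser:
    id: int
    sex: str
    energy: float
    e_init: float
    e_min: float
    e_max: float
    x: float
    y: float
    heading: float = 0.0
    activity_mode: str = "searching"
    vigilance: str = "risky"
    steps_taken: int = 0
    sites_visited: int = 0
    memory: MemoryMap = field(default_factory=MemoryMap)
    status: str = DISPERSING
    death_cause: Optional[str] = None
    death_time: Optional[SimTime] = None
    natal_x: float = 0.0
    natal_y: float = 0.0
    visited_site_ids: set = field(default_factory=set)
    settle_time: Optional[SimTime] = None
    settle_step: Optional[int] = None
    bouts: Optional[object] = None  # BoutSchedule, attached by the engine
    path_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.e_min < self.e_init <= self.e_max):
            raise ConfigurationError(
                f"energy bounds must satisfy E_min < E0 <= E_max, got "
                f"{self.e_min} / {self.e_init} / {self.e_max}"
            )

    @property
    def alive(self) -> bool:
        return self.status != DEAD

    def die(self, cause: str, t: SimTime) -> None:
        self.status = DEAD
        self.death_cause = cause
        self.death_time = t


@dataclass
class Resident:
    id: int
    sex: str
    home_range: "object"  # homerange.HomeRange


def initialize_population(landscape, scenario: str, cfg, rng: np.random.Generator,
                          registry=None) -> tuple[list[Resident], list[Disperser]]:
    """Build the year-1 population for one of the three starting scenarios.

    release_only    — dispersers created at the release points; no residents.
    residents_only  — residents with generated home ranges at the roster
                      centers; the first dispersers arise from breeding.
    combined        — both.
    """
    from . import homerange as hr

    if scenario not in ("release_only", "residents_only", "combined"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    registry = registry if registry is not None else hr.RangeRegistry()
    residents: list[Resident] = []
    dispersers: list[Disperser] = []

    want_residents = scenario in ("residents_only", "combined")
    want_release = scenario in ("release_only", "combined")

    roster = list(getattr(cfg, "resident_roster", []) or [])
    releases = list(landscape.release_points or [])
    if want_release and scenario == "release_only" and not releases:
        raise ConfigurationError("release_only scenario requires a non-empty release layer")
    if want_residents and scenario == "residents_only" and not roster:
        raise ConfigurationError("residents_only scenario requires a resident roster")
    if scenario == "combined" and not roster and not releases:
        raise ConfigurationError("combined scenario with no residents and no releases")

    suit_map = landscape.maps["suitability"]
    next_id = 1
    if want_residents:
        for entry in roster:
            sex = entry["sex"]
            a_min = cfg.a_min[sex]
            center = (float(entry["x"]), float(entry["y"]))
            home = hr.establish_resident_range(center, sex, a_min, suit_map,
                                               registry, rng, owner_id=next_id)
            residents.append(Resident(next_id, sex, home))
            next_id += 1

    if want_release:
        flip = 0
        for rp in releases:
            for k in range(rp.count):
                if rp.sex is not None:
                    sex = rp.sex
                else:
                    sex = MALE if flip % 2 == 0 else FEMALE
                    flip += 1
                dispersers.append(Disperser(
                    id=next_id, sex=sex, energy=cfg.e_init, e_init=cfg.e_init,
                    e_min=cfg.e_min, e_max=cfg.e_max, x=rp.x, y=rp.y,
                    natal_x=rp.x, natal_y=rp.y,
                    heading=rng.uniform(-np.pi, np.pi),
                ))
                next_id += 1
    return residents, dispersers
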