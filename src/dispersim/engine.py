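"""Run orchestration: the discrete clock, the fixed per-step pipeline, animal
ordering, the season/year loop, and the single seeded random stream.

Every source of randomness in a run is drawn from one numpy Generator in a
fixed order, so (config, seed) fully determines every output byte. Animals
are processed sequentially each step in the order of ids reassigned
geographically (north->south, then west->east) at the start of each year.

The per-step sub-pipeline for each disperser is:

  1. bout check (resting animals log and stop)
  2. modifier resolution at the current location
  3. vigilance draw
  4. activity-mode check against the forage/search energy threshold
  5. movement (turn, step, boundary decisions, extent reflection)
  6. energy cost        \
  7. foraging gain       } one ledger update, starvation evaluated after both
  8. starvation check   /
  9. predation draw
 10. perception: memory update and sites-visited accounting
 11. settlement trigger -> candidate scoring -> settlement attempt
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import behavior, demography, forage_risk, homerange, movement
from .agents import (DEAD, DISPERSING, SETTLED, Disperser, Resident,
                     initialize_population)
from .behavior import Modifier, ModifierSet
from .errors import ConfigurationError
from .landscape import (Landscape, SwapEvent, load_parameter_map,
                        load_release_points)
from .simtime import SimTime, clock_at

LOG_COLUMNS = ["year", "day", "step", "animal_id", "sex", "x", "y", "energy",
               "active", "activity_mode", "vigilance", "status", "death_cause",
               "settled"]

CANDIDATE_N = 30  # candidate points drawn from memory per settlement attempt


@dataclass
class SimConfig:
    """Full parameterization of a run (time model, species and behaviour
    parameters, home-range and demography settings, maps, seed)."""

    # time model
    years: int = 1
    season_days: int = 1
    step_minutes: int = 60
    start_hour: int = 0
    start_date: str = ""
    scenario: str = "release_only"
    # species energetics / perception / vigilance
    e_init: float = 100.0
    e_min: float = 0.0
    e_max: float = 200.0
    forage_threshold: Optional[float] = None
    perception_radius: float = 100.0
    p_risky_to_safe: float = 0.0
    p_safe_to_risky: float = 0.0
    # activity bouts (hours)
    active_mean_h: float = 24.0
    active_sd_h: float = 0.0
    rest_mean_h: float = 0.0
    rest_sd_h: float = 0.0
    # home range
    trigger_mode: str = "steps"
    trigger_threshold: int = 100
    criterion: str = "closest"
    distance_weight: dict = field(default_factory=lambda: {"male": 1000.0, "female": 1000.0})
    a_min: dict = field(default_factory=lambda: {"male": 1e4, "female": 1e4})
    # demography
    resident_step_mortality: float = 0.0
    interdispersal_mortality: float = 0.0
    p_pregnant: float = 0.0
    litter_mean: float = 0.0
    litter_sd: float = 0.0
    p_female: float = 0.5
    resident_roster: list = field(default_factory=list)
    # behaviour modifiers
    modifiers: Optional[ModifierSet] = None
    modifiers_enabled: bool = True
    # maps (paths + field maps + swap schedule) — optional if a Landscape is
    # passed to run() directly
    map_paths: dict = field(default_factory=dict)
    field_maps: dict = field(default_factory=dict)
    release_path: Optional[str] = None
    release_fields: dict = field(default_factory=dict)
    swap_schedule: list = field(default_factory=list)  # {year, day, hour, role, path}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1 or self.season_days < 1 or self.step_minutes < 1:
            raise ConfigurationError("years, season_days and step_minutes must be >= 1")
        if not 0 <= self.start_hour <= 23:
            raise ConfigurationError("start_hour must be in [0, 23]")
        if not (self.e_min < self.e_init <= self.e_max):
            raise ConfigurationError("energy bounds must satisfy E_min < E0 <= E_max")
        for p in (self.p_risky_to_safe, self.p_safe_to_risky,
                  self.resident_step_mortality, self.interdispersal_mortality,
                  self.p_pregnant, self.p_female):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        if self.trigger_mode not in ("steps", "sites"):
            raise ConfigurationError("trigger_mode must be 'steps' or 'sites'")
        if self.criterion not in homerange.CRITERIA:
            raise ConfigurationError(f"criterion must be one of {homerange.CRITERIA}")
        for sex in ("male", "female"):
            if self.a_min.get(sex, 0) <= 0:
                raise ConfigurationError("minimum home-range areas must be > 0")
            if self.distance_weight.get(sex, 0) <= 0:
                raise ConfigurationError("distance weighting factors must be > 0")

    @property
    def steps_per_season(self) -> int:
        return (self.season_days * 1440) // self.step_minutes

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kw: dict = {}
        time = raw.get("time", {})
        for k in ("years", "season_days", "step_minutes", "start_hour", "start_date"):
            if k in time:
                kw[k] = time[k]
        kw["scenario"] = raw.get("scenario", "release_only")
        for section in ("species", "behavior", "homerange", "demography"):
            for k, v in (raw.get(section) or {}).items():
                kw[k] = v
        mods = [Modifier(m["parameter"], m["kind"],
                         tuple(m["key"]) if isinstance(m["key"], list) else m["key"],
                         float(m["multiplier"]))
                for m in (raw.get("modifiers") or [])]
        if mods:
            kw["modifiers"] = ModifierSet(mods)
        maps = raw.get("maps") or {}
        kw["map_paths"] = {r: maps[r]["path"] for r in maps if r != "release"}
        kw["field_maps"] = {r: maps[r].get("fields", {}) for r in maps if r != "release"}
        if "release" in maps:
            kw["release_path"] = maps["release"]["path"]
            kw["release_fields"] = maps["release"].get("fields", {})
        kw["swap_schedule"] = raw.get("swaps", []) or []
        if "roster" in raw:
            kw["resident_roster"] = raw["roster"]
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        return cls(**kw)


def load_landscape(cfg: SimConfig) -> Landscape:
    """Load and validate all maps, the release layer, and the swap schedule."""
    maps = {}
    for role in ("movement", "food", "risk", "suitability"):
        if role not in cfg.map_paths:
            raise ConfigurationError(f"config is missing the {role} map path")
        maps[role] = load_parameter_map(cfg.map_paths[role], role,
                                        cfg.field_maps.get(role, {}))
    releases = (load_release_points(cfg.release_path, cfg.release_fields)
                if cfg.release_path else [])
    swaps = []
    for ev in cfg.swap_schedule:
        rep = load_parameter_map(ev["path"], ev["role"],
                                 cfg.field_maps.get(ev["role"], {}))
        swaps.append(SwapEvent(SimTime(int(ev.get("year", 1)), int(ev["day"]),
                                       float(ev["hour"])), ev["role"], rep))
    return Landscape(maps=maps, swaps=swaps, release_points=releases)


@dataclass
class SimulationResult:
    log_rows: list
    home_ranges: dict          # year -> list[HomeRange]
    perception: dict           # year -> list[(animal_id, geometry)]
    animals: dict              # year -> list[Disperser] (final states)
    summary: Optional[dict] = None


def order_animals(dispersers: list[Disperser], start_id: int = 1) -> list[Disperser]:
    """Reassign ids geographically — north to south, ties west to east — and
    return the processing order. Input order is immaterial."""
    ordered = sorted(dispersers, key=lambda a: (-a.y, a.x))
    for i, a in enumerate(ordered):
        a.id = start_id + i
    return ordered


def _log_row(animal: Disperser, t: SimTime, step: int, active: bool) -> list:
    return [t.year, t.day, step, animal.id, animal.sex,
            round(animal.x, 6), round(animal.y, 6), round(animal.energy, 6),
            int(active), animal.activity_mode, animal.vigilance,
            animal.status, animal.death_cause or "", int(animal.status == SETTLED)]


def step_animal(animal: Disperser, landscape: Landscape, cfg: SimConfig,
                t: SimTime, elapsed_min: float, step: int,
                rng: np.random.Generator, registry: homerange.RangeRegistry,
                log_rows: list) -> None:
    """Run the fixed 11-stage pipeline for one animal at one time-step."""
    # (1) bout check
    if animal.bouts is not None and not animal.bouts.is_active(elapsed_min):
        log_rows.append(_log_row(animal, t, step, active=False))
        return

    move_map = landscape.active_map("movement", t)
    food_map = landscape.active_map("food", t)
    risk_map = landscape.active_map("risk", t)
    suit_map = landscape.active_map("suitability", t)

    # all per-step map queries anchor at the step's origin
    move_attrs = move_map.attrs_at(animal.x, animal.y)
    food_attrs = food_map.attrs_at(animal.x, animal.y)
    risk_attrs = risk_map.attrs_at(animal.x, animal.y)

    # (2) modifier resolution
    mods = cfg.modifiers if (cfg.modifiers_enabled and cfg.modifiers) else None
    eff = behavior.resolve(move_attrs, food_attrs, risk_attrs, mods, animal, t,
                           cfg.perception_radius)

    # (3) vigilance draw
    behavior.update_vigilance(animal, cfg.p_risky_to_safe, cfg.p_safe_to_risky, rng)

    # (4) activity mode vs energy threshold
    behavior.update_activity_mode(animal, cfg.forage_threshold)

    # (5) movement
    seg = movement.advance(animal, move_map, eff, rng)
    animal.steps_taken += 1

    # (6)-(8) energy ledger, starvation evaluated once
    gain = forage_risk.forage(eff, food_attrs, rng)
    forage_risk.apply_energy(animal, eff.energy_cost, gain, t)
    if animal.status == DEAD:
        log_rows.append(_log_row(animal, t, step, active=True))
        return

    # (9) predation
    if forage_risk.predation_draw(eff, rng):
        animal.die("predation", t)
        log_rows.append(_log_row(animal, t, step, active=True))
        return

    # (10) perception -> memory; sites-visited accounting
    window = movement.perception_polygon(seg, eff.perception_radius)
    animal.path_points.extend(seg.points)
    if not window.is_empty and window.area > 0:
        for i in suit_map.query_intersecting(window):
            a = suit_map.attrs[i]
            region = suit_map.geoms[i].intersection(window)
            if region.is_empty:
                continue
            animal.memory.remember(region, suitable=bool(a.suitable),
                                   occupied_male=bool(a.occupied_male),
                                   occupied_female=bool(a.occupied_female), t=t)
    here = suit_map.feature_at(animal.x, animal.y)
    if here not in animal.visited_site_ids:
        animal.visited_site_ids.add(here)
        a = suit_map.attrs[here]
        if a.suitable and not a.occupied_by(animal.sex):
            animal.sites_visited += 1

    # (11) settlement
    if homerange.trigger_reached(animal, cfg.trigger_mode, cfg.trigger_threshold):
        _attempt_settlement(animal, landscape, cfg, t, step, rng, registry,
                            food_map, risk_map, suit_map)

    log_rows.append(_log_row(animal, t, step, active=True))


def _attempt_settlement(animal, landscape, cfg, t, step, rng, registry,
                        food_map, risk_map, suit_map) -> None:
    pts = animal.memory.candidate_points(animal.sex, CANDIDATE_N, rng)
    if not pts:
        return
    candidates = []
    for (x, y) in pts:
        fa = food_map.attrs_at(x, y)
        ra = risk_map.attrs_at(x, y)
        candidates.append(homerange.CandidateSite(
            x=x, y=y, distance=math.dist((animal.x, animal.y), (x, y)),
            food_quality=fa.p_capture * fa.size_mean,
            risk_quality=1.0 - ra.p_mortality))
    site = homerange.score_candidates(candidates, cfg.criterion,
                                      cfg.distance_weight[animal.sex], rng)
    if site is None:
        return
    # the animal relocates to the chosen center before attempting
    animal.x, animal.y = site.x, site.y
    hr = homerange.attempt_settlement(animal, site, suit_map, registry,
                                      cfg.a_min[animal.sex], rng, t)
    if hr is not None:
        animal.status = SETTLED
        animal.settle_time = t
        animal.settle_step = animal.steps_taken
    else:
        # mark the failed site ineligible in memory: the area the range
        # would have needed is remembered as unsuitable
        r = math.sqrt(cfg.a_min[animal.sex] / math.pi)
        from shapely.geometry import Point as _P
        animal.memory.remember(_P(site.x, site.y).buffer(r), suitable=False,
                               occupied_male=False, occupied_female=False, t=t)


def run(cfg: SimConfig, landscape: Optional[Landscape] = None) -> SimulationResult:
    """Execute a full simulation and return logs, layers and final states."""
    if landscape is None:
        landscape = load_landscape(cfg)
    rng = np.random.default_rng(cfg.seed)
    registry = homerange.RangeRegistry()
    residents, dispersers = initialize_population(landscape, cfg.scenario, cfg,
                                                  rng, registry)
    log_rows: list = []
    result = SimulationResult(log_rows=log_rows, home_ranges={}, perception={},
                              animals={})
    horizon = cfg.season_days * 1440.0
    next_id = (max((r.id for r in residents), default=0)
               + len(dispersers) + 1)
    offspring: list = []

    for year in range(1, cfg.years + 1):
        if year > 1:
            dispersers = [Disperser(id=0, sex=o.sex, energy=cfg.e_init,
                                    e_init=cfg.e_init, e_min=cfg.e_min,
                                    e_max=cfg.e_max, x=o.natal_x, y=o.natal_y,
                                    natal_x=o.natal_x, natal_y=o.natal_y,
                                    heading=rng.uniform(-np.pi, np.pi))
                          for o in offspring]
        ordered = order_animals(dispersers, start_id=1)
        for a in ordered:
            a.bouts = behavior.schedule_bouts(
                cfg.active_mean_h, cfg.active_sd_h, cfg.rest_mean_h,
                cfg.rest_sd_h, cfg.start_hour, horizon, cfg.step_minutes, rng)

        last_suit = landscape.active_map("suitability", SimTime(year, 1, 0.0))
        for step in range(cfg.steps_per_season):
            t = clock_at(step, cfg.step_minutes, cfg.start_hour, year)
            suit_now = landscape.active_map("suitability", t)
            if suit_now is not last_suit:
                registry.remark(suit_now)  # carry occupancy across a swap
                last_suit = suit_now
            residents = forage_risk.resident_step_mortality(
                residents, cfg.resident_step_mortality, rng, registry, suit_now)
            elapsed = step * cfg.step_minutes
            for animal in ordered:
                if animal.status == DISPERSING:
                    step_animal(animal, landscape, cfg, t, elapsed, step, rng,
                                registry, log_rows)

        t_end = clock_at(cfg.steps_per_season, cfg.step_minutes, cfg.start_hour, year)
        homerange.end_of_season(ordered, t_end)
        for a in ordered:
            if a.status == SETTLED:
                hr = next(h for h in registry.ranges
                          if h.owner_id == a.id and h.established_at is not None
                          and h.established_at.year == year)
                residents.append(Resident(next_id, a.sex, hr))
                next_id += 1

        result.animals[year] = list(ordered)
        result.home_ranges[year] = list(registry.ranges)
        result.perception[year] = [
            (a.id, movement.PathSegment(a.path_points[0], a.path_points[1:-1],
                                        a.path_points[-1], a.heading))
            for a in ordered if len(a.path_points) >= 1]

        # inter-dispersal period: one discrete step of survival then breeding
        suit_now = landscape.active_map("suitability", t_end)
        residents = demography.interdispersal_survival(
            residents, cfg.interdispersal_mortality, rng, registry, suit_now)
        offspring = demography.breed(
            [r for r in residents if r.sex == "female"], cfg.p_pregnant,
            cfg.litter_mean, cfg.litter_sd, cfg.p_female, rng)

    return result
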