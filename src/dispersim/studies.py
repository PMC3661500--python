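"""Packaged synthetic study conditions.

Two ready-made experimental setups mirror the mechanisms the simulator is
designed to expose, at desk scale on synthetic landscapes:

* ``food_swap``     — a raccoon-style seasonal food pulse: the food map is
  scarce for 37 days, superabundant for 76 days, then scarce again. Suitable
  den patches are sparse, so settlement times spread across the first swap
  and the net energy of early vs late settlers diverges.
* ``threshold_study`` — a marten-style forage/search energy threshold:
  animals below the threshold switch to foraging mode, where a behavioural
  modifier quadruples capture success, so energies oscillate around the
  threshold instead of declining.

Both use field-plausible raccoon/marten energetics (3750/1800/10000 and
4548/.../5003 energy units, 12 h nocturnal activity or 4.5 h/7.5 h bouts,
triggers of 168 and 270 active steps) on landscapes small enough to run in
seconds.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import box

from .behavior import Modifier, ModifierSet
from .engine import SimConfig
from .landscape import (FoodAttrs, Landscape, MovementAttrs, ParameterMap,
                        ReleasePoint, RiskAttrs, SuitabilityAttrs)
from .simtime import SimTime
from .landscape import SwapEvent


def _grid(extent, nx, ny):
    minx, miny, maxx, maxy = extent
    dx, dy = (maxx - minx) / nx, (maxy - miny) / ny
    return [box(minx + i * dx, miny + j * dy,
                minx + (i + 1) * dx, miny + (j + 1) * dy)
            for j in range(ny) for i in range(nx)]


def _uniform_movement(geoms, **over):
    base = dict(tortuosity=0.5, step_mean=100.0, step_sd=20.0,
                energy_cost=10.0, crossing=1.0, perception_mod=1.0)
    base.update(over)
    return ParameterMap("movement", geoms, [MovementAttrs(**base) for _ in geoms])


# ---------------------------------------------------------------------------
# food-map swap study


def food_swap_landscape(seed: int = 2, n_animals: int = 20) -> Landscape:
    """4 km x 4 km agricultural matrix, 10 x 10 patches, 8 suitable woodlots.

    Food is scarce (p_capture 0.18, prey 10) at season start, superabundant
    (p_capture 0.9) from day 38 through day 113, then scarce again — the
    37/76/37-day schedule. Net energy per active step is slightly negative in
    scarcity and strongly positive in superabundance.
    """
    cells = _grid((0, 0, 4000, 4000), 10, 10)
    rng = np.random.default_rng(seed)
    suitable = set(int(i) for i in rng.choice(len(cells), size=8, replace=False))
    move = _uniform_movement(cells, tortuosity=0.4, step_mean=120.0,
                             step_sd=30.0, energy_cost=2.0)
    scarce = ParameterMap("food", cells, [FoodAttrs(0.18, 10.0, 0.0) for _ in cells])
    rich = ParameterMap("food", cells, [FoodAttrs(0.9, 10.0, 0.0) for _ in cells])
    risk = ParameterMap("risk", cells, [RiskAttrs(0.0) for _ in cells])
    suit = ParameterMap("suitability", cells,
                        [SuitabilityAttrs(int(i in suitable), 0, 0)
                         for i in range(len(cells))])
    return Landscape(
        maps={"movement": move, "food": scarce, "risk": risk,
              "suitability": suit},
        swaps=[SwapEvent(SimTime(1, 38, 0.0), "food", rich),
               SwapEvent(SimTime(1, 114, 0.0), "food", scarce)],
        release_points=[ReleasePoint(2000.0, 2000.0, n_animals, None)],
    )


def food_swap_config(seed: int = 1, season_days: int = 150,
                     modifiers: ModifierSet | None = None) -> SimConfig:
    """Raccoon-frame configuration: 150-day season, 1-h steps, nocturnal
    12 h activity from 18:00, trigger 168 active steps, energy 3750/1800/10000."""
    return SimConfig(
        years=1, season_days=season_days, step_minutes=60, start_hour=18,
        scenario="release_only",
        e_init=3750.0, e_min=1800.0, e_max=10_000.0,
        perception_radius=30.0,
        active_mean_h=12.0, rest_mean_h=12.0,
        trigger_mode="steps", trigger_threshold=168, criterion="integrated",
        distance_weight={"male": 1000.0, "female": 1000.0},
        a_min={"male": 5e4, "female": 5e4},
        modifiers=modifiers, seed=seed,
    )


# ---------------------------------------------------------------------------
# forage/search threshold study


def threshold_landscape(n_animals: int = 12) -> Landscape:
    """Homogeneous suitable 5 km x 5 km map: cost 10/step, searching-mode
    expected gain 5/step (p 0.2 x prey 25), so searching loses energy."""
    ext = box(0, 0, 5000, 5000)
    geoms = [ext]
    return Landscape(maps={
        "movement": _uniform_movement(geoms),
        "food": ParameterMap("food", geoms, [FoodAttrs(0.2, 25.0, 0.0)]),
        "risk": ParameterMap("risk", geoms, [RiskAttrs(0.0)]),
        "suitability": ParameterMap("suitability", geoms,
                                    [SuitabilityAttrs(1, 0, 0)]),
    }, release_points=[ReleasePoint(2500.0, 2500.0, n_animals, None)])


def foraging_boost_modifiers(factor: float = 4.0) -> ModifierSet:
    """Foraging mode multiplies capture probability (both vigilance states)."""
    return ModifierSet([
        Modifier("p_capture", "state", "risky-foraging", factor),
        Modifier("p_capture", "state", "safe-foraging", factor),
    ])


def threshold_config(threshold: float | None, seed: int = 1) -> SimConfig:
    """Marten-frame configuration: 60-day season, 1-h steps, 4.5/7.5-h bouts
    from 04:00, trigger 270 active steps, marten home-range minima
    (4.25 / 2.32 km^2); ``threshold=None`` turns the behaviour off."""
    return SimConfig(
        years=1, season_days=60, step_minutes=60, start_hour=4,
        scenario="release_only",
        e_init=4548.0, e_min=1000.0, e_max=5003.0,
        forage_threshold=threshold,
        perception_radius=100.0,
        active_mean_h=4.5, active_sd_h=0.8, rest_mean_h=7.5, rest_sd_h=0.8,
        trigger_mode="steps", trigger_threshold=270, criterion="closest",
        distance_weight={"male": 1000.0, "female": 1000.0},
        a_min={"male": 4.25e6, "female": 2.32e6},
        modifiers=foraging_boost_modifiers() if threshold is not None else None,
        seed=seed,
    )
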