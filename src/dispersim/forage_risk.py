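"""Energetics and mortality: foraging gains, the energy ledger with starvation
floor and ceiling, per-step depredation, and resident step mortality.

Energy is a unitless reserve (case studies use it as a surrogate for body
mass in grams). Each active step costs the movement map's energy rate; with
probability p_capture the animal gains a Normal prey size truncated at zero.
The ledger clamps at E_max and the animal starves the moment its reserve
falls below E_min. Depredation is a per-step Bernoulli trial at the risk
map's (modifier-resolved) probability, so survival under a constant hazard p
follows (1-p)^n exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .agents import DEAD, PREDATION, STARVATION, Disperser
from .simtime import SimTime


def forage(eff, food_attrs, rng: np.random.Generator) -> float:
    """Energy gained this step: Bernoulli(p_capture) success, then a
    Normal(size_mean, size_sd) prey size truncated below at 0."""
    if rng.uniform() >= eff.p_capture:
        return 0.0
    if food_attrs.size_sd == 0:
        return food_attrs.size_mean
    return max(0.0, rng.normal(food_attrs.size_mean, food_attrs.size_sd))


def apply_energy(animal: Disperser, cost: float, gain: float, t: SimTime) -> None:
    """Apply one step's energy ledger update.

    Cost and gain are applied together, the result clamps at E_max, and
    starvation (E < E_min) is evaluated once afterwards — a single evaluation
    point per step.
    """
    if cost < 0 or gain < 0:
        raise ValueError("energy cost and gain must be >= 0")
    animal.energy = min(animal.energy - cost + gain, animal.e_max)
    if animal.energy < animal.e_min:
        animal.die(STARVATION, t)


def predation_draw(eff, rng: np.random.Generator) -> bool:
    """True if the animal dies to depredation this step (one uniform draw)."""
    if not 0.0 <= eff.p_mortality <= 1.0:
        raise ValueError("p_mortality must be in [0, 1]")
    return rng.uniform() < eff.p_mortality


def resident_step_mortality(residents: list, p_step: float, rng: np.random.Generator,
                            registry, suitability_map) -> list:
    """Aspatial per-step Bernoulli mortality for residents.

    Deaths free the home range: the range leaves the registry and its
    occupancy flags clear, so the area is available to settlers from the next
    processing moment on.
    """
    if not 0.0 <= p_step <= 1.0:
        raise ValueError("p_step must be in [0, 1]")
    if p_step == 0.0 or not residents:
        return residents
    survivors, dead = [], []
    for res in residents:
        if rng.uniform() < p_step:
            dead.append(res.home_range)
        else:
            survivors.append(res)
    registry.remove_many(dead, suitability_map)
    return survivors
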