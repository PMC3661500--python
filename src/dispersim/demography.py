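"""Inter-dispersal demography: resident survival over the off-season and
reproduction that supplies the next season's dispersers.

The part of the year outside the dispersal season is a single discrete
period: each resident survives it with probability 1 - p_inter (deaths free
their ranges), then each surviving female is pregnant with probability
p_pregnant and bears round(Normal(litter_mean, litter_sd)) young — negative
draws yield zero. Offspring sexes are iid Bernoulli(p_female) and every
juvenile starts the next season at the center of its mother's home range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .agents import FEMALE, MALE, Resident


@dataclass
class OffspringSpec:
    sex: str
    natal_x: float
    natal_y: float
    mother_id: int


def interdispersal_survival(residents: list, p_inter: float,
                            rng: np.random.Generator, registry,
                            suitability_map) -> list:
    """Single Bernoulli survival trial per resident; deaths clear occupancy."""
    if not 0.0 <= p_inter <= 1.0:
        raise ValueError("p_inter must be in [0, 1]")
    if p_inter == 0.0:
        return residents
    survivors, dead = [], []
    for res in residents:
        if rng.uniform() < p_inter:
            dead.append(res.home_range)
        else:
            survivors.append(res)
    registry.remove_many(dead, suitability_map)
    return survivors


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def litter_size(litter_mean: float, litter_sd: float, rng: np.random.Generator) -> int:
    """round(Normal(mean, sd)), half away from zero; negative integers map to 0."""
    draw = rng.normal(litter_mean, litter_sd) if litter_sd > 0 else litter_mean
    return max(0, _round_half_away(draw))


def breed(females: Sequence[Resident], p_pregnant: float, litter_mean: float,
          litter_sd: float, p_female: float, rng: np.random.Generator
          ) -> list[OffspringSpec]:
    """Reproduction by surviving female residents.

    Only females breed, only residents breed, and the resulting juveniles
    join the NEXT season's disperser roster at their mothers' range centers.
    """
    for p in (p_pregnant, p_female):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if litter_sd < 0:
        raise ValueError("litter_sd must be >= 0")
    out: list[OffspringSpec] = []
    for mother in females:
        if mother.sex != FEMALE:
            continue
        if rng.uniform() >= p_pregnant:
            continue
        n = litter_size(litter_mean, litter_sd, rng)
        cx, cy = mother.home_range.center
        for _ in range(n):
            sex = FEMALE if rng.uniform() < p_female else MALE
            out.append(OffspringSpec(sex, cx, cy, mother.id))
    return out
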