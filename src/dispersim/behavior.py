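"""Behaviour-state machinery: multiplicative modifiers, activity/vigilance
transitions, and activity/rest bout scheduling.

Baseline habitat parameters can be modified multiplicatively by an animal's
sex, its behavioural state (risky/safe x searching/foraging), the hour of day,
and the date. A modifier that is absent is 1, so a run configured with every
multiplier at 1 is behaviourally identical to one with the machinery off —
the null-model convention used when variability due to gender, time, or
behaviour is to be eliminated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .simtime import SimTime

# Parameters a modifier may target.
MODIFIABLE = ("p_capture", "p_mortality", "energy_cost", "step_mean",
              "tortuosity", "perception")

STATES = ("risky-searching", "risky-foraging", "safe-searching", "safe-foraging")


@dataclass
class Modifier:
    parameter: str
    kind: str       # 'sex' | 'state' | 'hour' | 'date'
    key: object     # sex name, state name, (start_hour, end_hour), (start_day, end_day)
    multiplier: float

    def __post_init__(self) -> None:
        if self.parameter not in MODIFIABLE:
            raise ConfigurationError(f"unknown modifiable parameter {self.parameter!r}")
        if self.kind not in ("sex", "state", "hour", "date"):
            raise ConfigurationError(f"unknown modifier kind {self.kind!r}")
        if self.multiplier < 0:
            raise ConfigurationError("modifier multipliers must be >= 0")

    def applies(self, sex: str, state: str, t: SimTime) -> bool:
        if self.kind == "sex":
            return self.key == sex
        if self.kind == "state":
            return self.key == state
        if self.kind == "hour":
            lo, hi = self.key
            # half-open [lo, hi); a window may wrap midnight (e.g. 18 -> 6)
            if lo <= hi:
                return lo <= t.hour < hi
            return t.hour >= lo or t.hour < hi
        lo, hi = self.key
        return lo <= t.day < hi


class ModifierSet:
    """Immutable-during-run table of multiplicative behaviour modifiers."""

    def __init__(self, modifiers: Sequence[Modifier] = ()) -> None:
        self.modifiers = list(modifiers)

    def multiplier(self, parameter: str, sex: str, state: str, t: SimTime) -> float:
        m = 1.0
        for mod in self.modifiers:
            if mod.parameter == parameter and mod.applies(sex, state, t):
                m *= mod.multiplier
        return m

    def is_neutral(self) -> bool:
        return all(m.multiplier == 1.0 for m in self.modifiers)


@dataclass
class EffectiveParams:
    """Per-step resolved parameters after modifier application and clamping."""

    p_capture: float
    p_mortality: float
    energy_cost: float
    step_mean: float
    step_sd: float
    tortuosity: float
    perception_radius: float


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def resolve(move_attrs, food_attrs, risk_attrs, mods: Optional[ModifierSet],
            animal, t: SimTime, base_perception: float) -> EffectiveParams:
    """Resolve the animal's effective parameters at its current location.

    Each parameter is base x sex-mult x state-mult x hour-mult x date-mult
    (the product over all applicable modifiers — order is immaterial), then
    clamped to its legal range. The perception radius is additionally scaled
    by the movement map's perception-window modifier field. ``mods=None``
    disables the machinery entirely.
    """
    state = f"{animal.vigilance}-{animal.activity_mode}"

    def mult(p: str) -> float:
        if mods is None:
            return 1.0
        return mods.multiplier(p, animal.sex, state, t)

    return EffectiveParams(
        p_capture=_clamp01(food_attrs.p_capture * mult("p_capture")),
        p_mortality=_clamp01(risk_attrs.p_mortality * mult("p_mortality")),
        energy_cost=max(0.0, move_attrs.energy_cost * mult("energy_cost")),
        step_mean=max(0.0, move_attrs.step_mean * mult("step_mean")),
        step_sd=move_attrs.step_sd,
        tortuosity=_clamp01(move_attrs.tortuosity * mult("tortuosity")),
        perception_radius=max(
            0.0, base_perception * move_attrs.perception_mod * mult("perception")),
    )


def update_activity_mode(animal, threshold: Optional[float]) -> None:
    """Energy-threshold switch between searching and foraging.

    Strictly below the threshold -> foraging; at or above -> searching. The
    transition is symmetric, so energies recrossing the threshold switch the
    mode back. ``threshold=None`` disables the switch (always searching).
    """
    if threshold is None:
        return
    animal.activity_mode = "foraging" if animal.energy < threshold else "searching"


def update_vigilance(animal, p_risky_to_safe: float, p_safe_to_risky: float,
                     rng: np.random.Generator) -> None:
    """One uniform draw per step; the current mode switches iff the draw falls
    below that mode's switching probability."""
    u = rng.uniform()
    if animal.vigilance == "risky":
        if u < p_risky_to_safe:
            animal.vigilance = "safe"
    else:
        if u < p_safe_to_risky:
            animal.vigilance = "risky"


@dataclass
class BoutSchedule:
    """Alternating active/rest bout durations covering one season.

    Durations are in minutes; the first bout is active, anchored at the
    season's start time. Whether a given elapsed minute falls in an active
    bout is a cumulative-sum lookup.
    """

    start_hour: float
    durations: list[tuple[str, float]]  # (state, minutes), state alternates from 'active'
    _edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.durations or self.durations[0][0] != "active":
            raise ConfigurationError("bout schedule must begin with an active bout")
        self._edges = np.cumsum([d for _, d in self.durations])

    def is_active(self, elapsed_minutes: float) -> bool:
        """True if ``elapsed_minutes`` since season start falls in an active bout."""
        i = int(np.searchsorted(self._edges, elapsed_minutes, side="right"))
        if i >= len(self.durations):
            return False  # beyond the scheduled horizon (should not happen)
        return self.durations[i][0] == "active"


def schedule_bouts(active_mean: float, active_sd: float, rest_mean: float,
                   rest_sd: float, start_hour: float, horizon_minutes: float,
                   step_minutes: float, rng: np.random.Generator) -> BoutSchedule:
    """Draw a season-long alternating activity/rest schedule for one animal.

    Means and SDs are hours. Each duration is Normal(mean, sd) truncated below
    at one time-step. The mean active+rest cycle must tile 24 h exactly
    (e.g. 12+12, or 4.5+7.5 twice a day); animals begin the season active.
    """
    if active_mean <= 0 or rest_mean < 0:
        raise ConfigurationError("bout means must be positive")
    cycle = active_mean + rest_mean
    n_cycles = 24.0 / cycle
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ConfigurationError(
            f"mean active+rest cycle ({cycle} h) must divide 24 h so that mean "
            "activity sums to 24 h per day"
        )
    if rest_mean == 0 and rest_sd == 0:
        # Continuously active species: one bout spans the season.
        return BoutSchedule(start_hour, [("active", horizon_minutes + step_minutes)])
    durations: list[tuple[str, float]] = []
    covered = 0.0
    state = "active"
    while covered < horizon_minutes:
        mean, sd = (active_mean, active_sd) if state == "active" else (rest_mean, rest_sd)
        minutes = rng.normal(mean, sd) * 60.0 if sd > 0 else mean * 60.0
        minutes = max(minutes, step_minutes)
        durations.append((state, minutes))
        covered += minutes
        state = "rest" if state == "active" else "active"
    return BoutSchedule(start_hour, durations)
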