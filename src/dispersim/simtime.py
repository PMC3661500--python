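"""Discrete simulation time.

The simulator's clock is (year, day-of-season, hour-of-day). Years and days
are 1-based; hour is a real number in [0, 24). Ordering is lexicographic, so
a time can key map-swap schedules and log rows alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering


@total_ordering
@dataclass(frozen=True)
class SimTime:
    year: int
    day: int
    hour: float

    def _key(self) -> tuple[int, int, float]:
        return (self.year, self.day, self.hour)

    def __lt__(self, other: "SimTime") -> bool:
        return self._key() < other._key()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimTime):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


def clock_at(step_index: int, step_minutes: int, start_hour: int, year: int) -> SimTime:
    """Clock reading at the start of step ``step_index`` (0-based) of a season.

    Day 1 of the season begins at ``start_hour``; day boundaries fall at
    midnight, so a season started at 18:00 rolls to day 2 after six hours.
    """
    total = start_hour * 60 + step_index * step_minutes
    day = 1 + total // 1440
    hour = (total % 1440) / 60.0
    return SimTime(year, int(day), hour)
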