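"""Shared fixtures: hand-built parameter maps and synthetic landscapes.

All fixtures are generated programmatically so tests carry no data files.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from dispersim.landscape import (FoodAttrs, Landscape, MovementAttrs,
                                 ParameterMap, RiskAttrs, SuitabilityAttrs)


def make_movement_map(cells):
    """cells: list of (geom, dict of movement attrs with defaults filled)."""
    defaults = dict(tortuosity=0.5, step_mean=10.0, step_sd=0.0,
                    energy_cost=1.0, crossing=1.0, perception_mod=1.0)
    geoms, attrs = [], []
    for geom, over in cells:
        geoms.append(geom)
        attrs.append(MovementAttrs(**{**defaults, **over}))
    return ParameterMap("movement", geoms, attrs)


def make_food_map(cells):
    defaults = dict(p_capture=0.5, size_mean=10.0, size_sd=0.0)
    geoms = [g for g, _ in cells]
    attrs = [FoodAttrs(**{**defaults, **o}) for _, o in cells]
    return ParameterMap("food", geoms, attrs)


def make_risk_map(cells):
    geoms = [g for g, _ in cells]
    attrs = [RiskAttrs(**{"p_mortality": 0.0, **o}) for _, o in cells]
    return ParameterMap("risk", geoms, attrs)


def make_suitability_map(cells):
    defaults = dict(suitable=1, occupied_male=0, occupied_female=0)
    geoms = [g for g, _ in cells]
    attrs = [SuitabilityAttrs(**{**defaults, **o}) for _, o in cells]
    return ParameterMap("suitability", geoms, attrs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_polygon_movement():
    """100x100 m extent split at x=50 into two movement classes."""
    return make_movement_map([
        (box(0, 0, 50, 100), {"tortuosity": 0.5}),
        (box(50, 0, 100, 100), {"tortuosity": 1.0}),
    ])


@pytest.fixture
def homogeneous_landscape():
    """One-polygon maps on a 1 km square; everything suitable, no risk."""
    ext = box(0, 0, 1000, 1000)
    return Landscape(maps={
        "movement": make_movement_map([(ext, {"tortuosity": 0.8, "step_mean": 20.0})]),
        "food": make_food_map([(ext, {})]),
        "risk": make_risk_map([(ext, {})]),
        "suitability": make_suitability_map([(ext, {})]),
    })


def grid_cells(extent, nx, ny):
    minx, miny, maxx, maxy = extent
    dx, dy = (maxx - minx) / nx, (maxy - miny) / ny
    return [box(minx + i * dx, miny + j * dy, minx + (i + 1) * dx, miny + (j + 1) * dy)
            for j in range(ny) for i in range(nx)]


@pytest.fixture
def four_class_movement():
    """2x2 grid on 200x200 m with crossing ranks 1..4 (quadrant order SW, SE, NW, NE)."""
    cells = grid_cells((0, 0, 200, 200), 2, 2)
    ranks = [1.0, 2.0, 3.0, 4.0]
    return make_movement_map([
        (g, {"crossing": r, "tortuosity": 0.0, "step_mean": 40.0})
        for g, r in zip(cells, ranks)
    ])
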