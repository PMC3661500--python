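"""Per-step displacement: the correlated random walk.

Each active step an animal turns by a wrapped-Cauchy angle (concentration
rho: 0 = uniform turning, 1 = dead straight), draws a Normal step length
truncated at zero, and walks the resulting ray through the movement-map
tessellation. At every polygon boundary it meets it decides whether to cross
by comparing the crossing ranks of the two classes: the odds of crossing are
q_to : q_from, so a rank-0 class is never entered and leaving a rank-0 class
(which the model forbids occupying) would always succeed. A refused crossing
truncates the step at the boundary; the landscape edge reflects specularly,
so animals always remain inside the extent. The realized path, buffered by
the perception radius, is the step's perceptual window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .errors import InvalidStateError
from .landscape import ParameterMap

TWO_PI = 2.0 * math.pi
_EPS = 1e-9
_PULLBACK = 1e-6   # m; refused crossings stop just inside the current polygon
_CLEARANCE = 1e-9  # m; minimum perpendicular clearance kept from the boundary
_DETECT = 5e-10    # m; boundary-crossing detection threshold (< _CLEARANCE)
_MAX_LEGS = 10_000


@dataclass
class PathSegment:
    """One step's realized path: origin, boundary/reflection waypoints, terminus."""

    origin: tuple[float, float]
    waypoints: list[tuple[float, float]]
    terminus: tuple[float, float]
    heading_out: float
    truncated_by_boundary: bool = False

    @property
    def points(self) -> list[tuple[float, float]]:
        return [self.origin, *self.waypoints, self.terminus]

    @property
    def length(self) -> float:
        pts = self.points
        return sum(math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))

    def line(self) -> LineString:
        pts = self.points
        if all(math.dist(pts[0], p) < _EPS for p in pts):
            return LineString()  # degenerate zero-length step
        return LineString(pts)


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    if -math.pi < a <= math.pi:
        return a
    a = (a + math.pi) % TWO_PI - math.pi
    if a == -math.pi:
        a = math.pi
    return a


def sample_turn_angle(prev_heading: float, rho: float, rng: np.random.Generator) -> float:
    """New heading = previous heading + wrapped-Cauchy(0, rho) turning angle.

    Sampled by the exact inverse-CDF transform
    theta = 2 atan(((1-rho)/(1+rho)) tan(pi (u - 1/2))). rho = 1 returns the
    previous heading unchanged; rho = 0 gives uniform turning.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if rho == 1.0:
        return wrap_angle(prev_heading)
    u = rng.uniform()
    theta = 2.0 * math.atan(((1.0 - rho) / (1.0 + rho)) * math.tan(math.pi * (u - 0.5)))
    return wrap_angle(prev_heading + theta)


def sample_step_length(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal(mean, sd) step length, truncated below at 0 (negative draws clamp)."""
    if mean < 0 or sd < 0:
        raise ValueError("step-length mean and sd must be >= 0")
    if sd == 0:
        return mean
    return max(0.0, rng.normal(mean, sd))


def crossing_decision(q_from: float, q_to: float, rng: np.random.Generator) -> bool:
    """Cross a habitat boundary with probability q_to / (q_from + q_to).

    q_to = 0: never cross (impassable class). q_from = 0: always cross (the
    animal cannot remain in an impassable class). Both zero is an invalid
    state.
    """
    if q_from < 0 or q_to < 0:
        raise ValueError("crossing ranks must be >= 0")
    if q_from == 0 and q_to == 0:
        raise InvalidStateError("animal occupies an impassable class adjoining another")
    if q_to == 0:
        return False
    if q_from == 0:
        return True
    return rng.uniform() < q_to / (q_from + q_to)


def _wall_hit(x: float, y: float, dx: float, dy: float,
              bounds: tuple[float, float, float, float]) -> tuple[float, int]:
    """Distance to the first extent wall along (dx, dy), and which wall.

    Wall codes: 0 = vertical (reflect dx), 1 = horizontal (reflect dy).
    Returns (inf, -1) if the ray never exits (zero direction).
    """
    minx, miny, maxx, maxy = bounds
    best_t, wall = math.inf, -1
    if dx > _EPS:
        t = (maxx - x) / dx
        if t < best_t:
            best_t, wall = t, 0
    elif dx < -_EPS:
        t = (minx - x) / dx
        if t < best_t:
            best_t, wall = t, 0
    if dy > _EPS:
        t = (maxy - y) / dy
        if t < best_t:
            best_t, wall = t, 1
    elif dy < -_EPS:
        t = (miny - y) / dy
        if t < best_t:
            best_t, wall = t, 1
    return best_t, wall


def _boundary_params(movement_map: ParameterMap, seg: LineString,
                     leg: float) -> list[float]:
    """Sorted distances along ``seg`` where it crosses any polygon boundary,
    strictly inside (0, leg)."""
    ts: list[float] = []
    for i in movement_map.query_intersecting(seg):
        inter = movement_map.geoms[i].boundary.intersection(seg)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type == "Point":
                ts.append(seg.project(g))
            elif g.geom_type == "LineString":
                # travelling along an edge: treat both ends as crossings
                ts.extend(seg.project(Point(c)) for c in g.coords)
    # Detection threshold must sit below the post-refusal clearance margin
    # (_CLEARANCE) so a boundary refused last step cannot be missed this step.
    ts = sorted(t for t in ts if _DETECT < t < leg - _DETECT)
    out: list[float] = []
    for t in ts:
        if not out or t - out[-1] > _DETECT:
            out.append(t)
    return out


def _pullback_t(movement_map: ParameterMap, cur_feat: int, x: float, y: float,
                dx: float, dy: float, t: float, prev_t: float) -> float:
    """Path parameter just short of a refused crossing at ``t`` such that the
    point lies strictly inside the current polygon with >= _CLEARANCE margin.

    The pullback escalates because at shallow incidence a fixed path-distance
    pullback leaves an arbitrarily small perpendicular clearance.
    """
    g = movement_map.geoms[cur_feat]
    pull = _PULLBACK
    while True:
        ct = t - pull
        if ct <= prev_t:
            if prev_t <= 0.0:
                return 0.0  # too close to gain clearance: forfeit the step
            return 0.5 * (prev_t + t)  # thin sliver between two boundaries
        p = Point(x + ct * dx, y + ct * dy)
        if g.covers(p) and g.boundary.distance(p) >= _CLEARANCE:
            return ct
        pull *= 10.0


def advance(animal, movement_map: ParameterMap, eff, rng: np.random.Generator
            ) -> PathSegment:
    """Execute one movement step for ``animal`` and update its position/heading.

    Draws the new heading and step length from the effective parameters, then
    traverses the ray: a boundary-crossing decision at every polygon boundary
    met (refusal truncates the step, forfeiting the remaining distance), and
    specular reflection at the landscape extent.
    """
    heading = sample_turn_angle(animal.heading, eff.tortuosity, rng)
    length = sample_step_length(eff.step_mean, eff.step_sd, rng)
    seg = traverse((animal.x, animal.y), heading, length, movement_map, rng)
    animal.x, animal.y = seg.terminus
    animal.heading = seg.heading_out
    return seg


def traverse(origin: tuple[float, float], heading: float, length: float,
             movement_map: ParameterMap, rng: np.random.Generator) -> PathSegment:
    """Walk a ray of ``length`` m from ``origin``, honouring crossing decisions
    and extent reflection. Exposed separately for testing."""
    bounds = movement_map.extent.bounds
    x, y = origin
    hd = heading
    remaining = length
    waypoints: list[tuple[float, float]] = []
    truncated = False

    for _ in range(_MAX_LEGS):
        if remaining <= _EPS:
            break
        dx, dy = math.cos(hd), math.sin(hd)
        t_wall, wall = _wall_hit(x, y, dx, dy, bounds)
        # stop a hair short of the wall so positions stay strictly inside
        leg = min(remaining, max(t_wall - _PULLBACK, 0.0))
        hit_wall = leg < remaining - _EPS
        ex, ey = x + leg * dx, y + leg * dy
        if leg > _EPS:
            seg = LineString([(x, y), (ex, ey)])
            ts = _boundary_params(movement_map, seg, leg)
            cur_feat = movement_map.feature_at(*_midpoint(x, y, dx, dy, 0.0,
                                                          ts[0] if ts else leg))
            refused_at = None
            prev_t = 0.0
            for k, t in enumerate(ts):
                nxt_end = ts[k + 1] if k + 1 < len(ts) else leg
                nxt_feat = movement_map.feature_at(*_midpoint(x, y, dx, dy, t, nxt_end))
                if nxt_feat == cur_feat:
                    prev_t = t
                    continue
                q_from = movement_map.attrs[cur_feat].crossing
                q_to = movement_map.attrs[nxt_feat].crossing
                if crossing_decision(q_from, q_to, rng):
                    waypoints.append((x + t * dx, y + t * dy))
                    cur_feat = nxt_feat
                    prev_t = t
                else:
                    refused_at = _pullback_t(movement_map, cur_feat, x, y,
                                             dx, dy, t, prev_t)
                    break
            if refused_at is not None:
                x, y = x + refused_at * dx, y + refused_at * dy
                truncated = True
                remaining = 0.0
                break
            x, y = ex, ey
            remaining -= leg
        if hit_wall and remaining > _EPS:
            waypoints.append((x, y))
            if wall == 0:
                hd = wrap_angle(math.pi - hd)
            else:
                hd = wrap_angle(-hd)

    return PathSegment(origin=origin, waypoints=waypoints, terminus=(x, y),
                       heading_out=hd, truncated_by_boundary=truncated)


def _midpoint(x: float, y: float, dx: float, dy: float, t0: float, t1: float
              ) -> tuple[float, float]:
    tm = 0.5 * (t0 + t1)
    return (x + tm * dx, y + tm * dy)


def perception_polygon(segment: PathSegment, radius: float):
    """The step's perceptual window: the realized path buffered by ``radius``.

    Round caps and joins; a zero-length path gives a disc, radius 0 gives an
    empty (zero-width) geometry.
    """
    if radius < 0:
        raise ValueError("perception radius must be >= 0")
    line = segment.line()
    base = Point(segment.origin) if line.is_empty else line
    return base.buffer(radius) if radius > 0 else base.buffer(0)
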