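"""Turning angles, step lengths, boundary crossing, path traversal, and the
perceptual window."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from dispersim.behavior import EffectiveParams
from dispersim.errors import InvalidStateError
from dispersim.movement import (PathSegment, crossing_decision,
                                perception_polygon, sample_step_length,
                                sample_turn_angle, traverse, wrap_angle)

from conftest import make_movement_map


def _eff(step_mean=10.0, step_sd=0.0, tortuosity=0.5, radius=0.0):
    return EffectiveParams(p_capture=0.0, p_mortality=0.0, energy_cost=0.0,
                           step_mean=step_mean, step_sd=step_sd,
                           tortuosity=tortuosity, perception_radius=radius)


class TestTurnAngles:
    def test_rho_one_is_exactly_straight(self, rng):
        for h in (-2.0, 0.0, 1.3):
            assert sample_turn_angle(h, 1.0, rng) == wrap_angle(h)

    def test_rho_zero_is_uniform(self):
        """Mean resultant length of 1e5 uniform turning angles ~ n^(-1/2)."""
        rng = np.random.default_rng(3)
        turns = np.array([sample_turn_angle(0.0, 0.0, rng) for _ in range(100_000)])
        R = np.hypot(np.cos(turns).mean(), np.sin(turns).mean())
        assert R < 0.01

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_mean_resultant_length_equals_rho(self, rho):
        """E[cos theta] = rho for the wrapped Cauchy distribution."""
        rng = np.random.default_rng(4)
        turns = np.array([sample_turn_angle(0.0, rho, rng) for _ in range(100_000)])
        R = np.hypot(np.cos(turns).mean(), np.sin(turns).mean())
        assert R == pytest.approx(rho, abs=0.01)

    def test_result_wrapped(self, rng):
        for _ in range(200):
            a = sample_turn_angle(3.0, 0.2, rng)
            assert -math.pi < a <= math.pi


class TestStepLength:
    def test_sd_zero_is_exact_mean(self, rng):
        assert sample_step_length(42.0, 0.0, rng) == 42.0

    def test_zero_mean(self, rng):
        assert sample_step_length(0.0, 0.0, rng) == 0.0

    def test_sample_mean_recovers_mean(self):
        rng = np.random.default_rng(6)
        draws = np.array([sample_step_length(100.0, 10.0, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(100.0, abs=0.2)
        assert draws.min() >= 0.0


class TestCrossingDecision:
    def test_impassable_destination_never_crossed(self, rng):
        assert not any(crossing_decision(3.0, 0.0, rng) for _ in range(1000))

    def test_leaving_impassable_always_crosses(self, rng):
        assert all(crossing_decision(0.0, 2.0, rng) for _ in range(100))

    def test_both_zero_is_invalid_state(self, rng):
        with pytest.raises(InvalidStateError):
            crossing_decision(0.0, 0.0, rng)

    @pytest.mark.parametrize("q_from,q_to,expected", [
        (2.0, 2.0, 0.50),
        (1.0, 3.0, 0.75),
    ])
    def test_empirical_frequency_matches_odds_form(self, q_from, q_to, expected):
        rng = np.random.default_rng(8)
        n = 10_000
        freq = sum(crossing_decision(q_from, q_to, rng) for _ in range(n)) / n
        assert freq == pytest.approx(expected, abs=0.01)


class TestTraverse:
    def test_homogeneous_map_straight_step(self):
        m = make_movement_map([(box(0, 0, 1000, 1000), {})])
        rng = np.random.default_rng(1)
        seg = traverse((100.0, 100.0), math.pi / 4, 50.0, m, rng)
        assert not seg.truncated_by_boundary
        ex = 100 + 50 * math.cos(math.pi / 4)
        ey = 100 + 50 * math.sin(math.pi / 4)
        assert seg.terminus == pytest.approx((ex, ey), abs=1e-9)
        assert seg.length == pytest.approx(50.0, abs=1e-9)

    def test_impassable_neighbor_truncates_at_boundary(self):
        m = make_movement_map([
            (box(0, 0, 50, 100), {"crossing": 2.0}),
            (box(50, 0, 100, 100), {"crossing": 0.0}),
        ])
        rng = np.random.default_rng(2)
        seg = traverse((40.0, 50.0), 0.0, 30.0, m, rng)
        assert seg.truncated_by_boundary
        assert seg.terminus[0] == pytest.approx(50.0, abs=1e-3)
        assert seg.terminus[0] < 50.0  # remains on the origin side
        assert seg.length <= 30.0

    def test_impassable_class_never_entered_many_steps(self):
        """1e4 consecutive steps beside a crossing=0 class: never inside it."""
        m = make_movement_map([
            (box(0, 0, 50, 100), {"crossing": 2.0, "tortuosity": 0.0,
                                  "step_mean": 15.0}),
            (box(50, 0, 100, 100), {"crossing": 0.0}),
        ])
        forbidden = box(50, 0, 100, 100)
        rng = np.random.default_rng(11)
        x, y, hd = 25.0, 50.0, 0.0
        for _ in range(10_000):
            hd = sample_turn_angle(hd, 0.0, rng)
            seg = traverse((x, y), hd, 15.0, m, rng)
            x, y = seg.terminus
            assert x < 50.0 + 1e-9
            assert m.feature_at(x, y) == 0

    def test_reflection_keeps_positions_inside_extent(self):
        m = make_movement_map([(box(0, 0, 100, 100), {})])
        rng = np.random.default_rng(12)
        x, y, hd = 5.0, 5.0, 0.0
        for _ in range(2000):
            hd = sample_turn_angle(hd, 0.0, rng)
            seg = traverse((x, y), hd, 60.0, m, rng)  # steps longer than margins
            x, y = seg.terminus
            assert 0.0 <= x <= 100.0 and 0.0 <= y <= 100.0
            assert seg.length == pytest.approx(60.0, abs=1e-6)

    def test_crossing_frequencies_on_two_class_fixture(self):
        """Empirical boundary-crossing rate matches q_to/(q_from+q_to) within
        3 Monte-Carlo standard errors."""
        m = make_movement_map([
            (box(0, 0, 50, 100), {"crossing": 1.0}),
            (box(50, 0, 100, 100), {"crossing": 3.0}),
        ])
        rng = np.random.default_rng(13)
        n = 4000
        crossed = 0
        for _ in range(n):
            seg = traverse((45.0, 50.0), 0.0, 10.0, m, rng)  # aims into class 1
            crossed += not seg.truncated_by_boundary
        p = 3.0 / 4.0
        se = math.sqrt(p * (1 - p) / n)
        assert abs(crossed / n - p) < 3 * se

    def test_straight_line_trajectory_colinear(self):
        """rho=1, sd=0 on a homogeneous map: all positions colinear."""
        m = make_movement_map([(box(0, 0, 10_000, 10_000), {})])
        rng = np.random.default_rng(14)
        pts = [(100.0, 100.0)]
        hd = 0.7
        for _ in range(50):
            hd2 = sample_turn_angle(hd, 1.0, rng)
            assert hd2 == hd
            seg = traverse(pts[-1], hd2, 20.0, m, rng)
            pts.append(seg.terminus)
        (x0, y0), (x1, y1) = pts[0], pts[-1]
        for (x, y) in pts[1:-1]:
            cross = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
            assert abs(cross) < 1e-9 * math.dist(pts[0], pts[-1]) ** 2

    def test_displacement_never_exceeds_drawn_length(self):
        m = make_movement_map([
            (box(0, 0, 50, 100), {"crossing": 1.0}),
            (box(50, 0, 100, 100), {"crossing": 1.0}),
        ])
        rng = np.random.default_rng(15)
        for _ in range(500):
            ox, oy = rng.uniform(5, 95), rng.uniform(5, 95)
            hd = rng.uniform(-math.pi, math.pi)
            seg = traverse((ox, oy), hd, 30.0, m, rng)
            assert math.dist((ox, oy), seg.terminus) <= 30.0 + 1e-9

    def test_random_walk_msd_grows_linearly(self):
        """Net squared displacement of a rho=0 walk grows like n(mean^2+sd^2)."""
        m = make_movement_map([(box(-1e6, -1e6, 1e6, 1e6), {})])
        rng = np.random.default_rng(16)
        n_walks, n_steps, mean, sd = 400, 50, 10.0, 2.0
        sq = []
        for _ in range(n_walks):
            x = y = 0.0
            hd = 0.0
            for _ in range(n_steps):
                hd = sample_turn_angle(hd, 0.0, rng)
                L = sample_step_length(mean, sd, rng)
                x += L * math.cos(hd)
                y += L * math.sin(hd)
            sq.append(x * x + y * y)
        expected = n_steps * (mean ** 2 + sd ** 2)
        se = np.std(sq, ddof=1) / math.sqrt(n_walks)
        assert abs(np.mean(sq) - expected) < 3 * se


class TestPerceptionPolygon:
    def test_straight_segment_stadium_area(self):
        """100 m path, 120 m radius: area = 2*r*L + pi*r^2 within 0.5%."""
        seg = PathSegment((0, 0), [], (100, 0), 0.0)
        area = perception_polygon(seg, 120.0).area
        expected = 2 * 120 * 100 + math.pi * 120 ** 2
        assert area == pytest.approx(expected, rel=0.005)

    def test_zero_length_segment_is_disc(self):
        seg = PathSegment((5, 5), [], (5, 5), 0.0)
        area = perception_polygon(seg, 100.0).area  # marten baseline radius
        assert area == pytest.approx(math.pi * 100 ** 2, rel=0.005)

    def test_zero_radius_is_empty(self):
        seg = PathSegment((0, 0), [], (10, 0), 0.0)
        assert perception_polygon(seg, 0.0).area == 0.0
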