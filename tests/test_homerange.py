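"""Settlement trigger, candidate scoring, range-polygon generation, and
same-sex exclusion."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from dispersim.agents import Disperser
from dispersim.homerange import (CandidateSite, HomeRange, RangeRegistry,
                                 attempt_settlement, end_of_season,
                                 generate_polygon, nominal_radius,
                                 score_candidates, trigger_reached)
from dispersim.simtime import SimTime

from conftest import make_suitability_map

T = SimTime(1, 30, 12.0)


def _animal(steps=0, sites=0, sex="male"):
    a = Disperser(id=1, sex=sex, energy=100.0, e_init=100.0, e_min=0.0,
                  e_max=200.0, x=500.0, y=500.0)
    a.steps_taken = steps
    a.sites_visited = sites
    return a


class TestTrigger:
    @pytest.mark.parametrize("threshold", [168, 270, 1000])
    def test_steps_mode_reached_at_threshold(self, threshold):
        assert not trigger_reached(_animal(steps=threshold - 1), "steps", threshold)
        assert trigger_reached(_animal(steps=threshold), "steps", threshold)

    def test_sites_mode(self):
        assert trigger_reached(_animal(sites=5), "sites", 5)
        assert not trigger_reached(_animal(sites=4), "sites", 5)


class TestScoreCandidates:
    def test_single_candidate_always_chosen(self, rng):
        c = CandidateSite(1, 2, distance=50.0, food_quality=1.0, risk_quality=1.0)
        assert score_candidates([c], "integrated", 100.0, rng) is c

    def test_empty_set_signals_no_candidate(self, rng):
        assert score_candidates([], "closest", 100.0, rng) is None

    def test_distance_kernel_ratio(self):
        """Equal quality, distances d and 2d with w = d: selection ratio
        e^-1 : e^-2, i.e. 0.731 : 0.269."""
        rng = np.random.default_rng(31)
        d = 100.0
        a = CandidateSite(0, 0, distance=d, food_quality=1.0, risk_quality=1.0)
        b = CandidateSite(1, 1, distance=2 * d, food_quality=1.0, risk_quality=1.0)
        n = 10_000
        picks = sum(score_candidates([a, b], "closest", d, rng) is a
                    for _ in range(n))
        expected = math.e ** -1 / (math.e ** -1 + math.e ** -2)
        assert picks / n == pytest.approx(expected, abs=0.02)

    def test_huge_w_negates_proximity(self):
        """w = 1e9 m: selection frequencies depend only on quality."""
        from scipy import stats
        rng = np.random.default_rng(32)
        sites = [CandidateSite(i, 0, distance=d, food_quality=q, risk_quality=1.0)
                 for i, (d, q) in enumerate([(10.0, 1.0), (5000.0, 2.0),
                                             (20000.0, 1.0)])]
        n = 10_000
        counts = np.zeros(3)
        for _ in range(n):
            chosen = score_candidates(sites, "food", 1e9, rng)
            counts[sites.index(chosen)] += 1
        expected = np.array([0.25, 0.5, 0.25]) * n  # quality-only weights
        chi = stats.chisquare(counts, expected)
        assert chi.pvalue > 0.001

    def test_risk_criterion_prefers_safe_sites(self):
        rng = np.random.default_rng(33)
        safe = CandidateSite(0, 0, distance=100.0, food_quality=1.0,
                             risk_quality=0.999)
        risky = CandidateSite(1, 1, distance=100.0, food_quality=1.0,
                              risk_quality=0.5)
        picks = sum(score_candidates([safe, risky], "risk", 1e9, rng) is safe
                    for _ in range(2000))
        assert picks / 2000 == pytest.approx(0.999 / 1.499, abs=0.03)


class TestGeneratePolygon:
    def test_zero_sd_regular_12gon_area_exact(self, rng):
        a_min = 4.25e6  # marten male minimum, m^2
        poly = generate_polygon((0.0, 0.0), a_min, rng, radius_cv=0.0)
        assert poly.area == pytest.approx(a_min, rel=1e-9)
        assert len(poly.exterior.coords) == 13

    @pytest.mark.parametrize("a_min", [2.32e6, 4.25e6, 2000.0])
    def test_every_polygon_at_least_a_min(self, a_min):
        rng = np.random.default_rng(34)
        for _ in range(200):
            poly = generate_polygon((0.0, 0.0), a_min, rng)
            assert poly.is_valid
            assert poly.area >= a_min * (1 - 1e-9)
            assert poly.contains(Point(0, 0))

    def test_nominal_radius_closed_form(self):
        k = 12
        r0 = nominal_radius(1000.0, k)
        assert (k / 2) * r0 ** 2 * math.sin(2 * math.pi / k) == pytest.approx(1000.0)


class TestSettlement:
    def _suit(self, size=20_000.0):
        return make_suitability_map([(box(-size, -size, size, size), {})])

    def test_settle_in_vast_empty_region_then_exclude_same_sex(self):
        rng = np.random.default_rng(35)
        suit = self._suit()
        registry = RangeRegistry()
        a_min = 1e5
        site = CandidateSite(0.0, 0.0, 100.0, 1.0, 1.0)
        hr1 = attempt_settlement(_animal(), site, suit, registry, a_min, rng, T)
        assert hr1 is not None
        assert hr1.polygon.area >= a_min - 1e-6
        # a second male settling nearby must not overlap the first range
        hr2 = attempt_settlement(_animal(), CandidateSite(400.0, 0.0, 10.0, 1, 1),
                                 suit, registry, a_min, rng, T)
        if hr2 is not None:
            assert hr1.polygon.intersection(hr2.polygon).area < 1e-6

    def test_fully_occupied_same_sex_rejected(self):
        rng = np.random.default_rng(36)
        suit = self._suit()
        registry = RangeRegistry()
        blocker = HomeRange(owner_id=9, sex="male", center=(0.0, 0.0),
                            polygon=box(-20_000, -20_000, 20_000, 20_000))
        registry.add(blocker, suit)
        site = CandidateSite(0.0, 0.0, 100.0, 1.0, 1.0)
        assert attempt_settlement(_animal(), site, suit, registry, 1e5, rng, T) is None

    def test_opposite_sex_occupancy_does_not_block(self):
        rng = np.random.default_rng(37)
        suit = self._suit()
        registry = RangeRegistry()
        blocker = HomeRange(owner_id=9, sex="female", center=(0.0, 0.0),
                            polygon=box(-20_000, -20_000, 20_000, 20_000))
        registry.add(blocker, suit)
        site = CandidateSite(0.0, 0.0, 100.0, 1.0, 1.0)
        hr = attempt_settlement(_animal(sex="male"), site, suit, registry,
                                1e5, rng, T)
        assert hr is not None

    def test_unsuitable_habitat_rejected(self):
        rng = np.random.default_rng(38)
        suit = make_suitability_map([(box(-2000, -2000, 2000, 2000),
                                      {"suitable": 0})])
        registry = RangeRegistry()
        site = CandidateSite(0.0, 0.0, 100.0, 1.0, 1.0)
        assert attempt_settlement(_animal(), site, suit, registry, 1e4, rng, T) is None

    def test_occupancy_flags_marked_and_cleared(self):
        rng = np.random.default_rng(39)
        suit = self._suit()
        registry = RangeRegistry()
        site = CandidateSite(0.0, 0.0, 100.0, 1.0, 1.0)
        hr = attempt_settlement(_animal(sex="female"), site, suit, registry,
                                1e5, rng, T)
        assert suit.attrs[0].occupied_female == 1
        registry.remove(hr, suit)
        assert suit.attrs[0].occupied_female == 0

    def test_adding_ranges_shrinks_eligibility(self):
        """Settlement monotonicity: each added same-sex range can only reduce
        the usable area of a fixed candidate polygon."""
        suit = self._suit()
        registry = RangeRegistry()
        probe = Point(0, 0).buffer(400.0)
        prev = probe.area
        rng = np.random.default_rng(40)
        for cx in (200.0, -200.0, 0.0):
            hr = HomeRange(owner_id=1, sex="male", center=(cx, 0.0),
                           polygon=Point(cx, 0.0).buffer(150.0))
            registry.add(hr, suit)
            usable = probe.difference(registry.same_sex_union("male")).area
            assert usable <= prev + 1e-9
            prev = usable


class TestEndOfSeason:
    def test_dispersers_die_settled_survive(self):
        a, b = _animal(), _animal()
        b.status = "settled"
        end_of_season([a, b], T)
        assert a.status == "dead" and a.death_cause == "season_end"
        assert b.status == "settled"

    def test_cause_partition_sums(self):
        animals = [_animal() for _ in range(6)]
        animals[0].die("predation", T)
        animals[1].die("starvation", T)
        animals[2].status = "settled"
        end_of_season(animals, T)
        causes = [a.death_cause for a in animals if a.status == "dead"]
        assert sorted(causes) == ["predation", "season_end", "season_end",
                                  "season_end", "starvation"]
        assert len(causes) + 1 == len(animals)
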