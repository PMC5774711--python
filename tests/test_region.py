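"""Region generation, agent placement and supply-profile draws."""

import numpy as np
import pytest

from woodmarket.config import ConfigError, PopulationSpec, RegionSpec, substream
from woodmarket.region import (agents_to_frame, draw_supply_profiles,
                               generate_region, place_agents,
                               solve_truncated_lognormal_mu,
                               truncated_lognormal, truncated_lognormal_mean)


@pytest.fixture(scope="module")
def reference_agents():
    spec, pop = RegionSpec(), PopulationSpec()
    region = generate_region(spec, 1)
    agents = place_agents(region, pop, 1)
    draw_supply_profiles(agents, pop, 1)
    return region, agents


def count(agents, atype, zone):
    return sum(1 for a in agents if a.type == atype and a.zone == zone)


class TestRegionGeometry:
    def test_international_fraction_within_one_segment(self):
        region = generate_region(RegionSpec(), 1)
        per_segment = 1.0 / region.spec.n_border_segments
        assert abs(region.international_fraction() - 2 / 3) <= per_segment

    def test_zero_fraction_means_domestic_fallback(self):
        spec = RegionSpec(international_border_fraction=0.0)
        region = generate_region(spec, 1)
        assert not any(s.international for s in region.segments)
        agents = place_agents(region, PopulationSpec(), 1)
        # importers/exporters still placed, on the domestic boundary
        assert count(agents, "importer", "inner") == 6
        assert count(agents, "exporter", "inner") == 6

    def test_same_seed_is_bit_identical(self):
        a = generate_region(RegionSpec(), 7)
        b = generate_region(RegionSpec(), 7)
        assert [(s.start_arc, s.end_arc, s.international) for s in a.segments] \
            == [(s.start_arc, s.end_arc, s.international) for s in b.segments]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            generate_region(RegionSpec(inner_width_km=-1), 1)
        with pytest.raises(ConfigError):
            generate_region(RegionSpec(outer_belt_km=0), 1)

    def test_boundary_point_wraps_around_the_perimeter(self):
        region = generate_region(RegionSpec(), 1)
        x0, y0 = region.boundary_point(0.0)
        x1, y1 = region.boundary_point(region.perimeter)
        assert (x0, y0) == pytest.approx((x1, y1))


class TestPlacement:
    def test_reference_counts_per_type_and_zone(self, reference_agents):
        _, agents = reference_agents
        expected = {"public": (85, 85), "private": (85, 85),
                    "trader": (12, 12), "bundler": (8, 15),
                    "sawmill": (25, 25), "industrial": (1, 2),
                    "energy": (50, 50), "importer": (6, 6),
                    "exporter": (6, 6)}
        for atype, (inner, outer) in expected.items():
            assert count(agents, atype, "inner") == inner, atype
            assert count(agents, atype, "outer") == outer, atype

    def test_every_agent_in_exactly_one_zone(self, reference_agents):
        region, agents = reference_agents
        for a in agents:
            inner = region.in_inner(a.x, a.y)
            outer = region.in_outer(a.x, a.y)
            assert inner != outer
            assert (a.zone == "inner") == inner

    def test_zero_counts_give_empty_population(self):
        pop = PopulationSpec()
        for name in ("public", "private", "trader", "bundler", "sawmill",
                     "industrial", "energy", "importer", "exporter"):
            spec = getattr(pop, name)
            spec.count_inner = spec.count_outer = 0
        region = generate_region(RegionSpec(), 1)
        assert place_agents(region, pop, 1) == []

    def test_placement_deterministic_under_seed(self):
        region = generate_region(RegionSpec(), 3)
        a = place_agents(region, PopulationSpec(), 3)
        b = place_agents(region, PopulationSpec(), 3)
        assert [(x.id, x.type, x.x, x.y) for x in a] \
            == [(x.id, x.type, x.x, x.y) for x in b]

    def test_bundlers_affiliate_nearby_suppliers(self, reference_agents):
        region, agents = reference_agents
        by_id = {a.id: a for a in agents}
        radius = PopulationSpec().bundler.affiliation_radius_km
        for b in agents:
            if b.type != "bundler":
                continue
            for sid in b.affiliates:
                s = by_id[sid]
                assert s.type in ("public", "private")
                assert np.hypot(s.x - b.x, s.y - b.y) <= radius + 1e-9


class TestSupplyProfiles:
    def test_sawmill_capacities_within_printed_range(self, reference_agents):
        _, agents = reference_agents
        caps = [a.capacity for a in agents if a.type == "sawmill"]
        assert len(caps) == 50
        assert min(caps) >= 800.0 and max(caps) <= 8000.0

    def test_supplier_splits_sum_to_one(self, reference_agents):
        _, agents = reference_agents
        for a in agents:
            if a.type in ("public", "private"):
                assert sum(a.splits_soft) == pytest.approx(1.0, abs=1e-9)
                assert sum(a.splits_hard) == pytest.approx(1.0, abs=1e-9)
                assert a.max_supply > 0

    def test_softwood_share_matches_reference(self, reference_agents):
        _, agents = reference_agents
        pubs = [a for a in agents if a.type == "public"]
        assert all(a.soft_share == pytest.approx(0.97) for a in pubs)

    def test_zero_spread_degenerates_to_the_mean(self):
        rng = substream(1, "test")
        draws = truncated_lognormal(rng, 100, 2300.0, 0.0, 800.0, 8000.0)
        assert np.allclose(draws, 2300.0)

    def test_truncated_mean_solver_hits_target(self):
        # independent check: analytic truncated mean at the solved mu
        sigma = np.sqrt(np.log(1 + 0.55 ** 2))
        mu = solve_truncated_lognormal_mu(2300.0, sigma, 800.0, 8000.0)
        assert truncated_lognormal_mean(mu, sigma, 800.0, 8000.0) \
            == pytest.approx(2300.0, abs=1e-6)

    def test_monte_carlo_mean_matches_configured_mean(self):
        # 10,000 draws against the analytic mean of the configured
        # distribution, within 2%
        rng = substream(123, "capacity-draws")
        draws = truncated_lognormal(rng, 10_000, 2300.0, 0.55, 800.0, 8000.0)
        assert draws.mean() == pytest.approx(2300.0, rel=0.02)
        assert draws.min() >= 800.0 and draws.max() <= 8000.0

    def test_infeasible_distribution_rejected(self):
        with pytest.raises(ConfigError):
            solve_truncated_lognormal_mu(10_000.0, 0.5, 800.0, 8000.0)

    def test_agent_frame_export(self, reference_agents):
        _, agents = reference_agents
        df = agents_to_frame(agents)
        assert len(df) == len(agents)
        assert set(df["type"]) == {"public", "private", "trader", "bundler",
                                   "sawmill", "industrial", "energy",
                                   "importer", "exporter"}
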