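"""Role behaviours: supply planning, reservations, processing, border trade."""

import numpy as np
import pytest

from woodmarket.agents import (BorderAgentState, ProcessorState,
                               SupplierState, PriceView, available_pools,
                               border_price, plan_annual_supply,
                               process_deliveries, reserve_for_regulars)
from woodmarket.config import BehaviorSpec, ConfigError, PriceSeriesSpec
from woodmarket.markets import ASSORTMENTS
from woodmarket.region import Agent


def make_supplier(atype="public", max_supply=3500.0, beh=None,
                  own=None) -> SupplierState:
    beh = beh or BehaviorSpec()
    agent = Agent(id=0, type=atype, zone="inner", x=0, y=0,
                  max_supply=max_supply, soft_share=0.97,
                  splits_soft=(0.81, 0.13, 0.06),
                  splits_hard=(0.02, 0.95, 0.03), terrain=1.0)
    return SupplierState(agent=agent, beh=beh, elastic_amount=0.3,
                         elastic_split=0.5, own_consumption=own or {})


def ref_prices() -> PriceView:
    levels = PriceSeriesSpec().levels
    return PriceView(dict(levels), dict(levels))


class TestSupplyPlanning:
    def test_reference_prices_reproduce_reference_splits(self):
        s = make_supplier()
        plan = plan_annual_supply(s, ref_prices())
        assert plan.splits["soft"] == pytest.approx((0.81, 0.13, 0.06))
        assert plan.splits["hard"] == pytest.approx((0.02, 0.95, 0.03))
        beh = BehaviorSpec()
        assert plan.annual_target == pytest.approx(
            3500.0 * beh.base_harvest_fraction)
        assert sum(plan.annual.values()) == pytest.approx(plan.annual_target)

    def test_zero_elasticity_makes_plan_price_independent(self):
        s = make_supplier()
        s.elastic_amount = s.elastic_split = 0.0
        levels = PriceSeriesSpec().levels
        doubled = {a: 2.0 * v for a, v in levels.items()}
        p1 = plan_annual_supply(s, ref_prices())
        p2 = plan_annual_supply(s, PriceView(doubled, dict(levels)))
        assert p1.annual_target == pytest.approx(p2.annual_target)
        assert p1.splits == p2.splits

    def test_energy_price_doubling_shifts_share_upward(self):
        # hand-recomputed shift: s_i proportional to ref_i * ratio_i^e
        s = make_supplier()
        levels = dict(PriceSeriesSpec().levels)
        current = dict(levels)
        current["energy_soft"] = 2.0 * levels["energy_soft"]
        plan = plan_annual_supply(s, PriceView(current, levels))
        e = s.elastic_split
        raw = [0.81, 0.13 * 2.0 ** e, 0.06]
        expected = tuple(v / sum(raw) for v in raw)
        assert plan.splits["soft"] == pytest.approx(expected)
        assert plan.splits["soft"][1] > 0.13
        assert sum(plan.splits["soft"]) == pytest.approx(1.0)

    def test_higher_prices_raise_the_target_up_to_the_cap(self):
        s = make_supplier()
        levels = dict(PriceSeriesSpec().levels)
        up = {a: 1.3 * v for a, v in levels.items()}
        base = plan_annual_supply(s, ref_prices()).annual_target
        boosted = plan_annual_supply(s, PriceView(up, levels)).annual_target
        assert base < boosted <= s.agent.max_supply

    def test_private_own_consumption_removed_before_marketing(self):
        own = {"sawlogs": 0.10, "energy": 0.60, "industrial": 0.05}
        s = make_supplier("private", own=own)
        plan = plan_annual_supply(s, ref_prices())
        for a in ASSORTMENTS:
            prod = a.rsplit("_", 1)[0]
            gross = plan.annual[a] + plan.own_consumption[a]
            assert plan.own_consumption[a] == pytest.approx(
                gross * own[prod])

    def test_harvesting_cost_increases_with_cumulative_cut(self):
        s = make_supplier()
        plan_annual_supply(s, ref_prices())
        c0 = s.harvesting_cost("sawlogs")
        s.harvested_ytd = 0.9 * s.plan.annual_target
        assert s.harvesting_cost("sawlogs") > c0
        assert s.harvesting_cost("energy") < s.harvesting_cost("sawlogs")


class TestReservations:
    def test_zero_reservation_opens_everything(self):
        beh = BehaviorSpec()
        beh.reservation = {"sawlogs": 0.0, "energy": 0.0, "industrial": 0.0}
        s = make_supplier(beh=beh)
        plan_annual_supply(s, ref_prices())
        pools = reserve_for_regulars(s, month=2)
        for a in ASSORTMENTS:
            assert pools[a]["nonregular"] == pytest.approx(
                pools[a]["regular"])

    def test_reserved_fraction_arithmetic(self):
        # 42% reservation on 1000 m3 of sawlogs -> 420 reserved initially
        s = make_supplier()
        plan_annual_supply(s, ref_prices())
        a = "sawlogs_soft"
        plan = s.plan.annual[a]
        reg, nonreg = available_pools(s, a, month=2)
        assert reg == pytest.approx(plan)
        assert nonreg == pytest.approx(plan * (1.0 - 0.42))
        assert plan - nonreg == pytest.approx(0.42 * plan)

    def test_release_month_opens_reserved_amounts(self):
        s = make_supplier()
        plan_annual_supply(s, ref_prices())
        a = "sawlogs_soft"
        reg, nonreg = available_pools(s, a, month=9)   # October
        assert nonreg == pytest.approx(reg)

    def test_nonregular_sales_deplete_only_the_open_pool(self):
        s = make_supplier()
        plan_annual_supply(s, ref_prices())
        a = "sawlogs_soft"
        plan = s.plan.annual[a]
        s.sold_nonregular[a] = 100.0
        s.annual_committed[a] = 100.0
        reg, nonreg = available_pools(s, a, month=2)
        assert reg == pytest.approx(plan - 100.0)
        assert nonreg == pytest.approx(plan * 0.58 - 100.0)


class TestProcessing:
    def make_proc(self, capacity=12000.0):
        agent = Agent(id=1, type="sawmill", zone="inner", x=0, y=0,
                      capacity=capacity)
        return ProcessorState(agent=agent,
                              yields={"energy": 0.2, "industrial": 0.15},
                              stock_months=2.0)

    def test_linear_yield_arithmetic(self):
        p = self.make_proc()
        by = process_deliveries(p, 1000.0)
        assert by["energy_soft"] == pytest.approx(200.0)
        assert by["industrial_soft"] == pytest.approx(150.0)
        assert p.byproduct_stock["energy_soft"] == pytest.approx(200.0)

    def test_zero_processed_zero_byproducts(self):
        p = self.make_proc()
        assert all(v == 0.0 for v in process_deliveries(p, 0.0).values())

    def test_full_year_at_capacity_is_full_utilization(self):
        p = self.make_proc(capacity=1200.0)
        for _ in range(12):
            process_deliveries(p, 100.0)
            p.processed_by_year[2001] = p.processed_by_year.get(2001, 0) + 100
        assert p.utilization(2001) == pytest.approx(1.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ConfigError):
            process_deliveries(self.make_proc(), -1.0)

    def test_stock_headroom_tracks_warehouse_capacity(self):
        p = self.make_proc(capacity=12000.0)   # monthly 1000, cap 2000
        assert p.stock_headroom("sawlogs_soft") == pytest.approx(2000.0)
        p.stock["sawlogs_soft"] = 1500.0
        assert p.stock_headroom("sawlogs_soft") == pytest.approx(500.0)


class TestBorderAgents:
    def make_border(self, side, spread=0.0, fx=None, prices=None):
        agent = Agent(id=2, type="importer" if side == "import" else
                      "exporter", zone="inner", x=0, y=0)
        n = 24
        prices = prices if prices is not None else np.full((n, 6), 100.0)
        fx = fx if fx is not None else np.ones(n)
        return BorderAgentState(agent=agent, side=side, prices=prices, fx=fx,
                                spread=spread, initial_volume=1000.0,
                                annual_increase=500.0)

    def test_identity_at_unit_fx_and_zero_spread(self):
        b = self.make_border("import")
        assert border_price(b, "sawlogs_soft", 3) == pytest.approx(100.0)

    def test_exchange_rate_shift_is_exactly_linear(self):
        fx = np.ones(24)
        fx[12:] = 1.10
        b = self.make_border("export", fx=fx)
        p0 = border_price(b, "energy_soft", 0)
        p1 = border_price(b, "energy_soft", 12)
        assert p1 == pytest.approx(1.10 * p0)

    def test_spread_direction_by_side(self):
        imp = self.make_border("import", spread=0.1)
        exp = self.make_border("export", spread=0.1)
        assert border_price(imp, "sawlogs_soft", 0) == pytest.approx(110.0)
        assert border_price(exp, "sawlogs_soft", 0) == pytest.approx(90.0)

    def test_month_outside_series_is_an_error(self):
        b = self.make_border("import")
        with pytest.raises(ConfigError):
            border_price(b, "sawlogs_soft", 999)

    def test_annual_increase_cap_truncates_requests(self):
        b = self.make_border("export")
        assert b.allowance(2001) == pytest.approx(1000.0)
        b.record(2001, 1000.0)
        assert b.allowance(2001) == 0.0
        # next year: last year's volume plus the configured increase
        assert b.allowance(2002) == pytest.approx(1500.0)
        b.record(2002, 200.0)
        assert b.allowance(2002) == pytest.approx(1300.0)
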