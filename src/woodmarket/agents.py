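"""Role behaviours: supply planning, reservations, processing, border trade.

Nine agent roles participate in the six markets:

* **Public forest managers / private forest owners** plan an annual cut
  (price-elastic in the absolute price level, with assortment shares shifted
  by relative prices; private owners shift more), spread it equably over the
  harvesting season, reserve part of it for regular customers, and harvest
  to order against an increasing marginal-cost curve scaled by terrain.
  Private owners remove an own-consumption share before marketing.
* **Sawmills** buy sawlogs targeting constant capacity utilisation, hold at
  most two months of demand in stock, and accumulate processing residuals
  (bark, chips, shavings, sawdust) which they sell as energy and industrial
  wood.
* **Industrial and energy wood buyers** cover fixed annual demands; energy
  buyers concentrate their demand in the heating period and hold one month
  of stock.
* **Traders and bundling organisations** buy to resell at a margin; bundlers
  buy only from affiliated suppliers.
* **Importers and exporters** couple the region to exogenous international
  prices via the exchange rate; their volumes are unlimited but the annual
  increase is capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BehaviorSpec, ConfigError
from .markets import ASSORTMENTS, assortment, product_of, species_of
from .region import Agent


# ---------------------------------------------------------------------------
# suppliers
# ---------------------------------------------------------------------------

@dataclass
class SupplyPlan:
    """One supplier's plan for a calendar year (marketable volumes)."""

    annual_target: float                       # total cut incl. own consumption
    splits: dict[str, tuple[float, float, float]]  # species -> (sawlogs, energy, ind.)
    annual: dict[str, float]                   # assortment -> marketable m3/yr
    monthly: dict[str, float]                  # assortment -> m3 per season month
    own_consumption: dict[str, float]          # assortment -> m3/yr kept


@dataclass
class SupplierState:
    agent: Agent
    beh: BehaviorSpec
    elastic_amount: float        # harvest-level price elasticity
    elastic_split: float         # assortment-share shift elasticity
    own_consumption: dict[str, float]   # product -> fraction kept (private only)
    plan: SupplyPlan | None = None
    harvested_ytd: float = 0.0          # m3 cut so far this calendar year
    stock: dict[str, float] = field(default_factory=dict)   # harvested, undelivered
    committed: dict[tuple[str, int], float] = field(default_factory=dict)
    annual_committed: dict[str, float] = field(default_factory=dict)
    sold_nonregular: dict[str, float] = field(default_factory=dict)

    def reset_year(self) -> None:
        self.harvested_ytd = 0.0
        self.annual_committed = {}
        self.sold_nonregular = {}
        self.committed = {k: v for k, v in self.committed.items()}

    def remaining_annual(self, a: str) -> float:
        if self.plan is None:
            return 0.0
        return max(0.0, self.plan.annual.get(a, 0.0)
                   - self.annual_committed.get(a, 0.0))

    def harvesting_cost(self, product: str) -> float:
        """Marginal harvesting cost (currency/m3) at the current cumulative cut.

        Piecewise-linear increasing in the fraction of the annual target
        already harvested, scaled by the supplier's terrain factor and a
        per-product multiplier (energy wood is cheaper to produce than
        sawlog-quality timber).
        """
        beh = self.beh
        target = self.plan.annual_target if self.plan else self.agent.max_supply
        frac = min(1.0, self.harvested_ytd / target) if target > 0 else 1.0
        return (beh.harvest_cost_base * beh.cost_product_mult.get(product, 1.0)
                * self.agent.terrain * (1.0 + beh.harvest_cost_slope * frac))


class PriceView:
    """Current and reference prices per assortment, as seen by planners."""

    def __init__(self, current: dict[str, float], reference: dict[str, float]):
        missing = [a for a in ASSORTMENTS if a not in current or a not in reference]
        if missing:
            raise ConfigError(f"prices missing for {missing}")
        self.current = current
        self.reference = reference

    def ratio(self, a: str) -> float:
        return self.current[a] / self.reference[a]


def plan_annual_supply(s: SupplierState, prices: PriceView) -> SupplyPlan:
    """Plan the annual cut and its assortment composition.

    The target amount responds log-linearly to the supply-weighted absolute
    price level (capped at the annual maximum); assortment shares are
    shifted from their reference values by relative prices with the
    supplier's shift elasticity and renormalised per species.  With all
    prices at reference levels the plan reproduces the reference splits
    exactly.  The marketable plan removes own consumption and is spread
    equably over the harvesting-season months.
    """
    ag, beh = s.agent, s.beh
    ref_splits = {"soft": ag.splits_soft, "hard": ag.splits_hard}
    shares = {"soft": ag.soft_share, "hard": 1.0 - ag.soft_share}
    products = ("sawlogs", "energy", "industrial")

    # absolute price level, weighted by the reference composition
    level = 0.0
    for sp in ("soft", "hard"):
        for frac, prod in zip(ref_splits[sp], products):
            level += shares[sp] * frac * prices.ratio(assortment(prod, sp))
    target = ag.max_supply * beh.base_harvest_fraction * level ** s.elastic_amount
    target = min(target, ag.max_supply)

    splits: dict[str, tuple[float, float, float]] = {}
    for sp in ("soft", "hard"):
        shifted = [frac * prices.ratio(assortment(prod, sp)) ** s.elastic_split
                   for frac, prod in zip(ref_splits[sp], products)]
        tot = sum(shifted)
        splits[sp] = tuple(v / tot for v in shifted) if tot > 0 else ref_splits[sp]

    annual: dict[str, float] = {}
    own: dict[str, float] = {}
    for sp in ("soft", "hard"):
        for frac, prod in zip(splits[sp], products):
            a = assortment(prod, sp)
            vol = target * shares[sp] * frac
            kept = vol * s.own_consumption.get(prod, 0.0)
            own[a] = kept
            annual[a] = vol - kept
    n_season = len(beh.season_months)
    monthly = {a: v / n_season for a, v in annual.items()}
    s.plan = SupplyPlan(annual_target=target, splits=splits, annual=annual,
                        monthly=monthly, own_consumption=own)
    return s.plan


def available_pools(s: SupplierState, a: str, month: int) -> tuple[float, float]:
    """(regular, non-regular) uncommitted annual volume for one assortment."""
    remaining = s.remaining_annual(a)
    beh = s.beh
    res_frac = beh.reservation.get(product_of(a), 0.0)
    if res_frac == 0.0 or (month % 12) >= beh.reservation_release_month:
        return remaining, remaining
    plan = s.plan.annual.get(a, 0.0) if s.plan else 0.0
    pool = (1.0 - res_frac) * plan - s.sold_nonregular.get(a, 0.0)
    return remaining, max(0.0, min(remaining, pool))


def reserve_for_regulars(s: SupplierState, month: int) -> dict[str, dict[str, float]]:
    """Volume available per customer class, per assortment, this month.

    A configured fraction of the annual plan is reserved for regular
    customers until the release month; reservations are not absolute — a
    non-regular buyer offering the configured price premium is served from
    the reserved pool as well (handled at negotiation time via the
    ``regular`` class).  Returns ``{assortment: {"regular": m3,
    "nonregular": m3}}`` of uncommitted annual volume.
    """
    out: dict[str, dict[str, float]] = {}
    for a in ASSORTMENTS:
        reg, nonreg = available_pools(s, a, month)
        out[a] = {"regular": reg, "nonregular": nonreg}
    return out


# ---------------------------------------------------------------------------
# processors and fixed-demand buyers
# ---------------------------------------------------------------------------

@dataclass
class ProcessorState:
    """Sawmill processing state (input stock, byproducts, utilisation)."""

    agent: Agent
    yields: dict[str, float]            # product -> m3 byproduct per m3 processed
    stock_months: float
    start_month: int = 0                # first month of processing operation
    stock: dict[str, float] = field(default_factory=dict)       # input sawlogs
    byproduct_stock: dict[str, float] = field(default_factory=dict)
    processed_ytd: float = 0.0
    processed_by_year: dict[int, float] = field(default_factory=dict)
    contracted_in: dict[tuple[str, int], float] = field(default_factory=dict)

    @property
    def monthly_demand(self) -> float:
        return self.agent.capacity / 12.0

    @property
    def stock_capacity(self) -> float:
        return self.stock_months * self.monthly_demand

    def stock_headroom(self, a: str) -> float:
        if not a.startswith("sawlogs"):
            return float("inf")
        total = sum(self.stock.values())
        return max(0.0, self.stock_capacity - total)

    def utilization(self, year: int) -> float:
        cap = self.agent.capacity
        return self.processed_by_year.get(year, 0.0) / cap if cap > 0 else 0.0


def process_deliveries(p: ProcessorState, delivered: float) -> dict[str, float]:
    """Process ``delivered`` m3 of sawlogs; return byproduct volumes.

    Byproduct volumes are the yield fractions times the processed volume and
    are added to the mill's sell-side stock of the energy and industrial
    markets (softwood byproducts).  The processed volume itself leaves the
    model as sawn products (downstream markets are out of scope).
    """
    if delivered < 0:
        raise ConfigError("processed volume must be >= 0")
    out: dict[str, float] = {}
    for prod, y in p.yields.items():
        vol = y * delivered
        a = assortment(prod, "soft")
        out[a] = vol
        p.byproduct_stock[a] = p.byproduct_stock.get(a, 0.0) + vol
    p.processed_ytd += delivered
    return out


@dataclass
class ConsumerState:
    """Fixed-demand buyer (industrial or energy wood)."""

    agent: Agent
    demand: dict[str, float]            # assortment -> m3/yr
    active_months: tuple[int, ...]      # calendar months with consumption
    stock_months: float
    stock: dict[str, float] = field(default_factory=dict)
    contracted_in: dict[tuple[str, int], float] = field(default_factory=dict)
    consumed_by_year: dict[int, float] = field(default_factory=dict)

    def monthly_demand(self, a: str, cal_month: int) -> float:
        if cal_month not in self.active_months:
            return 0.0
        return self.demand.get(a, 0.0) / len(self.active_months)

    def stock_headroom(self, a: str) -> float:
        cap = self.stock_months * self.demand.get(a, 0.0) / max(1, len(self.active_months))
        return max(0.0, cap - self.stock.get(a, 0.0))


# ---------------------------------------------------------------------------
# intermediaries
# ---------------------------------------------------------------------------

@dataclass
class TraderState:
    agent: Agent
    monthly_volume: float
    min_margin: float
    affiliates: frozenset[int] = frozenset()    # bundlers: allowed sellers
    stock: dict[str, float] = field(default_factory=dict)
    cost_basis: dict[str, float] = field(default_factory=dict)
    bought_this_month: dict[str, float] = field(default_factory=dict)
    committed_out: dict[tuple[str, int], float] = field(default_factory=dict)

    def available(self, a: str, month: int) -> float:
        return max(0.0, self.stock.get(a, 0.0)
                   - self.committed_out.get((a, month), 0.0))

    def record_purchase(self, a: str, amount: float, price: float) -> None:
        old = self.stock.get(a, 0.0)
        basis = self.cost_basis.get(a, price)
        self.cost_basis[a] = ((basis * old + price * amount) / (old + amount)
                              if old + amount > 0 else price)
        self.stock[a] = old + amount
        self.bought_this_month[a] = self.bought_this_month.get(a, 0.0) + amount


# ---------------------------------------------------------------------------
# border agents
# ---------------------------------------------------------------------------

@dataclass
class BorderAgentState:
    """Importer/exporter price coupling and annual volume-growth cap."""

    agent: Agent
    side: str                     # 'import' (sells inward) | 'export' (buys)
    prices: "np.ndarray"          # months x assortments, international series
    fx: "np.ndarray"              # exchange-rate series
    spread: float
    initial_volume: float
    annual_increase: float
    traded_by_year: dict[int, float] = field(default_factory=dict)

    def border_price(self, a: str, month: int) -> float:
        """International series value x exchange rate, with the buy/sell spread."""
        if month >= len(self.fx):
            raise ConfigError(f"month {month} outside exogenous price series")
        base = float(self.prices[month, ASSORTMENTS.index(a)] * self.fx[month])
        if self.side == "import":
            return base * (1.0 + self.spread)
        return base * (1.0 - self.spread)

    def allowance(self, year: int) -> float:
        """Remaining tradable volume this year under the growth cap."""
        prev = self.traded_by_year.get(year - 1, 0.0)
        cap = max(self.initial_volume, prev + self.annual_increase)
        return max(0.0, cap - self.traded_by_year.get(year, 0.0))

    def record(self, year: int, amount: float) -> None:
        self.traded_by_year[year] = self.traded_by_year.get(year, 0.0) + amount


def border_price(b: BorderAgentState, a: str, month: int) -> float:
    return b.border_price(a, month)
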