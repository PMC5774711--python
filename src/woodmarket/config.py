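"""Configuration model, reference parameter set, RNG substreams and
exogenous price-series generation.

All tunable parameters of the simulator live in one nested dataclass tree
(:class:`FullConfig`).  The shipped defaults are the *reference
configuration*: the quantity structure of the study region (agent counts,
supply/demand means, assortment splits, reservation and own-consumption
fractions) together with the shipped behavioural calibration (part-worth
utilities, thresholds, trust steps).  Configs round-trip losslessly through
YAML and are identified by a SHA-256 hash of their canonical form, which is
stamped into every output.

Randomness is organised as named substreams derived from one root seed, so
that e.g. changing the number of decision draws does not perturb the region
layout drawn for the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .markets import ASSORTMENTS, PRODUCTS


class ConfigError(ValueError):
    """A configuration violates a documented invariant."""


# ---------------------------------------------------------------------------
# dataclass tree
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Synthetic two-zone region geometry.

    The inner zone (the evaluated study region) is a rectangle; the outer
    zone is a surrounding belt of agents that buffers boundary effects.
    Road distances are Euclidean distances times ``detour_factor``.
    """

    inner_width_km: float = 90.0
    inner_height_km: float = 60.0
    outer_belt_km: float = 30.0
    international_border_fraction: float = 2.0 / 3.0
    detour_factor: float = 1.4
    n_border_segments: int = 12

    def validate(self) -> None:
        if self.inner_width_km <= 0 or self.inner_height_km <= 0:
            raise ConfigError("inner zone extents must be positive")
        if self.outer_belt_km <= 0:
            raise ConfigError("outer belt width must be positive")
        if not 0.0 <= self.international_border_fraction <= 1.0:
            raise ConfigError("international_border_fraction must lie in [0,1]")
        if self.detour_factor < 1.0:
            raise ConfigError("detour_factor must be >= 1")
        if self.n_border_segments < 1:
            raise ConfigError("need at least one border segment")


@dataclass
class SupplierTypeSpec:
    """Population parameters for a wood-supplier type (per agent)."""

    count_inner: int
    count_outer: int
    mean_supply: float          # annual maximum supply, m3/yr, population mean
    cv_supply: float            # coefficient of variation of the supply draw
    min_supply: float
    max_supply: float
    soft_share: float           # softwood fraction of the annual supply
    # assortment split at reference prices, order (sawlogs, energy, industrial)
    splits_soft: tuple[float, float, float]
    splits_hard: tuple[float, float, float]

    def validate(self, name: str) -> None:
        _check_counts(name, self.count_inner, self.count_outer)
        if not (self.min_supply <= self.mean_supply <= self.max_supply):
            raise ConfigError(f"{name}: mean supply outside [min,max]")
        if not 0.0 <= self.soft_share <= 1.0:
            raise ConfigError(f"{name}: soft_share must lie in [0,1]")
        for sp, splits in (("soft", self.splits_soft), ("hard", self.splits_hard)):
            if any(not 0.0 <= s <= 1.0 for s in splits):
                raise ConfigError(f"{name}: {sp} splits must lie in [0,1]")
            if abs(sum(splits) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: {sp} splits must sum to 1")


@dataclass
class SawmillSpec:
    count_inner: int = 25
    count_outer: int = 25
    mean_capacity: float = 2300.0   # m3/yr softwood sawlog processing
    cv_capacity: float = 0.55
    min_capacity: float = 800.0
    max_capacity: float = 8000.0
    hardwood_mills: int = 3         # mills that also process hardwood sawlogs
    hardwood_demand: float = 180.0  # m3/yr fixed hardwood side demand per such mill
    stock_months: float = 2.0       # full warehouse covers demand for two months
    byproduct_energy: float = 0.20  # m3 energy wood per m3 sawlogs processed
    byproduct_industrial: float = 0.15

    def validate(self) -> None:
        _check_counts("sawmill", self.count_inner, self.count_outer)
        if not (self.min_capacity <= self.mean_capacity <= self.max_capacity):
            raise ConfigError("sawmill: mean capacity outside [min,max]")
        if self.byproduct_energy + self.byproduct_industrial >= 1.0:
            raise ConfigError("sawmill: byproduct yields must sum to < 1")


@dataclass
class FixedBuyerSpec:
    """Buyer type with fixed annual demand (industrial and energy buyers)."""

    count_inner: int
    count_outer: int
    demand_soft: float   # m3/yr per agent
    demand_hard: float
    stock_months: float

    def validate(self, name: str) -> None:
        _check_counts(name, self.count_inner, self.count_outer)
        if self.demand_soft < 0 or self.demand_hard < 0:
            raise ConfigError(f"{name}: demand must be >= 0")


@dataclass
class IntermediarySpec:
    count_inner: int
    count_outer: int
    monthly_volume: float = 600.0    # target turnover per assortment traded, m3/month
    min_margin: float = 0.05         # required resale margin, fraction of ref price
    affiliation_radius_km: float = 25.0  # bundlers: suppliers within this radius

    def validate(self, name: str) -> None:
        _check_counts(name, self.count_inner, self.count_outer)
        if self.monthly_volume < 0:
            raise ConfigError(f"{name}: monthly_volume must be >= 0")


@dataclass
class BorderTypeSpec:
    """Importers/exporters: unlimited volume, limited annual growth."""

    count_inner: int = 6
    count_outer: int = 6
    initial_volume: float = 30000.0   # m3/yr tradable in the first year, per agent
    annual_increase: float = 15000.0  # m3/yr growth cap, per agent
    spread: float = 0.05              # price spread over/under international parity
    transport_factor: float = 0.6     # rail/terminal advantage at the border

    def validate(self, name: str) -> None:
        _check_counts(name, self.count_inner, self.count_outer)
        if self.initial_volume < 0 or self.annual_increase < 0:
            raise ConfigError(f"{name}: volumes must be >= 0")


@dataclass
class PopulationSpec:
    public: SupplierTypeSpec = field(default_factory=lambda: SupplierTypeSpec(
        count_inner=85, count_outer=85,
        mean_supply=3500.0, cv_supply=0.6, min_supply=500.0, max_supply=12000.0,
        soft_share=0.97,
        splits_soft=(0.81, 0.13, 0.06), splits_hard=(0.02, 0.95, 0.03)))
    private: SupplierTypeSpec = field(default_factory=lambda: SupplierTypeSpec(
        count_inner=85, count_outer=85,
        mean_supply=100.0, cv_supply=0.6, min_supply=10.0, max_supply=400.0,
        soft_share=0.60,
        splits_soft=(0.81, 0.15, 0.04), splits_hard=(0.01, 0.96, 0.03)))
    trader: IntermediarySpec = field(default_factory=lambda: IntermediarySpec(
        count_inner=12, count_outer=12))
    bundler: IntermediarySpec = field(default_factory=lambda: IntermediarySpec(
        count_inner=8, count_outer=15))
    sawmill: SawmillSpec = field(default_factory=SawmillSpec)
    industrial: FixedBuyerSpec = field(default_factory=lambda: FixedBuyerSpec(
        count_inner=1, count_outer=2,
        demand_soft=4800.0, demand_hard=1200.0, stock_months=2.0))
    energy: FixedBuyerSpec = field(default_factory=lambda: FixedBuyerSpec(
        count_inner=50, count_outer=50,
        demand_soft=900.0, demand_hard=225.0, stock_months=1.0))
    importer: BorderTypeSpec = field(default_factory=lambda: BorderTypeSpec(
        count_inner=6, count_outer=6, initial_volume=5000.0,
        annual_increase=3000.0, spread=0.25))
    exporter: BorderTypeSpec = field(default_factory=lambda: BorderTypeSpec(
        count_inner=6, count_outer=6, initial_volume=25000.0,
        annual_increase=20000.0, spread=0.0, transport_factor=0.4))

    def validate(self) -> None:
        self.public.validate("public")
        self.private.validate("private")
        self.trader.validate("trader")
        self.bundler.validate("bundler")
        self.sawmill.validate()
        self.industrial.validate("industrial")
        self.energy.validate("energy")
        self.importer.validate("importer")
        self.exporter.validate("exporter")


@dataclass
class TrustSpec:
    initial: float = 0.5        # trust toward phonebook contacts at start-up
    new_contact: float = 0.2    # trust toward a partner first met during the run
    success_step: float = 0.018 # additive increase after a concluded contract
    failure_step: float = 0.018 # additive decrease after a declined negotiation
    floor_weight: float = 0.05  # contact-selection weight floor (discoverability)
    regular_threshold: float = 0.7  # trust above which a buyer counts as regular
    exporter_initial: float = 0.9   # suppliers' trust in exporters at start-up
                                    # (export relationships are long-established)

    def validate(self) -> None:
        for name in ("initial", "new_contact", "regular_threshold",
                     "exporter_initial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"trust.{name} must lie in [0,1]")
        if self.success_step <= 0 or self.failure_step <= 0:
            raise ConfigError("trust steps must be > 0")


@dataclass
class BehaviorSpec:
    """Role behaviour parameters shared by the agents module."""

    base_harvest_fraction: float = 0.90   # planned fraction of max supply at ref prices
    harvest_elasticity_public: float = 0.3   # dlog(target)/dlog(price level)
    harvest_elasticity_private: float = 0.6  # private owners react more strongly
    split_elasticity_public: float = 0.5     # assortment-share shift exponent
    split_elasticity_private: float = 1.0    # "wider scope" for private owners
    season_months: tuple[int, ...] = (0, 1, 2, 8, 9, 10, 11)   # Sep-Mar
    heating_months: tuple[int, ...] = (0, 1, 2, 3, 9, 10, 11)  # Oct-Apr
    reservation: dict[str, float] = field(default_factory=lambda: {
        "sawlogs": 0.42, "energy": 0.55, "industrial": 0.25})
    reservation_release_month: int = 9     # calendar month (0=Jan): Oct onwards open
    reservation_premium: float = 0.10      # price premium unlocking reserved wood
    reservation_unlock: float = 0.95        # share of the reserved pool a good
                                           # price unlocks for non-regulars
    trust_amount_floor: float = 0.15       # minimum trust-scaled share of
                                           # the monthly plan committed to an
                                           # unknown buyer
    month_room_factor: float = 1.3         # catch-up headroom over the even
                                           # monthly harvest plan, within season
    own_consumption: dict[str, float] = field(default_factory=lambda: {
        "sawlogs": 0.10, "energy": 0.60, "industrial": 0.05})
    harvest_cost_base: float = 48.0        # currency/m3 at zero cumulative harvest
    harvest_cost_slope: float = 0.6        # relative increase at full annual cut
    terrain_min: float = 0.8               # per-supplier terrain cost factor range
    terrain_max: float = 1.3
    cost_product_mult: dict[str, float] = field(default_factory=lambda: {
        "sawlogs": 1.0, "industrial": 0.7, "energy": 0.6})
    framework_years_min: int = 5           # energy-wood supply relationships
    framework_years_max: int = 15
    max_initiations: int = 3               # negotiation attempts per agent per round
    max_initiations_large: int = 250       # cap for capacity-scaled budgets, so
                                           # large mills work key accounts rather
                                           # than every supplier every month
    plan_horizon: int = 3                  # months of forthcoming demand considered
    contract_horizon: int = 6              # max months ahead a request may target
    phonebook_size: int = 10               # nearest candidates per counterparty role
    transport_cost_rate: float = 0.35      # currency per m3 per road-km
    byproduct_sell_threshold: float = 0.25 # stock fill ratio that triggers selling

    def validate(self) -> None:
        if not 0 < self.base_harvest_fraction <= 1.0:
            raise ConfigError("base_harvest_fraction must lie in (0,1]")
        for d in (self.reservation, self.own_consumption):
            for prod, v in d.items():
                if prod not in PRODUCTS:
                    raise ConfigError(f"unknown product {prod!r}")
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"fraction for {prod} must lie in [0,1]")
        if not self.season_months:
            raise ConfigError("season_months must be non-empty")


@dataclass
class NegotiationSpec:
    price_spread: float = 0.03      # sd of the initiator's price proposal noise
    buy_discount: float = 0.10      # buyers open below the prevailing price and
                                    # let the responder's counter discover price
    urgency_wtp: float = 0.40       # how strongly unmet demand raises the price
                                    # a buyer tolerates above its reference price
                                    # (quadratic in urgency: only truly starved
                                    # buyers pay far above their anchor)
    anchor_ema: float = 0.01        # monthly weight of new purchases in the
                                    # buyer's personal reference price
    adapt_fraction: float = 1.05    # responder counter: fraction of the gap to
                                    # its reservation price (>1: small markup)
    max_counter_ratio: float = 1.6  # decline instead of countering beyond this
    price_ema: float = 0.3          # monthly prevailing-price update weight

    def validate(self) -> None:
        if self.price_spread < 0:
            raise ConfigError("price_spread must be >= 0")
        if self.adapt_fraction < 1.0:
            raise ConfigError("adapt_fraction must be >= 1 (counter must be "
                              "acceptable to the responder itself)")


@dataclass
class DecisionSpec:
    """Shipped reference part-worth calibration (see decision module).

    The per-criterion part-worths and per-type thresholds are calibration
    parameters of the artifact; criterion values are normalised as documented
    in :mod:`woodmarket.decision`.
    """

    part_worths: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "supplier_sell": {"amount_available": 1.0, "amount_in_demand": 0.5,
                          "trust": 1.5, "margin": 3.0},
        "sawmill_buy": {"urgency": 1.5, "order_size": 0.3,
                        "trust": 0.8, "price": 2.0},
        "sawmill_sell": {"stock_utilization": 1.0, "price": 2.0, "trust": 0.5},
        "energy_buy": {"urgency": 1.5, "price": 1.5, "trust": 0.8},
        "industrial_buy": {"urgency": 1.5, "price": 1.5, "trust": 0.8},
        "trader_buy": {"price": 2.0, "trust": 0.5},
        "trader_sell": {"price": 2.0, "trust": 0.5},
        "bundler_buy": {"margin": 2.0},
        "bundler_sell": {"margin": 2.0},
        "importer_sell": {"price": 4.0},
        "exporter_buy": {"price": 4.0},
    })
    beta0: dict[str, float] = field(default_factory=lambda: {
        "supplier_sell": 3.30,
        "sawmill_buy": 0.5, "sawmill_sell": 0.4,
        "energy_buy": 0.4, "industrial_buy": 0.4,
        "trader_buy": 0.35, "trader_sell": 0.1,
        "bundler_buy": 0.1, "bundler_sell": 0.1,
        "importer_sell": 0.0, "exporter_buy": 0.0,
    })
    heterogeneity_cv: float = 0.08  # lognormal CV of per-agent part-worth noise
    epsilon_scale: float = 0.0      # Gumbel scale of the random component (0=off)

    def validate(self) -> None:
        for model, pws in self.part_worths.items():
            if model not in self.beta0:
                raise ConfigError(f"no beta0 for decision model {model!r}")
            if not pws:
                raise ConfigError(f"empty part-worth set for {model!r}")
        if self.heterogeneity_cv < 0 or self.epsilon_scale < 0:
            raise ConfigError("heterogeneity_cv/epsilon_scale must be >= 0")


@dataclass
class PriceSeriesSpec:
    """Synthetic exogenous international price series (one per assortment)."""

    levels: dict[str, float] = field(default_factory=lambda: {
        "sawlogs_soft": 90.0, "sawlogs_hard": 85.0,
        "industrial_soft": 55.0, "industrial_hard": 50.0,
        "energy_soft": 60.0, "energy_hard": 60.0})
    trend: float = 0.0          # linear drift, fraction of level per year
    ar1_rho: float = 0.95
    ar1_sigma: float = 0.01     # innovation sd, fraction of level
    fx_level: float = 1.0       # exchange rate study-region currency per unit
    fx_rho: float = 0.98
    fx_sigma: float = 0.005
    shocks: list[tuple[int, float]] = field(default_factory=list)
    # each shock: (month, relative jump applied to all assortments from there on)

    def validate(self) -> None:
        for a in ASSORTMENTS:
            if a not in self.levels:
                raise ConfigError(f"missing price level for {a}")
            if self.levels[a] <= 0:
                raise ConfigError(f"price level for {a} must be > 0")
        if self.fx_level <= 0:
            raise ConfigError("fx_level must be > 0")


@dataclass
class SimulationSpec:
    years: int = 20
    start_year: int = 2001
    settle_months: int = 36
    lcm_per_m3: float = 2.5   # loose cubic meters per solid m3 (energy wood)

    def validate(self) -> None:
        if self.years < 0:
            raise ConfigError("years must be >= 0")
        if self.settle_months < 0:
            raise ConfigError("settle_months must be >= 0")

    @property
    def months(self) -> int:
        return 12 * self.years


@dataclass
class FullConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    negotiation: NegotiationSpec = field(default_factory=NegotiationSpec)
    decision: DecisionSpec = field(default_factory=DecisionSpec)
    trust: TrustSpec = field(default_factory=TrustSpec)
    prices: PriceSeriesSpec = field(default_factory=PriceSeriesSpec)
    simulation: SimulationSpec = field(default_factory=SimulationSpec)

    def validate(self) -> "FullConfig":
        self.region.validate()
        self.population.validate()
        self.behavior.validate()
        self.negotiation.validate()
        self.decision.validate()
        self.trust.validate()
        self.prices.validate()
        self.simulation.validate()
        return self

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _plain(dataclasses.asdict(self))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def copy(self) -> "FullConfig":
        return from_dict(self.to_dict())


def _check_counts(name: str, inner: int, outer: int) -> None:
    if inner < 0 or outer < 0:
        raise ConfigError(f"{name}: counts must be >= 0")


def _plain(obj: Any) -> Any:
    """Make a dataclasses.asdict result YAML/JSON friendly (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"splits_soft", "splits_hard", "season_months", "heating_months"}


def from_dict(data: dict[str, Any]) -> FullConfig:
    """Build a validated FullConfig from a (possibly partial) nested dict."""
    cfg = FullConfig()
    for section, value in data.items():
        if not hasattr(cfg, section):
            raise ConfigError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        _apply(target, value, section)
    return cfg.validate()


def _apply(target: Any, value: dict[str, Any], path: str) -> None:
    if not isinstance(value, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    for key, v in value.items():
        if not hasattr(target, key):
            raise ConfigError(f"unknown config field {path}.{key}")
        cur = getattr(target, key)
        if dataclasses.is_dataclass(cur):
            _apply(cur, v, f"{path}.{key}")
        elif key in _TUPLE_FIELDS:
            setattr(target, key, tuple(v))
        elif key == "shocks":
            setattr(target, key, [tuple(s) for s in v])
        else:
            setattr(target, key, v)


def load_config(path) -> FullConfig:
    """Load, default-resolve and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return from_dict(data)


def save_config(cfg: FullConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def reference_config() -> FullConfig:
    """The shipped reference configuration (study-region quantity structure)."""
    return FullConfig().validate()


# ---------------------------------------------------------------------------
# RNG substreams
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one root seed.

    Each stochastic component (region layout, shuffles, decisions, prices,
    ...) draws from its own stream, so changing the number of draws of one
    component does not perturb the others; this keeps paired seed
    comparisons across scenario sweeps stable.
    """
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), tag])))


# ---------------------------------------------------------------------------
# exogenous price series
# ---------------------------------------------------------------------------

def make_price_series(spec: PriceSeriesSpec, months: int, seed: int):
    """Generate synthetic international price series and an exchange rate.

    Per assortment: level x (1 + trend) x AR(1) multiplicative noise, plus
    step shocks.  Returns ``(prices, fx)`` where ``prices`` is a DataFrame
    (months x assortments, currency/m3) and ``fx`` a Series of length
    ``months``.
    """
    import pandas as pd

    if months < 1:
        raise ConfigError("months must be >= 1")
    spec.validate()
    rng = substream(seed, "prices")
    t = np.arange(months)
    shock_mult = np.ones(months)
    for month_k, jump in spec.shocks:
        if 0 <= month_k < months:
            shock_mult[month_k:] *= 1.0 + jump
    out = {}
    for a in ASSORTMENTS:
        noise = _ar1(rng, months, spec.ar1_rho, spec.ar1_sigma)
        base = spec.levels[a] * (1.0 + spec.trend * t / 12.0)
        out[a] = base * (1.0 + noise) * shock_mult
    fx_noise = _ar1(rng, months, spec.fx_rho, spec.fx_sigma)
    fx = pd.Series(spec.fx_level * (1.0 + fx_noise), name="fx")
    return pd.DataFrame(out), fx


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = innov[0]
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x
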