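"""Simulation loop, market rounds and the bilateral negotiation protocol.

A run simulates ``years`` x 12 monthly steps.  Each month the six assortment
markets execute one round each, in fixed order (sawlogs before the byproduct
markets, softwood before hardwood).  A round performs five steps on a seeded
shuffle of the market's participants:

1. every participant may try to conclude new contracts (for the current or a
   forthcoming month, considering demand, stock and existing contracts);
2. sellers prepare deliveries (suppliers harvest to order);
3. sellers deliver;
4. intermediaries deliver (so wood can pass supplier -> trader -> mill
   within one month);
5. buyers process the deliveries (mills saw, consumers burn or pulp).

Contracts are concluded through a three-message bilateral protocol: the
initiator sends a *request* (assortment, amount, price, delivery month); the
responder accepts it as-is, adapts price and/or amount, or declines; if not
declined the responder replies with an *offer*, which the initiator finally
accepts or declines without further modification.  Both accept decisions use
the strict random-utility rule of :mod:`woodmarket.decision`.  Concluding a
contract raises mutual phonebook trust; a decline lowers it.  An agent never
compares simultaneous offers: each is judged on its own.

The run is a pure function of (configuration, seed, events): all randomness
flows from named substreams of the root seed and all iteration orders are
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import agents as roles
from .config import FullConfig, make_price_series, substream
from .decision import (ContextState, PartWorthTable, PhonebookEntry,
                       build_context, decision_model_for, price_coefficient,
                       select_contacts, update_trust, utility)
from .markets import ASSORTMENTS, A_INDEX, product_of
from .region import (Agent, BORDER_TYPES, INTERMEDIARY_TYPES, SUPPLIER_TYPES,
                     draw_supply_profiles, generate_region, place_agents)

MIN_LOT = 5.0               # m3; smaller requests are not worth a negotiation
REF_MILL_CAPACITY = 2300.0  # m3/yr; initiation budget scales with mill size


# ---------------------------------------------------------------------------
# messages and contracts
# ---------------------------------------------------------------------------

@dataclass
class NegotiationMessage:
    kind: str              # 'request' | 'offer'
    assortment: str
    amount: float          # m3
    price: float           # currency / m3
    month_due: int

    def adapted(self, price: float, amount: float) -> "NegotiationMessage":
        """An offer may differ from the request only in price and/or amount."""
        return NegotiationMessage("offer", self.assortment, amount, price,
                                  self.month_due)


@dataclass
class Contract:
    id: int
    buyer: int
    seller: int
    assortment: str
    amount: float
    price: float
    month_made: int
    month_due: int
    delivered: float = 0.0
    status: str = "open"   # open | partial | fulfilled | failed
    framework: bool = False


@dataclass
class SimulationClock:
    years: int
    month: int = 0

    @property
    def months(self) -> int:
        return 12 * self.years

    def calendar(self, m: int | None = None) -> int:
        return (self.month if m is None else m) % 12


@dataclass
class RoundLog:
    market: str
    month: int
    negotiations: int = 0
    contracts: int = 0
    volume: float = 0.0


@dataclass
class AgentRT:
    """Runtime wrapper: core agent plus role state, phonebook, part-worths."""

    core: Agent
    phonebook: dict[int, PhonebookEntry] = field(default_factory=dict)
    pw: dict[str, PartWorthTable] = field(default_factory=dict)
    supplier: roles.SupplierState | None = None
    proc: roles.ProcessorState | None = None
    consumer: roles.ConsumerState | None = None
    trader: roles.TraderState | None = None
    border: roles.BorderAgentState | None = None
    active: bool = True
    entered_month: int = 0
    id: int = -1
    type: str = ""
    pb_version: int = 0
    price_anchor: dict[str, float] = field(default_factory=dict)
    # EMA of the agent's own past purchase prices per assortment; the
    # buyer's sticky reference for what wood "should" cost

    def __post_init__(self):
        self.id = self.core.id
        self.type = self.core.type

    def stock_total(self) -> float:
        s = 0.0
        if self.supplier:
            s += sum(self.supplier.stock.values())
        if self.proc:
            s += sum(self.proc.stock.values())
            s += sum(self.proc.byproduct_stock.values())
        if self.consumer:
            s += sum(self.consumer.stock.values())
        if self.trader:
            s += sum(self.trader.stock.values())
        return s


@dataclass
class SimulationResult:
    """Per-month, per-agent and aggregated records of one run."""

    agents: pd.DataFrame
    agent_month: pd.DataFrame      # inner-zone agents only
    prices: pd.DataFrame           # per month: vw price, volume, prevailing
    contracts: pd.DataFrame
    meta: dict

    def to_dir(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        self.agents.to_csv(f"{path}/agents.csv", index=False,
                           float_format="%.6f")
        self.agent_month.to_csv(f"{path}/agent_month.csv", index=False,
                                float_format="%.6f")
        self.prices.to_csv(f"{path}/prices.csv", index=False,
                           float_format="%.6f")
        self.contracts.to_csv(f"{path}/contracts.csv", index=False,
                              float_format="%.6f")
        with open(f"{path}/meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# scenario events
# ---------------------------------------------------------------------------

@dataclass
class AgentEntry:
    """A processor entering the market mid-run (e.g. a bulk purchaser)."""

    month: int
    type: str = "sawmill"
    capacity: float = 0.0
    x: float = 0.0
    y: float = 0.0
    zone: str = "inner"
    transport_factor: float = 1.0   # site advantage (rail/highway access)
    label: str = "entrant"
    processing_start: Optional[int] = None  # first operating month (deliveries
                                            # before it are stock build-up)


@dataclass
class AgentExit:
    month: int
    label: str


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class Engine:
    """One simulation run.  See the module docstring for the scheduling."""

    def __init__(self, config: FullConfig, seed: int,
                 events: Optional[list] = None,
                 trace_ids: Optional[set[int]] = None,
                 trace_sink: Optional[Callable] = None,
                 part_worth_overrides: Optional[dict] = None,
                 record_agent_month: bool = True):
        config.validate()
        self.cfg = config
        self.trust_cfg = config.trust
        self.seed = int(seed)
        self.events = sorted(events or [], key=lambda e: (e.month, e.label))
        self.trace_ids = trace_ids or set()
        self.trace_sink = trace_sink
        self.pw_overrides = part_worth_overrides or {}
        self.record_agent_month = record_agent_month
        self.clock = SimulationClock(config.simulation.years)

        self.rng_shuffle = substream(seed, "shuffle")
        self.rng_decide = substream(seed, "decide")
        self.rng_hetero = substream(seed, "partworths")

        self.region = generate_region(config.region, seed)
        base_agents = place_agents(self.region, config.population, seed)
        draw_supply_profiles(base_agents, config.population, seed)
        n_months = max(1, self.clock.months
                       + config.behavior.contract_horizon + 1)
        prices_df, fx = make_price_series(config.prices, n_months, seed)
        self.intl_prices = prices_df.to_numpy()
        self.fx = fx.to_numpy()
        self.ref_price = {a: config.prices.levels[a] for a in ASSORTMENTS}
        self.prevailing = dict(self.ref_price)

        self.rt: dict[int, AgentRT] = {}
        self._next_agent_id = 0
        self._next_contract_id = 0
        self._flows: dict[int, np.ndarray] = {}   # [produced, received, delivered, consumed]
        self._counts: dict[int, np.ndarray] = {}  # [req_in, req_in_ok, req_out] x assortment
        self._prev_stock: dict[int, float] = {}
        for a in base_agents:
            self._register(a)
            self._next_agent_id = max(self._next_agent_id, a.id + 1)
        self._init_phonebooks()

        self.due: dict[tuple[str, int], list[Contract]] = {}
        self.contracts: list[Contract] = []
        self.frameworks: dict[tuple[int, int, str], dict] = {}
        self.labels: dict[str, int] = {}
        self._rows: list[dict] = []
        self._price_rows: list[dict] = []
        self._month_txn = {a: [0.0, 0.0] for a in ASSORTMENTS}
        self.max_depth = 0
        self.conservation_residual = 0.0
        self._cand_cache: dict = {}
        self._participants: dict[str, list] = {}
        self._reset_scratch()

    # -- construction -----------------------------------------------------

    def _register(self, core: Agent, entered: int = 0) -> AgentRT:
        cfg, beh = self.cfg, self.cfg.behavior
        rt = AgentRT(core=core, entered_month=entered)
        t = core.type
        if t in SUPPLIER_TYPES:
            rt.supplier = roles.SupplierState(
                agent=core, beh=beh,
                elastic_amount=(beh.harvest_elasticity_public if t == "public"
                                else beh.harvest_elasticity_private),
                elastic_split=(beh.split_elasticity_public if t == "public"
                               else beh.split_elasticity_private),
                own_consumption=(dict(beh.own_consumption) if t == "private"
                                 else {}))
        elif t == "sawmill":
            sm = cfg.population.sawmill
            rt.proc = roles.ProcessorState(
                agent=core,
                yields={"energy": sm.byproduct_energy,
                        "industrial": sm.byproduct_industrial},
                stock_months=sm.stock_months)
        elif t == "industrial":
            rt.consumer = roles.ConsumerState(
                agent=core,
                demand={"industrial_soft": core.demand_soft,
                        "industrial_hard": core.demand_hard},
                active_months=tuple(range(12)),
                stock_months=cfg.population.industrial.stock_months)
        elif t == "energy":
            rt.consumer = roles.ConsumerState(
                agent=core,
                demand={"energy_soft": core.demand_soft,
                        "energy_hard": core.demand_hard},
                active_months=tuple(beh.heating_months),
                stock_months=cfg.population.energy.stock_months)
        elif t in INTERMEDIARY_TYPES:
            spec = getattr(cfg.population, t)
            rt.trader = roles.TraderState(
                agent=core, monthly_volume=spec.monthly_volume,
                min_margin=spec.min_margin,
                affiliates=(frozenset(core.affiliates) if t == "bundler"
                            else frozenset()))
        elif t in BORDER_TYPES:
            spec = getattr(cfg.population, t)
            core.transport_factor = spec.transport_factor
            rt.border = roles.BorderAgentState(
                agent=core, side="import" if t == "importer" else "export",
                prices=self.intl_prices, fx=self.fx, spread=spec.spread,
                initial_volume=spec.initial_volume,
                annual_increase=spec.annual_increase)
        rt.pw = self._draw_part_worths(t)
        self.rt[core.id] = rt
        self._flows[core.id] = np.zeros(4)
        self._counts[core.id] = np.zeros((3, 6))
        self._prev_stock[core.id] = 0.0
        return rt

    def _draw_part_worths(self, agent_type: str,
                          heterogeneous: bool = True) -> dict[str, PartWorthTable]:
        """Per-agent heterogeneous part-worths (multiplicative lognormal)."""
        dec = self.cfg.decision
        cv = dec.heterogeneity_cv if heterogeneous else 0.0
        sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
        out: dict[str, PartWorthTable] = {}
        for side in ("buy", "sell"):
            try:
                model = decision_model_for(agent_type, side)
            except Exception:
                continue
            base = dict(dec.part_worths[model])
            over = self.pw_overrides.get(model, {})
            base.update(over.get("betas", {}))
            betas = {}
            for crit in sorted(base):
                f = (math.exp(self.rng_hetero.normal(-sigma * sigma / 2.0,
                                                     sigma))
                     if sigma > 0 else 1.0)
                betas[crit] = base[crit] * f
            beta0 = over.get("beta0", dec.beta0[model])
            if sigma > 0:   # thresholds are individual estimates as well
                beta0 *= math.exp(self.rng_hetero.normal(
                    -sigma * sigma / 2.0, sigma))
            out[model] = PartWorthTable(betas=betas, beta0=beta0,
                                        epsilon_scale=dec.epsilon_scale)
        return out

    def _init_phonebooks(self) -> None:
        """Nearest candidates per counterparty role, at the initial trust."""
        k = self.cfg.behavior.phonebook_size
        ids = list(self.rt)
        pos = {i: (self.rt[i].core.x, self.rt[i].core.y) for i in ids}
        sellers = {a: [i for i in ids if self.rt[i].core.sells(a)]
                   for a in ASSORTMENTS}
        buyers = {a: [i for i in ids if self.rt[i].core.buys(a)]
                  for a in ASSORTMENTS}
        t0 = self.trust_cfg.initial
        exporters = [i for i in ids if self.rt[i].type == "exporter"]
        importers = [i for i in ids if self.rt[i].type == "importer"]
        for i in ids:
            rt = self.rt[i]
            wanted: set[int] = set()
            for a in ASSORTMENTS:
                if rt.core.buys(a):
                    wanted.update(self._nearest(i, sellers[a], pos, k))
                if rt.core.sells(a):
                    wanted.update(self._nearest(i, buyers[a], pos, k))
            # border agents are well-known outlets along the border
            if rt.supplier is not None or rt.trader is not None:
                wanted.update(self._nearest(i, exporters, pos, 4))
            if rt.proc is not None or rt.consumer is not None \
                    or rt.trader is not None:
                wanted.update(self._nearest(i, importers, pos, 2))
            if rt.type == "bundler":
                wanted.update(rt.core.affiliates)
            for j in sorted(wanted):
                trust = t0
                if (self.rt[j].type == "exporter"
                        and (rt.supplier is not None
                             or rt.trader is not None)):
                    trust = self.trust_cfg.exporter_initial
                rt.phonebook[j] = PhonebookEntry(contact_id=j, trust=trust)

    @staticmethod
    def _nearest(i: int, candidates: list[int], pos: dict, k: int) -> list[int]:
        cand = [c for c in candidates if c != i]
        cand.sort(key=lambda c: ((pos[c][0] - pos[i][0]) ** 2
                                 + (pos[c][1] - pos[i][1]) ** 2, c))
        return cand[:k]

    def _reset_scratch(self) -> None:
        self._harv_scratch: dict[int, np.ndarray] = {}
        self._deliv_scratch: dict[int, np.ndarray] = {}
        self._recv_scratch: dict[int, np.ndarray] = {}
        self._proc_scratch: dict[int, float] = {}

    # -- small helpers -----------------------------------------------------

    def _ensure_contact(self, rt: AgentRT, other: int) -> PhonebookEntry:
        e = rt.phonebook.get(other)
        if e is None:
            e = PhonebookEntry(contact_id=other,
                               trust=self.trust_cfg.new_contact)
            rt.phonebook[other] = e
            rt.pb_version += 1
        return e

    def trust_of(self, rt: AgentRT, other: int) -> float:
        e = rt.phonebook.get(other)
        return e.trust if e else self.trust_cfg.new_contact

    def road_distance(self, a: AgentRT, b: AgentRT) -> float:
        return self.region.distance(a.core, b.core)

    def transport_cost(self, buyer: AgentRT, seller: AgentRT) -> float:
        """Transport cost in currency/m3, borne by the buyer."""
        return (self.cfg.behavior.transport_cost_rate
                * self.road_distance(buyer, seller)
                * buyer.core.transport_factor)

    def year_of(self, month: int) -> int:
        return self.cfg.simulation.start_year + month // 12

    # -- demand / supply coverage -----------------------------------------

    def buyer_need(self, rt: AgentRT, a: str, m: int) -> tuple[float, float]:
        """(uncovered, planned) demand over the planning horizon, in m3."""
        H = self.cfg.behavior.plan_horizon
        if rt.proc is not None and a.startswith("sawlogs"):
            if a == "sawlogs_hard":
                md = rt.core.hardwood_demand / 12.0
                planned = md * H
                have = rt.proc.stock.get(a, 0.0)
            else:
                md = rt.proc.monthly_demand
                active = sum(1 for mm in range(m, m + H)
                             if mm >= rt.proc.start_month)
                planned = md * active + 0.5 * rt.proc.stock_capacity
                have = sum(rt.proc.stock.values())
            have += sum(rt.proc.contracted_in.get((a, mm), 0.0)
                        for mm in range(m, m + H))
            return max(0.0, planned - have), max(planned, 1e-9)
        if rt.consumer is not None:
            c = rt.consumer
            planned = sum(c.monthly_demand(a, (m + j) % 12) for j in range(H))
            planned += 0.5 * c.stock_months * c.demand.get(a, 0.0) / max(
                1, len(c.active_months))
            have = c.stock.get(a, 0.0) + sum(
                c.contracted_in.get((a, mm), 0.0) for mm in range(m, m + H))
            return max(0.0, planned - have), max(planned, 1e-9)
        if rt.trader is not None:
            t = rt.trader
            have = t.stock.get(a, 0.0) + t.bought_this_month.get(a, 0.0)
            return max(0.0, t.monthly_volume - have), max(t.monthly_volume,
                                                          1e-9)
        if rt.border is not None:   # exporter
            allow = rt.border.allowance(self.year_of(m))
            return allow, max(allow, 1e-9)
        return 0.0, 1.0

    def seller_avail(self, rt: AgentRT, a: str, m: int,
                     buyer_trust: float = 1.0,
                     premium: bool = False) -> float:
        """Volume the seller can still commit for delivery month ``m``.

        Suppliers scale the amount they commit to one buyer with their trust
        in that buyer: an unknown customer can only buy small amounts and
        must prove reliability before volumes grow.  A price above the
        premium threshold (``premium``) unlocks part of the reserved pool
        for non-regulars.
        """
        beh = self.cfg.behavior
        if rt.supplier is not None:
            s = rt.supplier
            if s.plan is None:
                return 0.0
            in_season = (m % 12) in beh.season_months
            monthly = (s.plan.monthly.get(a, 0.0) * beh.month_room_factor
                       if in_season else 0.0)
            month_room = max(0.0, monthly - s.committed.get((a, m), 0.0))
            if m == self.clock.month:
                month_room += s.stock.get(a, 0.0)
            regular = buyer_trust >= self.trust_cfg.regular_threshold
            reg, nonreg = roles.available_pools(s, a, m)
            if regular:
                pool = reg
            elif premium:
                pool = nonreg + beh.reservation_unlock * (reg - nonreg)
            else:
                pool = nonreg
            if not regular:
                frac = max(beh.trust_amount_floor,
                           buyer_trust / self.trust_cfg.regular_threshold)
                if premium:   # a good price buys a larger allocation
                    frac = max(frac, beh.reservation_unlock)
                month_room *= min(1.0, frac)
            return min(month_room, pool)
        if rt.trader is not None:
            return rt.trader.available(a, m)
        if rt.proc is not None:     # byproducts
            return rt.proc.byproduct_stock.get(a, 0.0)
        if rt.border is not None:   # importer
            return rt.border.allowance(self.year_of(m))
        return 0.0

    # -- decision contexts -------------------------------------------------

    def make_context(self, rt: AgentRT, side: str, other: AgentRT,
                     msg: NegotiationMessage):
        """Build the deciding agent's normalisation state and context."""
        a = msg.assortment
        st = ContextState(ref_price=self.ref_price[a],
                          trust=self.trust_of(rt, other.id))
        if side == "sell" and rt.supplier is not None:
            s = rt.supplier
            st.remaining_annual = s.remaining_annual(a)
            st.annual_plan = s.plan.annual.get(a, 0.0) if s.plan else 0.0
            st.monthly_plan = s.plan.monthly.get(a, 0.0) if s.plan else 0.0
            st.harvest_cost = s.harvesting_cost(product_of(a))
        elif side == "sell" and rt.proc is not None:
            cap = max(1e-9, 0.5 * rt.proc.stock_capacity)
            st.stock_utilization = rt.proc.byproduct_stock.get(a, 0.0) / cap
            st.cost_basis = 0.5 * self.ref_price[a]
        elif side == "sell" and rt.trader is not None:
            st.prevailing = self.prevailing[a]
            st.cost_basis = rt.trader.cost_basis.get(a, self.prevailing[a])
            st.min_margin = rt.trader.min_margin
        elif side == "sell" and rt.border is not None:
            st.border_price = rt.border.border_price(a, msg.month_due)
        elif side == "buy":
            st.transport = self.transport_cost(rt, other)
            if rt.trader is not None:
                st.prevailing = self.prevailing[a]
                st.min_margin = rt.trader.min_margin
            elif rt.border is not None:
                st.border_price = rt.border.border_price(a, msg.month_due)
            else:
                unc, planned = self.buyer_need(rt, a, self.clock.month)
                st.uncovered, st.horizon_demand = unc, planned
                if rt.proc is not None:
                    st.monthly_need = (rt.proc.monthly_demand
                                       if a == "sawlogs_soft"
                                       else rt.core.hardwood_demand / 12.0)
                elif rt.consumer is not None:
                    st.monthly_need = rt.consumer.demand.get(a, 0.0) / max(
                        1, len(rt.consumer.active_months))
        return st, build_context(rt.type, side, msg.price, msg.amount, st)

    # -- negotiation protocol ---------------------------------------------

    def negotiate(self, initiator: AgentRT, responder: AgentRT,
                  req: NegotiationMessage, init_side: str) -> Contract | None:
        """Run the three-message protocol; returns the contract or None.

        The responder may adapt price and/or amount only; the initiator's
        final decision cannot modify the offer.  Negotiation depth never
        exceeds three messages.
        """
        a = req.assortment
        resp_side = "buy" if init_side == "sell" else "sell"
        tr = self.trust_cfg
        self._ensure_contact(initiator, responder.id)
        self._ensure_contact(responder, initiator.id)
        ai = A_INDEX[a]
        self._counts[initiator.id][2, ai] += 1    # outgoing request
        self._counts[responder.id][0, ai] += 1    # incoming request
        depth = 1
        outcome, reason = "declined", "infeasible"
        contract = None
        u_resp = u_init = None
        ctx = ictx = pw = ipw = None

        if resp_side == "sell":
            buyer_trust = self.trust_of(responder, initiator.id)
            regular = buyer_trust >= tr.regular_threshold
            if (responder.type == "bundler"
                    and initiator.id not in responder.trader.affiliates):
                avail = 0.0
            else:
                avail = self.seller_avail(responder, a, req.month_due,
                                          buyer_trust)
        else:
            regular = True
            unc, _ = self.buyer_need(responder, a, self.clock.month)
            avail = unc
        amount = min(req.amount, avail)

        if amount >= MIN_LOT:
            probe = req.adapted(req.price, amount)
            st, ctx = self.make_context(responder, resp_side, initiator, probe)
            pw = responder.pw[decision_model_for(responder.type, resp_side)]
            u_resp = utility(pw, ctx, self.rng_decide)
            depth = 2
            anchor = None
            if resp_side == "buy" and (responder.proc is not None
                                       or responder.consumer is not None):
                # willingness to pay above the buyer's own reference price
                # rises with unmet demand (insufficient utilisation)
                neg = self.cfg.negotiation
                ref = responder.price_anchor.get(
                    a, self.prevailing[a] * (1.0 - neg.buy_discount))
                urg = ctx.get("urgency", 0.0)
                anchor = ref * (1.0 + neg.urgency_wtp * urg ** 3)
            if u_resp > 0.0:
                if anchor is not None and req.price > anchor:
                    offer = probe.adapted(anchor, amount)
                else:
                    offer = probe
            else:
                offer = self._counter(responder, resp_side, req, amount,
                                      u_resp, pw, st)
                if offer is not None and anchor is not None \
                        and offer.price > anchor:
                    offer = offer.adapted(anchor, offer.amount)
            if (offer is not None and resp_side == "sell"
                    and responder.supplier is not None and not regular
                    and (initiator.proc is not None
                         or initiator.consumer is not None)
                    and offer.amount < req.amount - MIN_LOT):
                # reservations are not absolute: a good price unlocks part
                # of the amounts reserved for regular customers
                thresh = self.prevailing[a] * (
                    1.0 + self.cfg.behavior.reservation_premium)
                full = self.seller_avail(responder, a, req.month_due,
                                         buyer_trust, premium=True)
                if full > offer.amount + MIN_LOT:
                    offer = offer.adapted(max(offer.price, thresh),
                                          min(req.amount, full))
            if offer is None:
                reason = "responder declined"
            else:
                depth = 3
                _, ictx = self.make_context(initiator, init_side, responder,
                                            offer)
                ipw = initiator.pw[decision_model_for(initiator.type,
                                                      init_side)]
                u_init = utility(ipw, ictx, self.rng_decide)
                if u_init > 0.0:
                    contract = self._conclude(initiator, responder, offer,
                                              init_side, regular)
                    outcome = "concluded"
                else:
                    reason = "initiator declined offer"

        self.max_depth = max(self.max_depth, depth)
        if contract is not None:
            self._counts[responder.id][1, ai] += 1
            for rt, other in ((initiator, responder), (responder, initiator)):
                update_trust(rt.phonebook[other.id], "success",
                             tr.success_step, tr.failure_step,
                             self.clock.month)
        elif depth > 1:
            # trust suffers from declined decisions, not from a partner who
            # simply had nothing available this month
            for rt, other in ((initiator, responder), (responder, initiator)):
                update_trust(rt.phonebook[other.id], "failure",
                             tr.success_step, tr.failure_step,
                             self.clock.month)
        if self.trace_sink is not None and (
                initiator.id in self.trace_ids
                or responder.id in self.trace_ids):
            def _terms(c, p):
                if c is None or p is None:
                    return None
                t = {k: p.betas[k] * v for k, v in c.items()}
                t["beta0"] = -p.beta0
                return t

            self.trace_sink({
                "kind": "negotiation", "month": self.clock.month,
                "assortment": a, "initiator": initiator.id,
                "responder": responder.id,
                "request": {"amount": round(req.amount, 3),
                            "price": round(req.price, 4),
                            "month_due": req.month_due},
                "utility_responder": u_resp, "utility_initiator": u_init,
                "terms_responder": _terms(ctx, pw),
                "terms_initiator": _terms(ictx, ipw),
                "outcome": outcome, "reason": reason, "depth": depth,
            })
        return contract

    def _counter(self, responder: AgentRT, side: str, req: NegotiationMessage,
                 amount: float, u_now: float, pw: PartWorthTable,
                 st: ContextState) -> NegotiationMessage | None:
        """Adapt the price toward the responder's reservation value.

        The price-like criterion is linear in price, so the price at which
        the responder is indifferent (U = 0) has a closed form; the counter
        moves the whole gap plus a small configurable markup, so a counter
        is always acceptable to the responder itself.  Beyond the maximum
        counter ratio the responder declines instead.
        """
        kp = price_coefficient(responder.type, side, pw) / max(st.ref_price,
                                                               1e-9)
        if kp == 0.0:
            return None
        p_res = req.price - u_now / kp
        price = req.price + self.cfg.negotiation.adapt_fraction * (
            p_res - req.price)
        ratio = self.cfg.negotiation.max_counter_ratio
        if price <= 0.0:
            return None
        if side == "sell" and price > req.price * ratio:
            return None
        if side == "buy" and price < req.price / ratio:
            return None
        return req.adapted(price, amount)

    # -- contract bookkeeping ---------------------------------------------

    def _conclude(self, initiator: AgentRT, responder: AgentRT,
                  offer: NegotiationMessage, init_side: str,
                  regular: bool) -> Contract:
        buyer, seller = ((initiator, responder) if init_side == "buy"
                         else (responder, initiator))
        c = Contract(id=self._next_contract_id, buyer=buyer.id,
                     seller=seller.id, assortment=offer.assortment,
                     amount=offer.amount, price=offer.price,
                     month_made=self.clock.month, month_due=offer.month_due)
        self._next_contract_id += 1
        self.contracts.append(c)
        self.due.setdefault((c.assortment, c.month_due), []).append(c)
        old = buyer.price_anchor.get(c.assortment)
        w = self.cfg.negotiation.anchor_ema
        buyer.price_anchor[c.assortment] = (c.price if old is None
                                            else (1 - w) * old + w * c.price)
        self._register_commitments(c, buyer, seller, regular)
        self._maybe_framework(buyer, seller, c)
        return c

    def _register_commitments(self, c: Contract, buyer: AgentRT,
                              seller: AgentRT, regular: bool) -> None:
        a, m = c.assortment, c.month_due
        if seller.supplier is not None:
            s = seller.supplier
            s.committed[(a, m)] = s.committed.get((a, m), 0.0) + c.amount
            s.annual_committed[a] = s.annual_committed.get(a, 0.0) + c.amount
            if not regular:
                s.sold_nonregular[a] = s.sold_nonregular.get(a, 0.0) + c.amount
        elif seller.trader is not None:
            t = seller.trader
            t.committed_out[(a, m)] = t.committed_out.get((a, m), 0.0) \
                + c.amount
        elif seller.border is not None:
            seller.border.record(self.year_of(m), c.amount)
        if buyer.proc is not None:
            buyer.proc.contracted_in[(a, m)] = \
                buyer.proc.contracted_in.get((a, m), 0.0) + c.amount
        elif buyer.consumer is not None:
            buyer.consumer.contracted_in[(a, m)] = \
                buyer.consumer.contracted_in.get((a, m), 0.0) + c.amount
        elif buyer.border is not None:
            buyer.border.record(self.year_of(m), c.amount)

    def _maybe_framework(self, buyer: AgentRT, seller: AgentRT,
                         c: Contract) -> None:
        """Energy-wood relationships become multi-year framework contracts
        (re-executed monthly during the heating period)."""
        if c.framework or not c.assortment.startswith("energy"):
            return
        if buyer.type != "energy" or seller.supplier is None:
            return
        key = (buyer.id, seller.id, c.assortment)
        if key in self.frameworks:
            return
        beh = self.cfg.behavior
        years = int(self.rng_decide.integers(beh.framework_years_min,
                                             beh.framework_years_max + 1))
        self.frameworks[key] = {"amount": c.amount,
                                "until": self.clock.month + 12 * years}

    # -- monthly execution ------------------------------------------------

    def run(self) -> SimulationResult:
        for m in range(self.clock.months):
            self.clock.month = m
            self._apply_events(m)
            if m % 12 == 0:
                self._annual_planning()
            logs = [self.execute_market_round(a, m) for a in ASSORTMENTS]
            self._end_of_month(m, logs)
        return self._result()

    def _apply_events(self, m: int) -> None:
        for ev in self.events:
            if ev.month != m:
                continue
            if isinstance(ev, AgentEntry):
                core = Agent(id=self._next_agent_id, type=ev.type,
                             zone=ev.zone, x=ev.x, y=ev.y,
                             capacity=ev.capacity,
                             transport_factor=ev.transport_factor)
                self._next_agent_id += 1
                rt = self._register(core, entered=m)
                # a scenario entrant is a specific firm: it gets the exact
                # configured part-worths, not a population draw
                rt.pw = self._draw_part_worths(core.type, heterogeneous=False)
                if rt.proc is not None and ev.processing_start is not None:
                    rt.proc.start_month = ev.processing_start
                self.labels[ev.label] = core.id
                shift = getattr(ev, "beta0_shift", 0.0)
                if shift:   # willingness to pay acts on the buying threshold
                    for model, pw in rt.pw.items():
                        if model.endswith("_buy"):
                            pw.beta0 += shift
                # the entrant scouts every counterparty; incumbents meet it
                # only when contacted, at the new-contact trust level
                tnew = self.trust_cfg.new_contact
                for j, other in self.rt.items():
                    if j == core.id:
                        continue
                    if any(other.core.sells(a) and core.buys(a)
                           for a in ASSORTMENTS):
                        rt.phonebook[j] = PhonebookEntry(contact_id=j,
                                                         trust=tnew)
            elif isinstance(ev, AgentExit):
                aid = self.labels.get(ev.label)
                if aid is not None:
                    self.rt[aid].active = False
            self._cand_cache.clear()
            self._participants.clear()

    def _annual_planning(self) -> None:
        view = roles.PriceView(dict(self.prevailing), dict(self.ref_price))
        for rt in self.rt.values():
            if rt.supplier is not None:
                rt.supplier.reset_year()
                roles.plan_annual_supply(rt.supplier, view)
            if rt.proc is not None:
                rt.proc.processed_ytd = 0.0

    def execute_market_round(self, a: str, m: int) -> RoundLog:
        """One market, one month: seeded shuffle, then the five steps."""
        log = RoundLog(market=a, month=m)
        participants = self._participants.get(a)
        if participants is None:
            participants = [rt for rt in self.rt.values()
                            if rt.active and (rt.core.buys(a)
                                              or rt.core.sells(a))]
            self._participants[a] = participants
        order = self.rng_shuffle.permutation(len(participants))
        self._auto_frameworks(a, m)
        for idx in order:                       # step 1: new contracts
            log.negotiations += self.make_new_contracts(
                participants[int(idx)], a, m, log)
        due_by_seller: dict[int, float] = {}
        for c in self.due.get((a, m), []):
            due_by_seller[c.seller] = due_by_seller.get(c.seller, 0.0) \
                + (c.amount - c.delivered)
        for rt in participants:                 # step 2: prepare deliveries
            if rt.supplier is not None and rt.id in due_by_seller:
                self._harvest_for_due(rt, a, due_by_seller[rt.id])
        due = self.due.pop((a, m), [])
        for c in due:                           # step 3: sellers deliver
            if self.rt[c.seller].trader is None:
                self._deliver(c)
        for c in due:                           # step 4: intermediaries deliver
            if self.rt[c.seller].trader is not None:
                self._deliver(c)
        for rt in participants:                 # step 5: buyers process
            self._process_step(rt, a, m)
        return log

    def _auto_frameworks(self, a: str, m: int) -> None:
        if not a.startswith("energy") or not self.frameworks:
            return
        if (m % 12) not in self.cfg.behavior.heating_months:
            return
        for key in list(self.frameworks):
            buyer_id, seller_id, fa = key
            if fa != a:
                continue
            fw = self.frameworks[key]
            if m > fw["until"]:
                del self.frameworks[key]
                continue
            buyer, seller = self.rt.get(buyer_id), self.rt.get(seller_id)
            if buyer is None or seller is None or not buyer.active:
                continue
            avail = self.seller_avail(seller, a, m, 1.0)
            unc, _ = self.buyer_need(buyer, a, m)
            amt = min(fw["amount"], avail, unc)
            if amt < MIN_LOT:
                continue
            c = Contract(id=self._next_contract_id, buyer=buyer_id,
                         seller=seller_id, assortment=a, amount=amt,
                         price=self.prevailing[a], month_made=m, month_due=m,
                         framework=True)
            self._next_contract_id += 1
            self.contracts.append(c)
            self.due.setdefault((a, m), []).append(c)
            self._register_commitments(c, buyer, seller, True)

    # -- step 1: initiating new contracts ----------------------------------

    def make_new_contracts(self, rt: AgentRT, a: str, m: int,
                           log: RoundLog | None = None) -> int:
        """Initiate up to the agent's budget of negotiations; stop when
        the uncovered need or unsold plan is exhausted."""
        n = 0
        if rt.core.buys(a):
            n += self._initiate_buys(rt, a, m, log)
        if rt.core.sells(a) and rt.type != "importer":
            n += self._initiate_sells(rt, a, m, log)
        return n

    def _budget(self, rt: AgentRT) -> int:
        """Negotiation attempts per round; scales with processing size so an
        aggregated-scale mill can realistically work many suppliers."""
        base = self.cfg.behavior.max_initiations
        if rt.proc is not None and rt.core.capacity > REF_MILL_CAPACITY:
            scaled = int(math.ceil(base * rt.core.capacity
                                   / REF_MILL_CAPACITY))
            return min(scaled, self.cfg.behavior.max_initiations_large)
        if rt.border is not None:   # aggregated border gateways
            return 3 * base
        return base

    def _candidates(self, rt: AgentRT, a: str, selling: bool,
                    allowed: frozenset | None = None) -> list[PhonebookEntry]:
        key = (rt.id, a, selling)
        cached = self._cand_cache.get(key)
        if cached is not None and cached[0] == rt.pb_version:
            return cached[1]
        out = []
        for e in rt.phonebook.values():
            other = self.rt.get(e.contact_id)
            if other is None or not other.active:
                continue
            if allowed is not None and e.contact_id not in allowed:
                continue
            ok = other.core.buys(a) if selling else other.core.sells(a)
            if ok:
                out.append(e)
        self._cand_cache[key] = (rt.pb_version, out)
        return out

    def _initiate_buys(self, rt: AgentRT, a: str, m: int, log) -> int:
        if (rt.trader is not None or rt.border is not None) \
                and (m % 12) not in self.cfg.behavior.season_months:
            return 0
        uncovered, _ = self.buyer_need(rt, a, m)
        if uncovered < MIN_LOT:
            return 0
        allowed = (rt.trader.affiliates if rt.type == "bundler" else None)
        sellers = self._candidates(rt, a, selling=False, allowed=allowed)
        picks = select_contacts(sellers, self._budget(rt), self.rng_decide,
                                self.trust_cfg.floor_weight)
        if not picks:
            return 0
        if rt.proc is not None or rt.consumer is not None:
            # imports are the marginal source: approach border gateways
            # after the domestic candidates
            picks.sort(key=lambda cid: self.rt[cid].border is not None)
        lot = max(MIN_LOT, uncovered / len(picks))
        if rt.border is not None:   # exporters procure in supplier-sized lots
            lot = min(lot, 600.0)
        neg = self.cfg.negotiation
        count = 0
        for cid in picks:
            if uncovered < MIN_LOT:
                break
            amount = min(lot, uncovered)
            if self.rt[cid].border is not None:
                # border gateways can serve any amount (up to their cap):
                # ask for the whole uncovered need
                amount = uncovered
            month_due = self._earliest_deficit_month(rt, a, m)
            base = self.prevailing[a] * (1.0 - neg.buy_discount)
            if rt.trader is None:
                base = min(base, rt.price_anchor.get(a, base))
            price = base * (1.0 + self.rng_decide.normal(0.0, neg.price_spread)
                            - (rt.trader.min_margin
                               if rt.trader is not None else 0.0))
            req = NegotiationMessage("request", a, amount,
                                     max(price, 0.01), month_due)
            c = self.negotiate(rt, self.rt[cid], req, "buy")
            count += 1
            if c is not None:
                uncovered = max(0.0, uncovered - c.amount)
                if log:
                    log.contracts += 1
                    log.volume += c.amount
        return count

    def _earliest_deficit_month(self, rt: AgentRT, a: str, m: int) -> int:
        """Delivery month for a new request: the earliest month of the
        planning horizon whose contracted inflow does not yet cover need."""
        last = self.clock.months - 1
        for mm in range(m, min(m + self.cfg.behavior.plan_horizon, last + 1)):
            if rt.proc is not None:
                need = (rt.proc.monthly_demand if a == "sawlogs_soft"
                        else rt.core.hardwood_demand / 12.0)
                got = rt.proc.contracted_in.get((a, mm), 0.0)
            elif rt.consumer is not None:
                need = rt.consumer.monthly_demand(a, mm % 12)
                got = rt.consumer.contracted_in.get((a, mm), 0.0)
            else:
                return m
            if got < need - 1e-9:
                return mm
        return m

    def _initiate_sells(self, rt: AgentRT, a: str, m: int, log) -> int:
        if rt.supplier is not None:
            unsold = self.seller_avail(rt, a, m, 1.0)
        elif rt.proc is not None:
            cap = max(1e-9, 0.5 * rt.proc.stock_capacity)
            if (rt.proc.byproduct_stock.get(a, 0.0) / cap
                    < self.cfg.behavior.byproduct_sell_threshold):
                return 0
            unsold = rt.proc.byproduct_stock.get(a, 0.0)
        elif rt.trader is not None:
            unsold = rt.trader.available(a, m)
        else:
            return 0
        if unsold < MIN_LOT:
            return 0
        buyers = self._candidates(rt, a, selling=True)
        picks = select_contacts(buyers, self.cfg.behavior.max_initiations,
                                self.rng_decide, self.trust_cfg.floor_weight)
        if not picks:
            return 0
        lot = max(MIN_LOT, unsold / len(picks))
        spread = self.cfg.negotiation.price_spread
        count = 0
        for cid in picks:
            if unsold < MIN_LOT:
                break
            price = self.prevailing[a] * (
                1.0 + self.rng_decide.normal(0.0, spread))
            price = max(price, 0.01,
                        self._own_sell_reservation(rt, a, cid,
                                                   min(lot, unsold), m))
            req = NegotiationMessage("request", a, min(lot, unsold),
                                     price, m)
            c = self.negotiate(rt, self.rt[cid], req, "sell")
            count += 1
            if c is not None:
                unsold = max(0.0, unsold - c.amount)
                if log:
                    log.contracts += 1
                    log.volume += c.amount
        return count

    def _own_sell_reservation(self, rt: AgentRT, a: str, buyer_id: int,
                              amount: float, m: int) -> float:
        """The lowest price at which the initiating seller itself accepts.

        A seller proposes at least this (it would decline its own final
        check otherwise); toward trusted regulars the reservation lies
        below the prevailing price, toward unknown buyers above it.
        """
        probe = NegotiationMessage("request", a, amount,
                                   self.prevailing[a], m)
        st, ctx = self.make_context(rt, "sell", self.rt[buyer_id], probe)
        pw = rt.pw[decision_model_for(rt.type, "sell")]
        u = utility(pw, ctx, self.rng_decide)
        if u > 0.0:
            return 0.0
        kp = price_coefficient(rt.type, "sell", pw) / max(st.ref_price, 1e-9)
        if kp <= 0.0:
            return 0.0
        return (self.prevailing[a] - u / kp) * 1.02

    # -- steps 2-5: physical flows ----------------------------------------

    def _harvest_for_due(self, rt: AgentRT, a: str, due: float) -> None:
        """Harvest to order: cut what this month's contracts require."""
        s = rt.supplier
        need = max(0.0, due - s.stock.get(a, 0.0))
        if need <= 0.0:
            return
        room = max(0.0, rt.core.max_supply - s.harvested_ytd)
        cut = min(need, room)
        if cut <= 0.0:
            return
        s.harvested_ytd += cut
        s.stock[a] = s.stock.get(a, 0.0) + cut
        self._flows[rt.id][0] += cut
        arr = self._harv_scratch.setdefault(rt.id, np.zeros(6))
        arr[A_INDEX[a]] += cut

    def _deliver(self, c: Contract) -> None:
        seller, buyer = self.rt[c.seller], self.rt[c.buyer]
        a = c.assortment
        remaining = c.amount - c.delivered
        if remaining <= 0 or not buyer.active or not seller.active:
            c.status = "fulfilled" if c.delivered >= c.amount - 1e-9 \
                else "failed"
            return
        if seller.supplier is not None:
            avail = seller.supplier.stock.get(a, 0.0)
        elif seller.trader is not None:
            avail = seller.trader.stock.get(a, 0.0)
        elif seller.proc is not None:
            avail = seller.proc.byproduct_stock.get(a, 0.0)
        else:                                    # importer: created at border
            avail = remaining
        if buyer.proc is not None and a.startswith("sawlogs"):
            headroom = buyer.proc.stock_headroom(a)
        elif buyer.consumer is not None:
            headroom = buyer.consumer.stock_headroom(a) \
                + buyer.consumer.monthly_demand(a, self.clock.calendar())
        else:
            headroom = remaining
        amt = min(remaining, avail, headroom)
        if amt > 0:
            self._move_wood(seller, buyer, a, amt, c.price)
            c.delivered += amt
            txn = self._month_txn[a]
            txn[0] += amt
            txn[1] += amt * c.price
        if c.delivered >= c.amount - 1e-9:
            c.status = "fulfilled"
        elif amt < remaining and avail < remaining:
            # the seller failed to serve a concluded contract
            c.status = "failed"
            e = buyer.phonebook.get(seller.id)
            if e is not None:
                update_trust(e, "failure", self.trust_cfg.success_step,
                             self.trust_cfg.failure_step, self.clock.month)
        else:
            c.status = "partial"

    def _move_wood(self, seller: AgentRT, buyer: AgentRT, a: str,
                   amt: float, price: float) -> None:
        fs, fb = self._flows[seller.id], self._flows[buyer.id]
        if seller.supplier is not None:
            seller.supplier.stock[a] = seller.supplier.stock.get(a, 0.0) - amt
        elif seller.trader is not None:
            seller.trader.stock[a] = seller.trader.stock.get(a, 0.0) - amt
        elif seller.proc is not None:
            seller.proc.byproduct_stock[a] = \
                seller.proc.byproduct_stock.get(a, 0.0) - amt
        elif seller.border is not None:
            fs[0] += amt             # imported wood enters at the border
        fs[2] += amt                 # delivered
        fb[1] += amt                 # received
        ai = A_INDEX[a]
        self._deliv_scratch.setdefault(seller.id, np.zeros(6))[ai] += amt
        self._recv_scratch.setdefault(buyer.id, np.zeros(6))[ai] += amt
        if buyer.proc is not None and a.startswith("sawlogs"):
            buyer.proc.stock[a] = buyer.proc.stock.get(a, 0.0) + amt
        elif buyer.consumer is not None:
            buyer.consumer.stock[a] = buyer.consumer.stock.get(a, 0.0) + amt
        elif buyer.trader is not None:
            buyer.trader.record_purchase(a, amt, price)
        elif buyer.border is not None:
            fb[3] += amt             # exported wood leaves the model

    def _process_step(self, rt: AgentRT, a: str, m: int) -> None:
        cal = self.clock.calendar()
        if rt.proc is not None and a == "sawlogs_soft":
            p = rt.proc
            if m < p.start_month:
                return
            run = min(sum(p.stock.values()), p.monthly_demand)
            if run > 0:
                total = sum(p.stock.values())
                for k in list(p.stock):
                    p.stock[k] -= p.stock[k] / total * run
                by = roles.process_deliveries(p, run)
                self._flows[rt.id][3] += run
                self._flows[rt.id][0] += sum(by.values())
                y = self.year_of(m)
                p.processed_by_year[y] = p.processed_by_year.get(y, 0.0) + run
                self._proc_scratch[rt.id] = \
                    self._proc_scratch.get(rt.id, 0.0) + run
        elif rt.consumer is not None and rt.core.buys(a):
            c = rt.consumer
            use = min(c.stock.get(a, 0.0), c.monthly_demand(a, cal))
            if use > 0:
                c.stock[a] = c.stock.get(a, 0.0) - use
                self._flows[rt.id][3] += use
                y = self.year_of(m)
                c.consumed_by_year[y] = c.consumed_by_year.get(y, 0.0) + use

    # -- month end ---------------------------------------------------------

    def _end_of_month(self, m: int, logs: list[RoundLog]) -> None:
        # conservation: d(stock) == produced + received - delivered - consumed
        for aid, rt in self.rt.items():
            stock = rt.stock_total()
            f = self._flows[aid]
            resid = abs(stock - self._prev_stock[aid]
                        - (f[0] + f[1] - f[2] - f[3]))
            if resid > self.conservation_residual:
                self.conservation_residual = resid
            self._prev_stock[aid] = stock
        alpha = self.cfg.negotiation.price_ema
        row: dict = {"month": m}
        for a in ASSORTMENTS:
            vol, val = self._month_txn[a]
            if vol > 0:
                mean = val / vol
                self.prevailing[a] = ((1 - alpha) * self.prevailing[a]
                                      + alpha * mean)
            else:
                mean = np.nan
                # drift back toward international parity when nothing traded
                parity = float(self.intl_prices[m, A_INDEX[a]] * self.fx[m])
                self.prevailing[a] = ((1 - 0.5 * alpha) * self.prevailing[a]
                                      + 0.5 * alpha * parity)
            row[f"price_{a}"] = mean
            row[f"volume_{a}"] = vol
            row[f"prevailing_{a}"] = self.prevailing[a]
            self._month_txn[a] = [0.0, 0.0]
        self._price_rows.append(row)
        if self.record_agent_month:
            self._record_agent_month(m)
        if self.trace_sink is not None:
            self._record_snapshots(m)
        for aid in self.rt:
            self._counts[aid][:] = 0.0
            self._flows[aid][:] = 0.0
        self._reset_scratch()
        for rt in self.rt.values():
            if rt.trader is not None:
                rt.trader.bought_this_month = {}

    def _record_agent_month(self, m: int) -> None:
        zeros = None
        for aid, rt in self.rt.items():
            if rt.core.zone != "inner" or not rt.active:
                continue
            if zeros is None:
                zeros = np.zeros(6)
            harv = self._harv_scratch.get(aid, zeros)
            dl = self._deliv_scratch.get(aid, zeros)
            rcv = self._recv_scratch.get(aid, zeros)
            cnt = self._counts[aid]
            rec = {"month": m, "agent": aid, "type": rt.type,
                   "stock": rt.stock_total(),
                   "processed": self._proc_scratch.get(aid, 0.0),
                   "capacity": rt.core.capacity}
            for a, ai in A_INDEX.items():
                rec[f"harvested_{a}"] = float(harv[ai])
                rec[f"delivered_{a}"] = float(dl[ai])
                rec[f"received_{a}"] = float(rcv[ai])
                rec[f"req_in_{a}"] = float(cnt[0, ai])
                rec[f"req_in_ok_{a}"] = float(cnt[1, ai])
                rec[f"req_out_{a}"] = float(cnt[2, ai])
            self._rows.append(rec)

    def _record_snapshots(self, m: int) -> None:
        from .trace import record_snapshot

        for aid in sorted(self.trace_ids):
            rt = self.rt.get(aid)
            if rt is not None:
                self.trace_sink(record_snapshot(rt, m))

    # -- result ------------------------------------------------------------

    _CONTRACT_COLS = ["id", "buyer", "seller", "buyer_type", "seller_type",
                      "assortment", "amount", "price", "month_made",
                      "month_due", "delivered", "status", "framework",
                      "distance_km"]

    def _result(self) -> SimulationResult:
        from .region import agents_to_frame

        agents = agents_to_frame([rt.core for rt in self.rt.values()])
        agents["active"] = [self.rt[i].active for i in agents["id"]]
        agent_month = pd.DataFrame(self._rows)
        prices = pd.DataFrame(self._price_rows)
        if self.contracts:
            contracts = pd.DataFrame([{
                "id": c.id, "buyer": c.buyer, "seller": c.seller,
                "buyer_type": self.rt[c.buyer].type,
                "seller_type": self.rt[c.seller].type,
                "assortment": c.assortment, "amount": c.amount,
                "price": c.price, "month_made": c.month_made,
                "month_due": c.month_due, "delivered": c.delivered,
                "status": c.status, "framework": c.framework,
                "distance_km": self.road_distance(self.rt[c.buyer],
                                                  self.rt[c.seller]),
            } for c in self.contracts])
        else:
            contracts = pd.DataFrame(columns=self._CONTRACT_COLS)
        meta = {
            "config_hash": self.cfg.hash(),
            "seed": self.seed,
            "version": "0.1.0",
            "months": self.clock.months,
            "start_year": self.cfg.simulation.start_year,
            "conservation_residual": self.conservation_residual,
            "max_negotiation_depth": self.max_depth,
            "labels": dict(self.labels),
        }
        return SimulationResult(agents=agents, agent_month=agent_month,
                                prices=prices, contracts=contracts, meta=meta)


def run_simulation(config: FullConfig, seed: int,
                   events: Optional[list] = None,
                   trace_ids: Optional[set[int]] = None,
                   trace_sink: Optional[Callable] = None,
                   part_worth_overrides: Optional[dict] = None,
                   record_agent_month: bool = True) -> SimulationResult:
    """Execute one full run; a pure function of (config, seed, events)."""
    eng = Engine(config, seed, events=events, trace_ids=trace_ids,
                 trace_sink=trace_sink,
                 part_worth_overrides=part_worth_overrides,
                 record_agent_month=record_agent_month)
    return eng.run()
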