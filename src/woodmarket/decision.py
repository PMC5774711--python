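"""Random-utility decision core, per-type decision criteria and trust.

Every accept/decline decision in the model evaluates one linear
random-utility function

    U = sum_i beta_i * c_i + epsilon - beta0

where ``beta_i`` is the part-worth utility of criterion ``i``, ``c_i`` its
numerical value in the current situation, ``epsilon`` a random component
(constant 0 by default) and ``beta0`` the minimum utility an option must
clear.  A request or offer is accepted iff U is strictly greater than zero.

Criterion values are normalised to documented scales so that the shipped
part-worth calibration is interpretable:

=====================  =====================================================
criterion              scale
=====================  =====================================================
trust                  phonebook trust in [0, 1]
urgency                uncovered forthcoming demand / planned demand, [0, 1]
order_size             requested amount / monthly need, capped at 1
amount_available       remaining annual plan / annual plan, [0, 1]
amount_in_demand       requested amount / monthly plan, capped at 1
margin (suppliers)     (price - harvesting cost) / reference price
price (buyers)         (reference price - price - transport) / reference price
price (traders)        resale margin vs prevailing price / reference price
price (border agents)  signed gap to the international parity price
stock_utilization      byproduct stock / stock capacity, [0, 1]
=====================  =====================================================

Trust lives in per-agent "phonebooks": trust increases after successful
negotiations, decreases after unsuccessful ones, and always stays in [0, 1].
Contacts with higher trust have a proportionally higher chance of being
considered when initiating a negotiation.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "PartWorthTable", "DecisionContext", "PhonebookEntry", "ContextState",
    "utility", "accept", "build_context", "update_trust", "select_contacts",
    "decision_model_for", "CRITERIA",
]


class DecisionError(ValueError):
    """A context/part-worth contract violation (a bug, not a market outcome)."""


DecisionContext = dict  # criterion name -> normalised numeric value


@dataclass
class PartWorthTable:
    """Part-worth utilities and threshold for one agent's decision model."""

    betas: dict[str, float]
    beta0: float = 0.0
    epsilon_scale: float = 0.0   # Gumbel scale of the random component; 0 = off

    def validate_for(self, criteria: Iterable[str]) -> None:
        missing = [c for c in criteria if c not in self.betas]
        if missing:
            raise DecisionError(f"part-worth table lacks criteria {missing}")


def utility(pw: PartWorthTable, ctx: DecisionContext,
            rng: Optional[np.random.Generator] = None) -> float:
    """Total utility of a request/offer: sum(beta_i c_i) + epsilon - beta0."""
    total = 0.0
    betas = pw.betas
    for crit, value in ctx.items():
        try:
            total += betas[crit] * value
        except KeyError:
            raise DecisionError(f"no part-worth for criterion {crit!r}") from None
    if pw.epsilon_scale > 0.0:
        if rng is None:
            raise DecisionError("epsilon enabled but no rng supplied")
        total += float(rng.gumbel(0.0, pw.epsilon_scale))
    return total - pw.beta0


def accept(u: float) -> bool:
    """Strict acceptance rule: accepted iff the total utility exceeds zero."""
    return u > 0.0


# ---------------------------------------------------------------------------
# per-type decision criteria
# ---------------------------------------------------------------------------

#: Decision criteria per (agent type, market side), the artifact's encoding of
#: the study-region objectives: suppliers weigh remaining cut, demand match,
#: trust and margin; sawmills buying weigh urgency, order size, trust, price;
#: bundlers use a bare margin; border agents price only.
CRITERIA: dict[str, tuple[str, ...]] = {
    "supplier_sell": ("amount_available", "amount_in_demand", "trust", "margin"),
    "sawmill_buy": ("urgency", "order_size", "trust", "price"),
    "sawmill_sell": ("stock_utilization", "price", "trust"),
    "energy_buy": ("urgency", "price", "trust"),
    "industrial_buy": ("urgency", "price", "trust"),
    "trader_buy": ("price", "trust"),
    "trader_sell": ("price", "trust"),
    "bundler_buy": ("margin",),
    "bundler_sell": ("margin",),
    "importer_sell": ("price",),
    "exporter_buy": ("price",),
}

_MODEL_BY_TYPE_SIDE = {
    ("public", "sell"): "supplier_sell",
    ("private", "sell"): "supplier_sell",
    ("sawmill", "buy"): "sawmill_buy",
    ("sawmill", "sell"): "sawmill_sell",
    ("energy", "buy"): "energy_buy",
    ("industrial", "buy"): "industrial_buy",
    ("trader", "buy"): "trader_buy",
    ("trader", "sell"): "trader_sell",
    ("bundler", "buy"): "bundler_buy",
    ("bundler", "sell"): "bundler_sell",
    ("importer", "sell"): "importer_sell",
    ("exporter", "buy"): "exporter_buy",
}


def decision_model_for(agent_type: str, side: str) -> str:
    try:
        return _MODEL_BY_TYPE_SIDE[(agent_type, side)]
    except KeyError:
        raise DecisionError(
            f"no decision criteria defined for {agent_type!r} on side {side!r}"
        ) from None


@dataclass
class ContextState:
    """Normalisation inputs the engine supplies when building a context.

    Only the fields relevant to the deciding agent's model need to be set;
    ``ref_price`` is the configured reference price of the assortment and is
    the common denominator of all price-like criteria.
    """

    ref_price: float = 1.0
    trust: float = 0.0
    # supplier sell
    remaining_annual: float = 0.0
    annual_plan: float = 0.0
    monthly_plan: float = 0.0
    harvest_cost: float = 0.0
    # buyers
    uncovered: float = 0.0
    horizon_demand: float = 0.0
    monthly_need: float = 0.0
    transport: float = 0.0
    # intermediaries
    prevailing: float = 0.0
    cost_basis: float = 0.0
    min_margin: float = 0.0
    # byproducts
    stock_utilization: float = 0.0
    # border agents
    border_price: float = 0.0


def build_context(agent_type: str, side: str, price: float, amount: float,
                  state: ContextState) -> DecisionContext:
    """Compute exactly the criteria of the agent type's decision model.

    ``side`` is the deciding agent's market side for this negotiation
    ("buy" or "sell"); ``price`` and ``amount`` come from the message under
    evaluation.  Raises :class:`DecisionError` for a type/side combination
    with no defined criteria.
    """
    model = decision_model_for(agent_type, side)
    ref = state.ref_price if state.ref_price > 0 else 1.0
    ctx: DecisionContext = {}
    for crit in CRITERIA[model]:
        if crit == "trust":
            ctx[crit] = _clamp01(state.trust)
        elif crit == "amount_available":
            plan = state.annual_plan
            ctx[crit] = _clamp01(state.remaining_annual / plan) if plan > 0 else 0.0
        elif crit == "amount_in_demand":
            mp = state.monthly_plan
            ctx[crit] = min(amount / mp, 1.0) if mp > 0 else 0.0
        elif crit == "margin" and model == "supplier_sell":
            ctx[crit] = (price - state.harvest_cost) / ref
        elif crit == "margin":  # intermediaries: resale margin requirement
            if side == "buy":
                ctx[crit] = (state.prevailing * (1.0 - state.min_margin)
                             - price - state.transport) / ref
            else:
                ctx[crit] = (price - state.cost_basis * (1.0 + state.min_margin)) / ref
        elif crit == "urgency":
            hd = state.horizon_demand
            ctx[crit] = _clamp01(state.uncovered / hd) if hd > 0 else 0.0
        elif crit == "order_size":
            mn = state.monthly_need
            ctx[crit] = min(amount / mn, 1.0) if mn > 0 else 0.0
        elif crit == "price" and model in ("energy_buy", "industrial_buy",
                                           "sawmill_buy"):
            ctx[crit] = (ref - price - state.transport) / ref
        elif crit == "price" and model == "trader_buy":
            ctx[crit] = (state.prevailing * (1.0 - state.min_margin)
                         - price - state.transport) / ref
        elif crit == "price" and model == "trader_sell":
            ctx[crit] = (price - state.cost_basis * (1.0 + state.min_margin)) / ref
        elif crit == "price" and model == "sawmill_sell":
            ctx[crit] = (price - state.cost_basis) / ref
        elif crit == "price" and model == "importer_sell":
            ctx[crit] = (price - state.border_price) / ref
        elif crit == "price" and model == "exporter_buy":
            ctx[crit] = (state.border_price - price - state.transport) / ref
        elif crit == "stock_utilization":
            ctx[crit] = _clamp01(state.stock_utilization)
        else:  # pragma: no cover - CRITERIA and branches kept in sync
            raise DecisionError(f"unhandled criterion {crit!r} for {model!r}")
    return ctx


def price_coefficient(agent_type: str, side: str, pw: PartWorthTable) -> float:
    """dU/dprice (per currency unit, before the 1/ref scaling).

    Positive for sellers (higher price raises utility), negative for buyers.
    Used by the negotiation protocol to solve for a responder's reservation
    price; the clamp-free price-like criteria above are linear in price.
    """
    model = decision_model_for(agent_type, side)
    crit = "margin" if "margin" in CRITERIA[model] else "price"
    if crit not in CRITERIA[model]:
        return 0.0
    beta = pw.betas[crit]
    return beta if side == "sell" else -beta


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


# ---------------------------------------------------------------------------
# phonebook and trust
# ---------------------------------------------------------------------------

@dataclass
class PhonebookEntry:
    contact_id: int
    trust: float
    last_month: int = -1
    successes: int = 0
    failures: int = 0

    def __post_init__(self):
        if not 0.0 <= self.trust <= 1.0:
            raise DecisionError("trust must lie in [0,1]")


def update_trust(entry: PhonebookEntry, outcome: str,
                 success_step: float = 0.05, failure_step: float = 0.10,
                 month: int | None = None) -> PhonebookEntry:
    """Additive, asymmetric trust update, clamped to [0, 1].

    A success strictly increases trust (unless already 1), a failure
    strictly decreases it (unless already 0); trust is easier to lose than
    to gain under the default steps.
    """
    if outcome == "success":
        entry.trust = min(1.0, entry.trust + success_step)
        entry.successes += 1
    elif outcome == "failure":
        entry.trust = max(0.0, entry.trust - failure_step)
        entry.failures += 1
    else:
        raise DecisionError(f"unknown outcome {outcome!r}")
    if month is not None:
        entry.last_month = month
    return entry


def load_part_worth_file(path) -> tuple[dict[str, dict[str, float]],
                                        dict[str, float]]:
    """Load part-worths and thresholds from a tabular text file.

    Rows are ``model,criterion,beta``; a criterion of ``beta0`` carries the
    model's threshold.  Every criterion of each model's criteria set must be
    present; unknown models or criteria are rejected.
    """
    import csv

    betas: dict[str, dict[str, float]] = {}
    beta0: dict[str, float] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")))]
    for r in rows:
        model, crit = r["model"], r["criterion"]
        if model not in CRITERIA:
            raise DecisionError(f"unknown decision model {model!r}")
        value = float(r["beta"])
        if crit == "beta0":
            beta0[model] = value
        elif crit not in CRITERIA[model]:
            raise DecisionError(f"criterion {crit!r} not defined for {model!r}")
        else:
            betas.setdefault(model, {})[crit] = value
    for model, crits in CRITERIA.items():
        missing = [c for c in crits if c not in betas.get(model, {})]
        if missing:
            raise DecisionError(f"{model}: missing part-worths for {missing}")
        if model not in beta0:
            raise DecisionError(f"{model}: missing beta0")
    return betas, beta0


def selection_weight(trust: float, floor: float = 0.05) -> float:
    """Contact-selection weight: trust plus a discoverability floor."""
    return trust + floor


def select_contacts(phonebook: list[PhonebookEntry], k: int,
                    rng: np.random.Generator, floor: float = 0.05) -> list[int]:
    """Sample ``k`` distinct contacts, weight increasing in trust.

    Sampling is without replacement with probability proportional to
    ``trust + floor`` (Gumbel top-k, equivalent to successive draws).  If
    ``k`` is at least the phonebook size, all contacts are returned in
    phonebook order.
    """
    if k < 0:
        raise DecisionError("k must be >= 0")
    if k == 0 or not phonebook:
        return []
    if k >= len(phonebook):
        return [e.contact_id for e in phonebook]
    n = len(phonebook)
    g = rng.gumbel(size=n)
    if n <= 64:
        keys = [math.log(phonebook[i].trust + floor) + g[i] for i in range(n)]
        top = heapq.nlargest(k, range(n), key=keys.__getitem__)
        return [phonebook[i].contact_id for i in top]
    w = np.array([e.trust + floor for e in phonebook])
    keys = np.log(w) + g
    top = np.argpartition(-keys, k - 1)[:k]
    top = top[np.argsort(-keys[top])]
    return [phonebook[int(i)].contact_id for i in top]
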