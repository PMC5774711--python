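"""Post-run statistics and survey-style reference comparison.

After a run settles in (the first simulated years are excluded because the
trading-relationship network needs time to form), the evaluators reduce the
monthly records to the validation surface used for this class of market
models: annual produced amounts by ownership and assortment, processed
amounts, quarterly volume-weighted prices, and micro statistics comparable
to practitioner surveys — requests in/out per agent-year, rejection rates,
supply perimeters, transport-cost shares, supplier-type shares of sawmill
deliveries, business-relationship durations and stock utilisation.  Each
micro statistic is reported as a mean and inter-quartile range over agents
and compared against packaged reference values with a three-level rating
("+" inside the reference IQR, "0" near miss, "-" otherwise).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FullConfig
from .markets import ASSORTMENTS, product_of


class EvaluationError(ValueError):
    pass


@dataclass
class ReferenceTable:
    """One reference variable: empirical average, IQR bounds, priority."""

    variable: str
    mean: float
    iqr_lo: float = np.nan
    iqr_hi: float = np.nan
    unit: str = ""
    priority: str = "high"       # high | medium | low | omitted

    def __post_init__(self):
        if np.isfinite(self.iqr_lo) and np.isfinite(self.iqr_hi) \
                and self.iqr_lo > self.iqr_hi:
            raise EvaluationError(f"{self.variable}: IQR lower > upper")


@dataclass
class RunSummary:
    """Reduced validation surface of one run (or an average of runs)."""

    stats: pd.DataFrame          # variable, mean, q25, q75
    production: pd.DataFrame     # owner_type x assortment annual mean, m3/yr
    prices: pd.DataFrame         # quarterly volume-weighted mean prices
    settle_months: int = 0
    n_months: int = 0

    def value(self, variable: str) -> float:
        row = self.stats.loc[self.stats["variable"] == variable]
        return float(row["mean"].iloc[0]) if len(row) else float("nan")


@dataclass
class Rating:
    variable: str
    simulated: float
    reference: float
    iqr_lo: float
    iqr_hi: float
    rating: str                  # '+', '0', '-', '?' (uncompared)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def supply_perimeter(distances, volumes, coverage: float = 0.9) -> float:
    """Minimum radius containing strictly more than ``coverage`` of volume.

    ``distances`` are delivery road distances (km), ``volumes`` the delivered
    m3.  Distances are scanned outward; the perimeter is the smallest
    delivery distance at which the cumulative sourced volume exceeds the
    coverage share.  Removing deliveries beyond the perimeter can only
    shrink it (monotonicity).
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if d.shape != v.shape or d.size == 0 or v.sum() <= 0:
        return float("nan")
    order = np.argsort(d, kind="stable")
    cum = np.cumsum(v[order])
    target = coverage * cum[-1]
    idx = int(np.searchsorted(cum, target, side="right"))
    idx = min(idx, d.size - 1)
    return float(d[order][idx])


def relationship_durations(ledger: pd.DataFrame,
                           months_per_year: int = 12) -> pd.Series:
    """Business-relationship duration per buyer-seller pair, in years.

    The duration of a pair is its longest streak of consecutive simulated
    years with at least one concluded contract.  Returns a Series indexed
    by (buyer, seller).
    """
    if len(ledger) == 0:
        return pd.Series(dtype=float)
    df = ledger[["buyer", "seller", "month_made"]].copy()
    df["year"] = df["month_made"] // months_per_year
    out = {}
    for (b, s), grp in df.groupby(["buyer", "seller"]):
        years = sorted(set(grp["year"]))
        best = cur = 1
        for i in range(1, len(years)):
            cur = cur + 1 if years[i] == years[i - 1] + 1 else 1
            best = max(best, cur)
        out[(b, s)] = float(best)
    return pd.Series(out, dtype=float)


def long_term_share(durations: pd.Series, threshold_years: float = 10.0) -> float:
    """Share of relationships lasting more than ``threshold_years``."""
    if len(durations) == 0:
        return float("nan")
    return float((durations > threshold_years).mean())


def _mean_iqr(values) -> tuple[float, float, float]:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    return float(v.mean()), float(np.percentile(v, 25)), \
        float(np.percentile(v, 75))


# ---------------------------------------------------------------------------
# run summary
# ---------------------------------------------------------------------------

def summarize_run(result, config: FullConfig | None = None,
                  settle_months: int | None = None) -> RunSummary:
    """Reduce one run to the validation surface.

    The first ``settle_months`` (default: the configured settle-in period)
    are excluded from every statistic.  Only inner-zone agents enter the
    summary; rows are means and IQRs over agents (and agent-years for the
    request statistics).
    """
    cfg = config or FullConfig()
    settle = cfg.simulation.settle_months if settle_months is None \
        else settle_months
    am = result.agent_month
    n_months = int(result.meta["months"])
    if settle >= n_months:
        raise EvaluationError("settle_months >= run length: nothing to "
                              "summarize")
    rows: list[dict] = []

    def add(variable, values):
        mean, lo, hi = _mean_iqr(values)
        rows.append({"variable": variable, "mean": mean, "q25": lo,
                     "q75": hi})

    am = am[am["month"] >= settle] if len(am) else am
    contracts = result.contracts
    if len(contracts):
        contracts = contracts[(contracts["month_due"] >= settle)
                              & (contracts["delivered"] > 0)]
    years_eval = max(1, (n_months - settle) // 12)

    # -- production by owner type and assortment (inner zone, m3/yr)
    prod_rows = []
    for owner in ("public", "private"):
        sub = am[am["type"] == owner] if len(am) else am
        for a in ASSORTMENTS:
            tot = float(sub[f"harvested_{a}"].sum()) if len(sub) else 0.0
            prod_rows.append({"owner": owner, "assortment": a,
                              "annual_m3": tot / years_eval})
    production = pd.DataFrame(prod_rows)

    # -- processed amounts
    mills = am[am["type"] == "sawmill"] if len(am) else am
    add("sawmill_processed_annual",
        [g["processed"].sum() / years_eval
         for _, g in mills.groupby("agent")] if len(mills) else [])

    # -- request statistics per agent-year
    def per_agent_year(sub: pd.DataFrame, cols: list[str]):
        if not len(sub):
            return []
        g = sub.assign(year=sub["month"] // 12)
        tot = g.groupby(["agent", "year"])[cols].sum().sum(axis=1)
        return list(tot)

    pfm = am[am["type"] == "public"] if len(am) else am
    for prod_name in ("sawlogs", "energy", "industrial"):
        cols_in = [f"req_in_{prod_name}_soft", f"req_in_{prod_name}_hard"]
        cols_ok = [f"req_in_ok_{prod_name}_soft",
                   f"req_in_ok_{prod_name}_hard"]
        add(f"pfm_requests_in_{prod_name}", per_agent_year(pfm, cols_in))
        if len(pfm):
            g = pfm.assign(year=pfm["month"] // 12)
            tot = g.groupby(["agent", "year"])[cols_in].sum().sum(axis=1)
            ok = g.groupby(["agent", "year"])[cols_ok].sum().sum(axis=1)
            rej = (1.0 - ok[tot > 0] / tot[tot > 0]) * 100.0
            add(f"pfm_rejection_rate_{prod_name}", list(rej))
        else:
            add(f"pfm_rejection_rate_{prod_name}", [])
    saw_in = ["req_in_sawlogs_soft", "req_in_sawlogs_hard"]
    saw_out = ["req_out_sawlogs_soft", "req_out_sawlogs_hard"]
    add("sawmill_requests_in", per_agent_year(mills, saw_in))
    add("sawmill_requests_out", per_agent_year(mills, saw_out))
    ebuy = am[am["type"] == "energy"] if len(am) else am
    add("energy_requests_in",
        per_agent_year(ebuy, ["req_in_energy_soft", "req_in_energy_hard"]))
    add("energy_requests_out",
        per_agent_year(ebuy, ["req_out_energy_soft", "req_out_energy_hard"]))

    # -- stock utilisation (sawmills; stock relative to warehouse capacity)
    if len(mills):
        util = []
        for agent, g in mills.groupby("agent"):
            cap = g["capacity"].iloc[0] / 12.0 * \
                cfg.population.sawmill.stock_months
            if cap > 0:
                util.append(float(g["stock"].mean() / cap) * 100.0)
        add("sawmill_stock_utilization", util)
    else:
        add("sawmill_stock_utilization", [])

    # -- contract-ledger statistics (inner-zone buyers)
    inner_ids = set(result.agents.loc[result.agents["zone"] == "inner", "id"])
    sawlog_del = contracts[
        contracts["assortment"].str.startswith("sawlogs")
        & (contracts["buyer_type"] == "sawmill")
        & contracts["buyer"].isin(inner_ids)] if len(contracts) else contracts

    perims, tshares = [], []
    shares = {"public": [], "bundler": [], "trader": []}
    per_supplier = {"public": [], "bundler": [], "trader": []}
    if len(sawlog_del):
        rate = cfg.behavior.transport_cost_rate
        for buyer, g in sawlog_del.groupby("buyer"):
            perims.append(supply_perimeter(g["distance_km"], g["delivered"]))
            cost_wood = float((g["price"] * g["delivered"]).sum())
            cost_tr = float((g["distance_km"] * rate * g["delivered"]).sum())
            if cost_wood + cost_tr > 0:
                tshares.append(cost_tr / (cost_wood + cost_tr) * 100.0)
            tot = g["delivered"].sum()
            by_type = g.groupby("seller_type")["delivered"].sum()
            for t in shares:
                shares[t].append(float(by_type.get(t, 0.0)) / tot * 100.0)
            gy = g.assign(year=g["month_due"] // 12)
            per = gy.groupby(["seller_type", "seller", "year"])[
                "delivered"].sum()
            for t in per_supplier:
                if t in per.index.get_level_values(0):
                    per_supplier[t].extend(per.loc[t].tolist())
    add("sawmill_supply_perimeter", perims)
    add("sawmill_transport_cost_share", tshares)
    for t in shares:
        add(f"sawmill_share_{t}", shares[t])
    for t in per_supplier:
        add(f"sawmill_delivery_per_{t}_supplier", per_supplier[t])

    energy_del = contracts[
        contracts["assortment"].str.startswith("energy")
        & (contracts["buyer_type"] == "energy")
        & contracts["buyer"].isin(inner_ids)] if len(contracts) else contracts
    eperims = [supply_perimeter(g["distance_km"], g["delivered"])
               for _, g in energy_del.groupby("buyer")] \
        if len(energy_del) else []
    add("energy_supply_perimeter", eperims)

    # -- relationship durations
    if len(sawlog_del):
        dur = relationship_durations(sawlog_del)
        add("sawmill_relationship_duration", list(dur))
        rows.append({"variable": "sawmill_longterm_share",
                     "mean": long_term_share(dur) * 100.0,
                     "q25": np.nan, "q75": np.nan})
    else:
        add("sawmill_relationship_duration", [])
        rows.append({"variable": "sawmill_longterm_share",
                     "mean": np.nan, "q25": np.nan, "q75": np.nan})

    # -- quarterly volume-weighted prices
    pr = result.prices
    pr = pr[pr["month"] >= settle] if len(pr) else pr
    qrows = []
    if len(pr):
        q = pr.assign(quarter=pr["month"] // 3)
        for a in ASSORTMENTS:
            vol = q.groupby("quarter")[f"volume_{a}"].sum()
            val = q.apply(lambda r: (r[f"price_{a}"] * r[f"volume_{a}"])
                          if np.isfinite(r[f"price_{a}"]) else 0.0, axis=1)
            valq = q.assign(val=val).groupby("quarter")["val"].sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_q = valq / vol
            for quarter, p in mean_q.items():
                qrows.append({"quarter": int(quarter), "assortment": a,
                              "price": float(p)})
    prices = pd.DataFrame(qrows)

    return RunSummary(stats=pd.DataFrame(rows), production=production,
                      prices=prices, settle_months=settle, n_months=n_months)


def average_summaries(summaries: list[RunSummary]) -> RunSummary:
    """Element-wise mean of per-run summaries (matching variables)."""
    if not summaries:
        raise EvaluationError("no summaries to average")
    import warnings

    base = summaries[0]
    stats = base.stats.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN variables
        for col in ("mean", "q25", "q75"):
            stats[col] = np.nanmean(
                np.column_stack([s.stats[col].to_numpy(dtype=float)
                                 for s in summaries]), axis=1)
    production = base.production.copy()
    production["annual_m3"] = np.mean(
        np.column_stack([s.production["annual_m3"].to_numpy()
                         for s in summaries]), axis=1)
    return RunSummary(stats=stats, production=production,
                      prices=base.prices, settle_months=base.settle_months,
                      n_months=base.n_months)


# ---------------------------------------------------------------------------
# reference comparison
# ---------------------------------------------------------------------------

def load_reference_tables() -> list[ReferenceTable]:
    """Packaged reference values (study-region statistics and surveys)."""
    src = importlib.resources.files("woodmarket.data") / "reference_tables.csv"
    with importlib.resources.as_file(src) as path:
        df = pd.read_csv(path, comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(ReferenceTable(
            variable=r["variable"], mean=float(r["mean"]),
            iqr_lo=float(r["iqr_lo"]) if np.isfinite(r["iqr_lo"]) else np.nan,
            iqr_hi=float(r["iqr_hi"]) if np.isfinite(r["iqr_hi"]) else np.nan,
            unit=str(r.get("unit", "")), priority=str(r["priority"])))
    return out


def compare_to_reference(summary: RunSummary,
                         refs: list[ReferenceTable],
                         rel_band: float = 0.25,
                         near_factor: float = 0.25) -> list[Rating]:
    """Three-level rating of simulated means against reference values.

    "+" if the simulated mean lies inside the closed reference IQR (or
    within ``rel_band`` of the mean when no IQR is given); "0" for a near
    miss, i.e. within the band extended by ``near_factor`` of its width
    beyond each bound (or within twice the relative band); "-" otherwise.
    Variables missing from the summary are listed as uncompared ("?").
    """
    out = []
    for ref in refs:
        if ref.priority == "omitted":
            continue
        sim = summary.value(ref.variable)
        if not np.isfinite(sim):
            out.append(Rating(ref.variable, sim, ref.mean, ref.iqr_lo,
                              ref.iqr_hi, "?"))
            continue
        has_iqr = np.isfinite(ref.iqr_lo) and np.isfinite(ref.iqr_hi)
        if has_iqr:
            lo, hi = ref.iqr_lo, ref.iqr_hi
            slack = near_factor * (hi - lo)
        else:
            lo = ref.mean - rel_band * abs(ref.mean)
            hi = ref.mean + rel_band * abs(ref.mean)
            slack = 0.5 * (hi - lo)      # doubles the relative band
        if lo <= sim <= hi:
            r = "+"
        elif (lo - slack) <= sim <= (hi + slack):
            r = "0"
        else:
            r = "-"
        out.append(Rating(ref.variable, sim, ref.mean, ref.iqr_lo,
                          ref.iqr_hi, r))
    return out


def ratings_report(ratings: list[Rating]) -> str:
    lines = [f"{'variable':40s} {'simulated':>12s} {'reference':>12s} "
             f"{'IQR':>17s} rating"]
    for r in ratings:
        iqr = (f"{r.iqr_lo:.6g}-{r.iqr_hi:.6g}"
               if np.isfinite(r.iqr_lo) else "-")
        sim = f"{r.simulated:.6g}" if np.isfinite(r.simulated) else "n/a"
        lines.append(f"{r.variable:40s} {sim:>12s} {r.reference:>12.6g} "
                     f"{iqr:>17s} {r.rating:>6s}")
    return "\n".join(lines)
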