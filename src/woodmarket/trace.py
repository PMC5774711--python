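"""Per-agent trace recording and offline querying.

Tracing selects a set of agents and records, for every simulation month, a
snapshot of their stocks and phonebooks, plus one record per negotiation the
agent took part in (message, both utilities, outcome and the per-criterion
utility terms behind each decision).  Traces are written as line-delimited
JSON — append-only, streamable and human-inspectable — and can be queried
offline to see which negotiations led to a contract and why.

Tracing is observation-only: it consumes no randomness and never mutates
simulation state, so enabling it does not change any output for a fixed
seed.
"""

from __future__ import annotations

import json
from typing import IO, Iterable, Optional


class TraceError(ValueError):
    pass


class TraceWriter:
    """Callable sink writing one JSON line per trace record."""

    def __init__(self, fh: IO[str]):
        self._fh = fh
        self.count = 0

    def __call__(self, record: dict) -> None:
        self._fh.write(json.dumps(record, sort_keys=True,
                                  default=_json_default) + "\n")
        self.count += 1


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class TraceCollector(list):
    """In-memory sink (a list of records) for tests and small runs."""

    def __call__(self, record: dict) -> None:
        self.append(record)


def record_snapshot(agent_rt, month: int) -> dict:
    """Build the per-month snapshot record for one traced agent.

    The snapshot contains the agent's current stock of all resources and
    its contacts with their trust values; the engine appends it to the
    trace stream after every simulated month.
    """
    stocks = {}
    for holder in (agent_rt.supplier, agent_rt.consumer, agent_rt.trader):
        if holder is not None:
            stocks.update({k: round(v, 6) for k, v in holder.stock.items()})
    if agent_rt.proc is not None:
        stocks.update({k: round(v, 6)
                       for k, v in agent_rt.proc.stock.items()})
        stocks.update({f"byproduct_{k}": round(v, 6)
                       for k, v in agent_rt.proc.byproduct_stock.items()})
    return {
        "kind": "snapshot", "month": month, "agent": agent_rt.id,
        "stock": stocks,
        "contacts": {str(k): round(e.trust, 6)
                     for k, e in agent_rt.phonebook.items()},
    }


def read_trace(path) -> list[dict]:
    """Read a line-delimited trace file; parse errors report the offset."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise TraceError(
                    f"corrupt trace stream at line {lineno}: {exc}") from exc
    return out


def query_trace(records_or_path, agent: Optional[int] = None,
                months: Optional[tuple[int, int]] = None,
                outcome: Optional[str] = None,
                kind: Optional[str] = None) -> list[dict]:
    """Filter trace records by agent, month range [a, b], outcome, kind."""
    records: Iterable[dict]
    if isinstance(records_or_path, (str, bytes)) or hasattr(records_or_path,
                                                            "__fspath__"):
        records = read_trace(records_or_path)
    else:
        records = records_or_path
    out = []
    for r in records:
        if agent is not None and agent not in (r.get("agent"),
                                               r.get("initiator"),
                                               r.get("responder")):
            continue
        if months is not None and not months[0] <= r["month"] <= months[1]:
            continue
        if outcome is not None and r.get("outcome") != outcome:
            continue
        if kind is not None and r.get("kind") != kind:
            continue
        out.append(r)
    return out


def explain(record: dict) -> str:
    """Human-readable account of one negotiation record.

    Shows the request, both total utilities against their thresholds, and
    the outcome — a declined negotiation shows the non-positive utility
    that caused it.
    """
    if record.get("kind") != "negotiation":
        return f"month {record['month']}: snapshot of agent {record['agent']}"
    req = record["request"]
    lines = [
        f"month {record['month']}: {record['initiator']} -> "
        f"{record['responder']} [{record['assortment']}] "
        f"{req['amount']:.0f} m3 @ {req['price']:.2f} due m{req['month_due']}",
    ]
    for side in ("responder", "initiator"):
        u = record.get(f"utility_{side}")
        if u is not None:
            verdict = "accept (U > 0)" if u > 0 else "decline (U <= 0)"
            lines.append(f"  {side} utility U = {u:.4f} -> {verdict}")
            terms = record.get(f"terms_{side}")
            if terms:
                parts = ", ".join(f"{k}: {v:+.3f}" for k, v in terms.items())
                lines.append(f"    terms: {parts}")
    lines.append(f"  outcome: {record['outcome']}"
                 + (f" ({record['reason']})"
                    if record.get("reason") and record["outcome"] != "concluded"
                    else ""))
    return "\n".join(lines)
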