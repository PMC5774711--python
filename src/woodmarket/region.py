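"""Synthetic two-zone region generation and agent placement.

The study region is emulated as a rectangular *inner zone* surrounded by a
belt-shaped *outer zone*.  The outer belt holds a mirror population of agents
whose only purpose is to buffer boundary effects: evaluation considers inner
agents only, but outer agents trade normally.  A configurable fraction of the
inner-region boundary is an *international* border; importer and exporter
agents are distributed along it and couple the region to exogenous
international prices.

Positions are in km.  Road distances are Euclidean distance times the
region's detour factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, PopulationSpec, RegionSpec, substream
from .markets import ASSORTMENTS

AGENT_TYPES = ("public", "private", "trader", "bundler", "sawmill",
               "industrial", "energy", "importer", "exporter")

SUPPLIER_TYPES = ("public", "private")
INTERMEDIARY_TYPES = ("trader", "bundler")
BORDER_TYPES = ("importer", "exporter")


@dataclass
class BorderSegment:
    start_arc: float
    end_arc: float
    international: bool
    midpoint: tuple[float, float]


@dataclass
class Region:
    spec: RegionSpec
    segments: list[BorderSegment]

    @property
    def inner_wh(self) -> tuple[float, float]:
        return self.spec.inner_width_km, self.spec.inner_height_km

    @property
    def perimeter(self) -> float:
        w, h = self.inner_wh
        return 2.0 * (w + h)

    def international_fraction(self) -> float:
        total = sum(s.end_arc - s.start_arc for s in self.segments)
        intl = sum(s.end_arc - s.start_arc for s in self.segments if s.international)
        return intl / total if total else 0.0

    def boundary_point(self, arc: float) -> tuple[float, float]:
        """Point on the inner boundary at arc length ``arc`` (ccw from (W,0))."""
        w, h = self.inner_wh
        arc = arc % self.perimeter
        if arc < h:                    # east side, going up
            return w, arc
        arc -= h
        if arc < w:                    # north side, going left
            return w - arc, h
        arc -= w
        if arc < h:                    # west side, going down
            return 0.0, h - arc
        arc -= h
        return arc, 0.0                # south side, going right

    def in_inner(self, x: float, y: float) -> bool:
        w, h = self.inner_wh
        return 0.0 <= x <= w and 0.0 <= y <= h

    def in_outer(self, x: float, y: float) -> bool:
        w, h = self.inner_wh
        b = self.spec.outer_belt_km
        inside_big = -b <= x <= w + b and -b <= y <= h + b
        return inside_big and not self.in_inner(x, y)

    def distance(self, a: "Agent", b: "Agent") -> float:
        """Road distance between two agents (Euclidean x detour factor)."""
        return math.hypot(a.x - b.x, a.y - b.y) * self.spec.detour_factor


@dataclass
class Agent:
    """A market participant with a fixed position and role parameters.

    Role-specific *dynamic* state (stocks, commitments, phonebook) is
    attached by the market engine; this class carries what the region
    generator assigns once per run.
    """

    id: int
    type: str
    zone: str                     # 'inner' | 'outer'
    x: float
    y: float
    # suppliers
    max_supply: float = 0.0       # m3/yr annual maximum supply
    soft_share: float = 0.0
    splits_soft: tuple[float, float, float] = (0.0, 0.0, 0.0)
    splits_hard: tuple[float, float, float] = (0.0, 0.0, 0.0)
    terrain: float = 1.0          # harvesting-cost factor (mountainousness)
    # processors
    capacity: float = 0.0         # m3/yr (sawmills: softwood sawlogs)
    hardwood_demand: float = 0.0  # m3/yr fixed hardwood sawlog side demand
    demand_soft: float = 0.0      # fixed buyers, m3/yr
    demand_hard: float = 0.0
    transport_factor: float = 1.0  # site advantage multiplier on transport cost
    affiliates: tuple[int, ...] = field(default_factory=tuple)  # bundlers

    def sells(self, a: str) -> bool:
        i = ASSORTMENTS.index(a) if a in ASSORTMENTS else -1
        if i < 0:
            return False
        if self.type in SUPPLIER_TYPES or self.type in INTERMEDIARY_TYPES:
            return True
        if self.type == "importer":
            return True
        if self.type == "sawmill":
            return a.startswith(("energy", "industrial"))  # byproducts
        return False

    def buys(self, a: str) -> bool:
        if self.type in INTERMEDIARY_TYPES or self.type == "exporter":
            return True
        if self.type == "sawmill":
            if a == "sawlogs_soft":
                return True
            return a == "sawlogs_hard" and self.hardwood_demand > 0
        if self.type == "industrial":
            return a.startswith("industrial")
        if self.type == "energy":
            return a.startswith("energy")
        return False


# ---------------------------------------------------------------------------
# region
# ---------------------------------------------------------------------------

def generate_region(spec: RegionSpec, seed: int) -> Region:
    """Build the two-zone region with labeled border segments.

    The inner boundary is split into ``n_border_segments`` equal arcs; the
    configured international fraction of them (rounded to whole segments, so
    the realised fraction matches within one segment) is labeled
    international, starting from the south-east corner.  Deterministic for a
    fixed seed.
    """
    spec.validate()
    n = spec.n_border_segments
    per = 2.0 * (spec.inner_width_km + spec.inner_height_km)
    seg_len = per / n
    n_intl = round(spec.international_border_fraction * n)
    region = Region(spec=spec, segments=[])
    for i in range(n):
        start, end = i * seg_len, (i + 1) * seg_len
        mid = Region(spec=spec, segments=[]).boundary_point((start + end) / 2.0)
        region.segments.append(BorderSegment(
            start_arc=start, end_arc=end, international=i < n_intl, midpoint=mid))
    return region


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_agents(region: Region, pop: PopulationSpec, seed: int) -> list[Agent]:
    """Place the configured agent population on the map.

    Public forest managers occupy a jittered grid in the inner zone
    (territorial coverage); each private-owner aggregate is co-located with
    one manager.  Importers and exporters are distributed along the
    international border segments (domestic-boundary fallback when the
    international fraction is zero).  All other agents are uniform within
    their zone.  Deterministic for a fixed seed.
    """
    pop.validate()
    rng = substream(seed, "placement")
    w, h = region.inner_wh
    belt = region.spec.outer_belt_km
    if w * h <= 0:
        raise ConfigError("inner zone has zero area")
    agents: list[Agent] = []
    next_id = 0

    def new(atype: str, zone: str, x: float, y: float, **kw) -> Agent:
        nonlocal next_id
        a = Agent(id=next_id, type=atype, zone=zone, x=float(x), y=float(y), **kw)
        next_id += 1
        agents.append(a)
        return a

    # -- public managers: jittered grid inner, uniform belt outer
    pub_inner = _jittered_grid(rng, pop.public.count_inner, w, h)
    publics_inner = [new("public", "inner", x, y) for x, y in pub_inner]
    publics_outer = [new("public", "outer", x, y)
                     for x, y in _uniform_belt(rng, pop.public.count_outer, w, h, belt)]

    # -- private owners: one aggregate in each manager's territory
    for i in range(pop.private.count_inner):
        anchor = publics_inner[i % len(publics_inner)] if publics_inner else None
        if anchor is not None:
            x = float(np.clip(anchor.x + rng.normal(0, 1.5), 0, w))
            y = float(np.clip(anchor.y + rng.normal(0, 1.5), 0, h))
        else:
            x, y = rng.uniform(0, w), rng.uniform(0, h)
        new("private", "inner", x, y)
    for i in range(pop.private.count_outer):
        anchor = publics_outer[i % len(publics_outer)] if publics_outer else None
        x = y = None
        if anchor is not None:
            for _ in range(20):
                cx = anchor.x + rng.normal(0, 1.5)
                cy = anchor.y + rng.normal(0, 1.5)
                if region.in_outer(cx, cy):
                    x, y = cx, cy
                    break
            else:
                x, y = anchor.x, anchor.y
        if x is None:
            x, y = _uniform_belt(rng, 1, w, h, belt)[0]
        new("private", "outer", x, y)

    # -- uniform types
    for atype in ("trader", "bundler", "sawmill", "industrial", "energy"):
        tspec = getattr(pop, atype)
        for x, y in _uniform_inner(rng, tspec.count_inner, w, h):
            new(atype, "inner", x, y)
        for x, y in _uniform_belt(rng, tspec.count_outer, w, h, belt):
            new(atype, "outer", x, y)

    # -- border agents along the international segments
    intl = [s for s in region.segments if s.international]
    segs = intl if intl else region.segments      # domestic fallback
    arcs = [s for s in segs]
    for atype in BORDER_TYPES:
        tspec = getattr(pop, atype)
        for zone, count in (("inner", tspec.count_inner), ("outer", tspec.count_outer)):
            for k in range(count):
                seg = arcs[k % len(arcs)]
                arc = seg.start_arc + (seg.end_arc - seg.start_arc) * rng.uniform(0.1, 0.9)
                x, y = region.boundary_point(arc)
                if zone == "outer":
                    # push onto the outer edge of the belt, radially outward
                    cx, cy = w / 2.0, h / 2.0
                    vx, vy = x - cx, y - cy
                    norm = math.hypot(vx, vy) or 1.0
                    x, y = x + vx / norm * belt * 0.95, y + vy / norm * belt * 0.95
                new(atype, zone, x, y)

    # -- bundler affiliations (suppliers within radius)
    radius = pop.bundler.affiliation_radius_km
    suppliers = [a for a in agents if a.type in SUPPLIER_TYPES]
    for b in agents:
        if b.type != "bundler":
            continue
        b.affiliates = tuple(
            s.id for s in suppliers
            if math.hypot(s.x - b.x, s.y - b.y) <= radius)

    # -- zone sanity
    for a in agents:
        if a.zone == "inner" and not region.in_inner(a.x, a.y):
            raise ConfigError(f"agent {a.id} placed outside inner zone")
        if a.zone == "outer" and region.in_inner(a.x, a.y):
            raise ConfigError(f"agent {a.id} placed inside inner zone")
    return agents


def _jittered_grid(rng, n: int, w: float, h: float) -> list[tuple[float, float]]:
    if n == 0:
        return []
    nc = max(1, round(math.sqrt(n * w / h)))
    nr = math.ceil(n / nc)
    cw, ch = w / nc, h / nr
    pts = []
    for i in range(n):
        r, c = divmod(i, nc)
        x = (c + 0.5) * cw + rng.uniform(-0.3, 0.3) * cw
        y = (r + 0.5) * ch + rng.uniform(-0.3, 0.3) * ch
        pts.append((float(np.clip(x, 0, w)), float(np.clip(y, 0, h))))
    return pts


def _uniform_inner(rng, n: int, w: float, h: float) -> list[tuple[float, float]]:
    return [(rng.uniform(0, w), rng.uniform(0, h)) for _ in range(n)]


def _uniform_belt(rng, n: int, w: float, h: float, b: float) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    while len(pts) < n:
        x = rng.uniform(-b, w + b)
        y = rng.uniform(-b, h + b)
        if not (0.0 <= x <= w and 0.0 <= y <= h):
            pts.append((x, y))
    return pts


# ---------------------------------------------------------------------------
# supply / demand profiles
# ---------------------------------------------------------------------------

def draw_supply_profiles(agents: list[Agent], pop: PopulationSpec, seed: int) -> list[Agent]:
    """Draw annual supply maxima, capacities and demand parameters in place.

    Supplier maxima and sawmill capacities follow a truncated lognormal
    (right-skewed, as real forest-district sizes and mill sizes are) whose
    parameters are solved so the *truncated* mean equals the configured
    population mean.  Returns the same list for chaining.
    """
    pop.validate()
    rng = substream(seed, "profiles")
    beh_terrain = (0.8, 1.3)
    for atype in SUPPLIER_TYPES:
        tspec = getattr(pop, atype)
        group = [a for a in agents if a.type == atype]
        if not group:
            continue
        draws = truncated_lognormal(rng, len(group), tspec.mean_supply,
                                    tspec.cv_supply, tspec.min_supply,
                                    tspec.max_supply)
        for a, v in zip(group, draws):
            a.max_supply = float(v)
            a.soft_share = tspec.soft_share
            a.splits_soft = tuple(tspec.splits_soft)
            a.splits_hard = tuple(tspec.splits_hard)
            a.terrain = float(rng.uniform(*beh_terrain))

    mills = [a for a in agents if a.type == "sawmill"]
    if mills:
        sm = pop.sawmill
        caps = truncated_lognormal(rng, len(mills), sm.mean_capacity,
                                   sm.cv_capacity, sm.min_capacity,
                                   sm.max_capacity)
        for a, v in zip(mills, caps):
            a.capacity = float(v)
        for zone in ("inner", "outer"):
            zmills = [a for a in mills if a.zone == zone]
            k = min(sm.hardwood_mills, len(zmills))
            if k:
                idx = rng.choice(len(zmills), size=k, replace=False)
                for i in sorted(int(j) for j in idx):
                    zmills[i].hardwood_demand = sm.hardwood_demand

    for atype in ("industrial", "energy"):
        tspec = getattr(pop, atype)
        for a in agents:
            if a.type == atype:
                a.demand_soft = tspec.demand_soft
                a.demand_hard = tspec.demand_hard
    return agents


# ---------------------------------------------------------------------------
# truncated lognormal with a target truncated mean
# ---------------------------------------------------------------------------

def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Analytic mean of a lognormal(mu, sigma) truncated to [lo, hi]."""
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    denom = _phi(b) - _phi(a)
    if denom <= 0.0:
        return float("nan")
    return math.exp(mu + sigma ** 2 / 2.0) * (_phi(b - sigma) - _phi(a - sigma)) / denom


def solve_truncated_lognormal_mu(target_mean: float, sigma: float,
                                 lo: float, hi: float) -> float:
    """Solve for mu such that the truncated mean equals ``target_mean``."""
    if not lo < target_mean < hi:
        raise ConfigError("target mean must lie strictly inside [lo, hi]")
    mu_lo, mu_hi = math.log(lo) - 5 * sigma, math.log(hi) + 5 * sigma
    for _ in range(200):
        mid = 0.5 * (mu_lo + mu_hi)
        if truncated_lognormal_mean(mid, sigma, lo, hi) < target_mean:
            mu_lo = mid
        else:
            mu_hi = mid
    return 0.5 * (mu_lo + mu_hi)


def truncated_lognormal(rng: np.random.Generator, n: int, mean: float,
                        cv: float, lo: float, hi: float) -> np.ndarray:
    """Draw ``n`` values; the population (truncated) mean equals ``mean``.

    ``cv`` parameterises the spread of the underlying lognormal
    (sigma^2 = ln(1 + cv^2)); cv = 0 degenerates to the constant ``mean``.
    Rejection sampling keeps the draw reproducible under the generator.
    """
    if cv == 0.0:
        return np.full(n, mean)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    mu = solve_truncated_lognormal_mu(mean, sigma, lo, hi)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(16, 2 * (n - filled)))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def agents_to_frame(agents: list[Agent]):
    """Agent table (id, type, zone, position, parameters) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame([{
        "id": a.id, "type": a.type, "zone": a.zone,
        "x_km": round(a.x, 6), "y_km": round(a.y, 6),
        "max_supply": a.max_supply, "capacity": a.capacity,
        "soft_share": a.soft_share, "terrain": a.terrain,
        "demand_soft": a.demand_soft, "demand_hard": a.demand_hard,
        "hardwood_demand": a.hardwood_demand,
    } for a in agents])


def agents_to_geojson(agents: list[Agent]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [a.x, a.y]},
            "properties": {"id": a.id, "type": a.type, "zone": a.zone},
        } for a in agents],
    }
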