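# Model and methods

`woodmarket` simulates a regional wood market as a population of
individually parameterised agents who trade through bilateral contract
negotiations.  This note documents the model, its assumptions, the shipped
reference calibration, and the choices made where the design was genuinely
open.

## Entities and scales

Six overlapping markets are simulated — sawlogs (the main product),
industrial wood and energy wood, each for softwood and hardwood.  One time
step is a month; a reference run covers 20 years starting in January 2001.
Nine agent types participate:

| type | inner + outer | key parameters |
|---|---|---|
| public forest managers | 85 + 85 | max supply ~3500 m³/yr, 97 % softwood; softwood split 81/13/6 % (sawlogs/energy/industrial), hardwood 2/95/3 % |
| private forest owners (aggregated) | 85 + 85 | max supply ~100 m³/yr, 60 % softwood; own consumption 10/60/5 % |
| traders | 12 + 12 | buy and resell at a margin |
| bundling organisations | 8 + 15 | as traders, but only from affiliated suppliers (≤ 25 km) |
| sawmills | 25 + 25 | capacity 800–8000 m³/yr, mean 2300; three per zone also process 180 m³/yr hardwood; two months of stock |
| industrial wood buyers | 1 + 2 | fixed demand 4800 m³ softwood + 1200 m³ hardwood |
| energy wood buyers (aggregated) | 50 + 50 | fixed demand 900 + 225 m³, heating period Oct–Apr, one month of stock |
| importers / exporters | 6 + 6 each | trade at international parity prices; annual volume increase capped |

The region is synthetic: a 90 × 60 km rectangular inner zone (the evaluated
study region) inside a 30 km outer belt whose mirror population only buffers
boundary effects.  Two thirds of the inner boundary is an international
border along which the importer and exporter agents sit.  The spatial extent
and belt width are assumptions (no printed values exist); they were chosen
so that typical mill–forest distances fall in the tens of kilometres.  Road
distances are Euclidean distances times a detour factor of 1.4 — a standard
road-detour ratio for mountainous terrain; real road-network routing is out
of scope.

Supplier maxima and mill capacities follow truncated lognormal
distributions whose parameters are solved so the *truncated* mean equals the
printed population mean (right-skewed, as real forest-district and mill
sizes are).  Public managers sit on a jittered grid (territorial coverage);
each private-owner aggregate is co-located with one manager.

## Scheduling

Each month the six markets execute one round each in a fixed order (sawlogs
before the byproduct markets, softwood before hardwood, because byproducts
of sawlog processing feed the side markets).  A round shuffles the
participants (seeded) and performs five steps: (1) everyone may initiate new
contracts, (2) suppliers harvest to order, (3) sellers deliver,
(4) intermediaries deliver, (5) buyers process.  After all six rounds, the
evaluators record the month.

## Negotiation and decisions

Contracts are concluded through a three-message protocol: request →
(accept / adapt price and/or amount / decline) → final accept or decline by
the initiator, with no further modification.  Agents never compare
simultaneous offers.  Every accept/decline evaluates the linear
random-utility function `U = Σ βᵢ·cᵢ + ε − β₀` with strict acceptance at
`U > 0`; the random component ε is off by default.  Criterion values are
normalised to documented scales (see the decision module); each agent's
part-worths and threshold carry multiplicative lognormal heterogeneity
(CV 0.08) mimicking individual-level preference estimates.  The shipped
part-worth tables are calibration parameters of the artifact, not empirical
claims.

Responders adapt by countering at their reservation price (the closed-form
`U = 0` price, plus a 5 % markup of the gap), declining instead beyond a
counter ratio of 1.6.  Buying processors and consumers additionally hold a
*personal reference price* — an EMA (weight 0.01/month) of their own past
purchase prices — and tolerate prices above it only in proportion to their
urgency (`anchor × (1 + 0.4·urgency³)`): insufficient utilisation raises
the willingness to pay.  Buyers open 10 % below the prevailing price and
let counters discover the price.

## Trust and phonebooks

Every agent holds a phonebook of contacts with trust values in [0, 1]
(initially 0.5 for the ten nearest counterparties per role, 0.2 for
partners first met during the run).  Trust rises by 0.02 after a concluded
contract and falls by 0.02 after a declined decision; a contact who simply
had nothing available is not penalised.  Failed deliveries cost the seller
trust.  Contacts are sampled without replacement with probability
proportional to `trust + 0.05` (the floor keeps new contacts discoverable).
Suppliers scale the amount they will commit to one buyer with their trust in
that buyer (an unknown customer starts at 15 % of the monthly plan and must
prove reliability), and treat buyers above trust 0.7 as regulars.

Suppliers' trust in exporters starts at 0.9: the region produces far more
sawlogs than its mills process, so export relationships are long-established
— this reproduces the observed imbalance between regional production and
regional processing capacity.

## Supply planning, reservations, processing, border trade

Suppliers plan an annual cut each January: 90 % of their maximum at
reference prices, responding log-linearly to the supply-weighted absolute
price level (elasticity 0.3 public / 0.6 private, capped at the maximum),
with assortment shares shifted by relative prices (shift elasticity 0.5
public / 1.0 private — private owners have the wider scope) and renormalised.
The marketable plan removes private own-consumption and is spread equably
over the harvesting season (September–March), with 30 % catch-up headroom
per month.  Marginal harvesting cost rises linearly with the cumulative
annual cut (48 currency/m³ base, +60 % at the full cut), scaled by a
per-supplier terrain factor (0.8–1.3) and a per-product multiplier.

A configured fraction of the plan (42 % sawlogs, 55 % energy, 25 %
industrial) is reserved for regular customers until October; reservations
are not absolute — a price 10 % above the prevailing level unlocks most of
the reserved allocation for non-regulars ("parts of the reserved amounts
are usually sold" at a good price).

Sawmills process `capacity/12` per month from stock (at most two months of
demand), producing byproducts (20 % energy, 15 % industrial wood per m³
processed — typical residual shares; not printed anywhere) which they sell
on the side markets once their byproduct store fills.  Energy buyers
concentrate demand in the heating period and convert first successful
supplier relationships into multi-year framework contracts (5–15 years,
re-executed monthly).  Importers and exporters trade at the international
price series times the exchange rate (import spread +25 %, export at
parity) with annual volume-increase caps; buyers treat imports as the
marginal source, approached after domestic candidates.

## Exogenous prices

International price series are synthetic: a level per assortment (90/85
sawlogs, 55/50 industrial, 60/60 energy, in generic currency units per m³)
with AR(1) multiplicative noise and optional step shocks.  The bulk-
purchaser scenario adds the historical price environment: +10 % from
mid-2006 and −8 % from mid-2009.  Energy wood is tradable in loose cubic
metres at 2.5 lcm per solid m³ (an assumption; internally everything is in
solid m³).

## The bulk-purchaser case study

A sawmill with 800 000 m³/yr capacity — far beyond every incumbent — enters
with sawlog deliveries from October 2006 (month 69) and starts processing in
January 2007, sited with rail/highway access (transport cost factor 0.7).
As a specific firm it uses the exact configured part-worths (no population
draw) and a higher willingness to pay (buying threshold −0.35).  The
reference calibration reproduces, averaged over seeds 1–20: a 2010
processing-capacity utilisation around 44 %, a mean price premium over
competing mills around 9 %, monotone growth of supplied volume as trust is
built, entry-year surplus flowing predominantly to exports, and a
considerable import increase when sawlog reservations are set to 100 %.
The reduced-willingness variant (threshold +0.1) makes the entrant pay
prices close to its competitors'; its supplied volume then collapses to
roughly 100 000 m³/yr.  The realized premium does not vanish entirely in
that variant — paying above the prevailing price is the only way a
non-regular obtains reserved wood at all — but it falls to roughly half the
reference level.  Insolvency is not modelled endogenously; the scenario
reports utilisation and prices over the full window.

## Evaluation

Evaluators consider inner-zone agents only and exclude the first 36 months
(settle-in: the relationship network needs 2–3 years to form).  The run
summary reports annual production by ownership and assortment, processed
amounts, quarterly volume-weighted prices, and survey-comparable micro
statistics (requests in/out per agent-year, rejection rates, supply
perimeters, transport-cost shares, supplier-type shares, relationship
durations, stock utilisation) as means and IQRs over agents.  The supply
perimeter is the smallest delivery radius containing strictly more than
90 % of a processor's sourced volume.  A relationship's duration is its
longest streak of consecutive years with at least one contract; "regular
customer" means trust above 0.7.  Ratings against the packaged reference
tables are "+" inside the closed reference IQR, "0" within the IQR extended
by 25 % of its width per side (doubled band for mean-only references), "−"
otherwise.

## Determinism and numerics

A run is a pure function of (configuration, seed, events).  All randomness
flows through named substreams (region, placement, profiles, shuffle,
decisions, prices) of the root seed, so paired-seed scenario comparisons
stay stable when one component changes.  Wood conservation is audited
monthly per agent (`Δstock = produced + received − delivered − consumed`)
and the maximum residual is reported with every run (≤ 1e−6 m³ over a full
reference run; observed ~1e−13).  Requests below 5 m³ are not negotiated.
Tracing is observation-only and never alters outputs.

## Problem sizes used by the tests

Unit and property tests run a scaled-down population (≈ 60 agents) over 1–3
years.  The conservation/protocol suite runs the full reference population
over the complete 240-month horizon once.  The case-study suite uses 20
seeds for the reference scenario and 5 paired seeds for the
reduced-willingness and reservation-sweep counterfactuals; the experiment
driver is documented as equivalent in expectation to the 100-run protocol.

## Known limitations

The synthetic region reproduces the *structure* of the study region
(two-zone layout, border shares, quantity structure), not its geography;
absolute production levels are therefore comparable only in order of
magnitude with printed regional statistics.  Part-worths are shipped
calibration values, not survey estimates.  Price formation is bilateral
with EMA price indices — no order book exists, and local price dispersion
is limited by the single prevailing index per assortment.  Hardwood sawlog
processing is a fixed side demand.  Forest growth, assortment quality
grades and downstream product markets are out of scope.
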