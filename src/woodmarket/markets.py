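"""Assortment and market identities.

Six overlapping markets are simulated: three products (sawlogs, the main
product; industrial wood for pulp/paper; energy wood for heating), each in a
softwood and a hardwood variant.  Market rounds are executed in a fixed order
each month: sawlogs first (byproducts of sawlog processing feed the side
markets), then industrial wood, then energy wood, softwood before hardwood.
"""

from __future__ import annotations

PRODUCTS = ("sawlogs", "industrial", "energy")
SPECIES = ("soft", "hard")

#: Fixed monthly execution order of the six markets.
ASSORTMENTS = (
    "sawlogs_soft",
    "sawlogs_hard",
    "industrial_soft",
    "industrial_hard",
    "energy_soft",
    "energy_hard",
)

A_INDEX = {a: i for i, a in enumerate(ASSORTMENTS)}


def product_of(assortment: str) -> str:
    return assortment.rsplit("_", 1)[0]


def species_of(assortment: str) -> str:
    return assortment.rsplit("_", 1)[1]


def assortment(product: str, species: str) -> str:
    if product not in PRODUCTS or species not in SPECIES:
        raise ValueError(f"unknown product/species: {product}/{species}")
    return f"{product}_{species}"
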