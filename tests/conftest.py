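"""Shared fixtures: scaled-down configurations for fast engine tests."""

import pytest

from woodmarket.config import FullConfig, reference_config


def small_population(cfg: FullConfig) -> FullConfig:
    """Shrink the agent population for sub-second engine runs."""
    pop = cfg.population
    pop.public.count_inner = pop.public.count_outer = 6
    pop.private.count_inner = pop.private.count_outer = 6
    pop.trader.count_inner = pop.trader.count_outer = 2
    pop.bundler.count_inner, pop.bundler.count_outer = 1, 2
    pop.sawmill.count_inner = pop.sawmill.count_outer = 3
    pop.sawmill.hardwood_mills = 1
    pop.industrial.count_inner = pop.industrial.count_outer = 1
    pop.energy.count_inner = pop.energy.count_outer = 4
    pop.importer.count_inner = pop.importer.count_outer = 2
    pop.exporter.count_inner = pop.exporter.count_outer = 2
    return cfg


@pytest.fixture
def small_config() -> FullConfig:
    cfg = small_population(reference_config())
    cfg.simulation.years = 3
    cfg.simulation.settle_months = 12
    return cfg.validate()


@pytest.fixture
def reference() -> FullConfig:
    return reference_config()
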