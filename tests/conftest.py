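"""Shared fixtures: synthetic registries at the default study conditions
and an illustrative other-MOF:hip ratio table.

The heavyweight registry fixtures are session-scoped so the simulation
cost is paid once per run.
"""

from __future__ import annotations

import pandas as pd
import pytest

import fraxkit as fx
from fraxkit.bands import AGE_BANDS


@pytest.fixture(scope="session")
def default_config() -> fx.SyntheticConfig:
    return fx.SyntheticConfig(seed=20171)


@pytest.fixture(scope="session")
def registry(default_config):
    """Population, line list, cases and life table at the default study
    conditions (three years, two nationality strata)."""
    cfg = default_config
    pop = fx.generate_population(cfg)
    records = fx.generate_line_list(cfg, pop)
    cases = fx.select_index_admissions(records, study_years=cfg.years)
    life = fx.generate_life_table(cfg)
    return {"config": cfg, "population": pop, "records": records,
            "cases": cases, "life": life}


@pytest.fixture(scope="session")
def big_config() -> fx.SyntheticConfig:
    """Scaled-up registry (>3 million national person-years) for
    parameter-recovery checks; duplicates and decoys off so counts map
    directly to the configured hazards."""
    base = fx.SyntheticConfig()
    pop = {
        nat: {b: 20 * v for b, v in bands.items()}
        for nat, bands in base.pop_size.items()
    }
    return fx.SyntheticConfig(seed=90210, pop_size=pop, dup_prob=0.0,
                              decoy_fraction=0.0)


@pytest.fixture(scope="session")
def big_registry(big_config):
    cfg = big_config
    pop = fx.generate_population(cfg)
    records = fx.generate_line_list(cfg, pop)
    cases = fx.select_index_admissions(records, study_years=cfg.years)
    return {"config": cfg, "population": pop, "records": records, "cases": cases}


@pytest.fixture(scope="session")
def ratio_table() -> pd.DataFrame:
    """Synthetic illustrative other-MOF:hip ratio table (Malmö-style
    shape: ratios fall with age, higher in women). Not the Swedish
    values — those are user inputs in real use."""
    women = [6.0, 5.5, 5.0, 4.5, 3.8, 3.0, 2.4, 1.9, 1.5]
    men = [4.0, 3.5, 3.0, 2.5, 2.0, 1.6, 1.2, 1.0, 0.8]
    rows = []
    for sex, vals in (("female", women), ("male", men)):
        rows += [{"sex": sex, "age_band": b, "ratio": r}
                 for b, r in zip(AGE_BANDS, vals)]
    return pd.DataFrame(rows)
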