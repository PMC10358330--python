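import numpy as np
import pandas as pd
import pytest

from hhdiet.afe import EnergyRequirementTable, convert_population
from hhdiet.simulate import (
    GeneratorConfig,
    generate_population,
    generate_reference_tables,
    make_worked_example,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def ereq():
    return EnergyRequirementTable.default()


@pytest.fixture(scope="session")
def small_survey(ereq):
    """A small simulated survey (n=400) shared across modules."""
    cfg = GeneratorConfig(n_households=400, seed=11)
    fct, groupmap, footprint = generate_reference_tables(cfg)
    households, consumption, truth = generate_population(cfg)
    per_afe, items = convert_population(households, consumption, fct, groupmap, ereq)
    return {
        "config": cfg,
        "fct": fct,
        "groupmap": groupmap,
        "footprint": footprint,
        "households": households,
        "consumption": consumption,
        "truth": truth,
        "per_afe": per_afe,
        "items": items,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_quintiles(rng):
    """n=500 households with balanced quintile labels and a scores frame."""
    n = 500
    scores = pd.DataFrame(
        {"PC1": rng.normal(size=n)}, index=[f"H{i:04d}" for i in range(n)]
    )
    return scores
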