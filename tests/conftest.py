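import numpy as np
import pandas as pd
import pytest

from survrake import MarginSet
from survrake.synthetic import (
    default_incidence_spec,
    default_population_spec,
    default_selection_spec,
    generate_population,
    draw_sample,
    simulate_followup,
)


@pytest.fixture(scope="session")
def population_bundle():
    """A moderate synthetic population with follow-up, shared across tests.

    Returns (population_with_followup, truth_margins, incidence_spec).
    """
    spec = default_population_spec(population_size=60_000)
    pop = generate_population(spec, seed=101)
    inc = default_incidence_spec()
    pop_fu = simulate_followup(pop, inc, seed=102)
    margins = MarginSet.from_sample(
        pop, list(spec.characteristics), population_name="truth"
    )
    return pop_fu, margins, inc


@pytest.fixture(scope="session")
def biased_sample(population_bundle):
    pop_fu, _, _ = population_bundle
    return draw_sample(pop_fu, default_selection_spec(seed=103))


@pytest.fixture()
def toy_sample():
    """A 12-unit two-characteristic sample for hand-checkable weighting."""
    return pd.DataFrame(
        {
            "sex": ["Male"] * 5 + ["Female"] * 7,
            "area": ["City", "City", "Rural", "Rural", "City",
                     "City", "Rural", "City", "City", "Rural", "City", "Rural"],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
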