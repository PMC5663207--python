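import pandas as pd
import pytest
from hypothesis import settings

from polyrx import synthetic, vocab

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_map():
    return vocab.demo_mapping()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, small enough for exhaustive checks."""
    return synthetic.simulate_cohort(synthetic.default_config(300, seed=7))


@pytest.fixture(scope="session")
def small_ingredient_claims(small_cohort, demo_map):
    claims, n_dropped = vocab.expand_to_ingredients(small_cohort.claims, demo_map)
    assert n_dropped == 0
    return claims


def make_claims(rows):
    """Claims table from (patient, code, fill_age, days_supply, payment) tuples."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "drug_code", "fill_age_days", "days_supply", "payment"],
    )


def make_exposures(rows):
    """Exposure table from (patient, window, ingredient) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "window_index", "ingredient"])
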