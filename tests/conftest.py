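import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cariesmap as cm

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_region():
    """A 20-parish region with a structured risk surface, ~200 children each."""
    cfg = cm.SimConfig(seed=42, n_parishes=20, grid_cols=5, mean_children_per_parish=200)
    return cm.simulate_region(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_region):
    return cm.simulate_cohort(small_region, 2010)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Sampler settings for unit tests (still >=100 retained draws/chain)."""
    return dict(n_chains=2, n_iterations=1500, n_burnin=750, seed=11)


@pytest.fixture(scope="session")
def fitted_small(small_region, small_cohort):
    counts = cm.expected_counts(cm.filter_cohort(small_cohort, birth_class="domestic"))
    mapper = cm.BYMMapper(n_chains=2, n_iterations=3000, n_burnin=1500, seed=9)
    mapper.fit(counts, small_region.graph)
    return counts, mapper


def make_children(n, *, cases=0, year=2010, parish="P01", birth_class="domestic", age=4):
    """Deterministic child table with an exact number of cases."""
    rows = []
    for i in range(n):
        rows.append(
            {
                "child_id": f"c{i:05d}",
                "exam_year": year,
                "age": age,
                "sex": "M" if i % 2 == 0 else "F",
                "parish_id": parish,
                "birth_class": birth_class,
                "dmfs": 3 if i < cases else 0,
            }
        )
    return cm.cohort.records_from_rows(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
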