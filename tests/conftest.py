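import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import recurseq as rq

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared by read-only tests."""
    return rq.generate_cohort(rq.SimConfig(seed=11))


@pytest.fixture(scope="session")
def normalized(default_bundle):
    return rq.ExpressionMatrix(default_bundle.counts).normalize()


@pytest.fixture(scope="session")
def cohort_calls(default_bundle, normalized):
    deltas, zeros = rq.pair_deltas(
        normalized.lognorm, default_bundle.case_table, default_bundle.counts
    )
    calls, fences = rq.classify_cohort(deltas, zeros)
    return calls, fences


def random_nb_tables(seed=20240601, n_tables=20):
    """Random negative-binomial count tables (shared with the TMM oracle fixture)."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        n_genes = int(rng.integers(200, 800))
        n_samples = int(rng.integers(3, 7))
        base = rng.lognormal(3.0, 1.5, size=n_genes)
        lib = rng.uniform(0.5, 2.0, size=n_samples)
        mu = base[:, None] * lib[None, :]
        disp = 0.15
        lam = rng.gamma(1.0 / disp, mu * disp)
        counts = rng.poisson(lam)
        tables.append(pd.DataFrame(counts, columns=[f"S{j}" for j in range(n_samples)]))
    return tables
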