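import logging

import pandas as pd
import pytest

from lncreg.preprocess import cpm_filter, normalize_log_standardize, \
    residualize_covariates, tmm_factors
from lncreg.synthdata import SimulationConfig, simulate_bundle

logging.getLogger("lncreg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated cohort shared by read-only tests."""
    return simulate_bundle(SimulationConfig(n_samples=120, seed=7))


@pytest.fixture(scope="session")
def small_expr(small_bundle):
    counts = small_bundle["counts"]
    filtered = cpm_filter(counts, 1.0, min_samples=int(0.41 * counts.shape[1]))
    expr = normalize_log_standardize(filtered, tmm_factors(filtered))
    return residualize_covariates(expr, small_bundle["covariates"])


def preprocess_counts(counts: pd.DataFrame, covariates: pd.DataFrame):
    """Convenience used by several test modules."""
    filtered = cpm_filter(counts, 1.0, min_samples=int(0.41 * counts.shape[1]))
    expr = normalize_log_standardize(filtered, tmm_factors(filtered))
    return residualize_covariates(expr, covariates)
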