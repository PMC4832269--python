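"""Shared fixtures.

The expensive pieces — one synthetic cohort of 20,000 complete cases and
the Model A / Model B fits to it — are session-scoped and shared between
the pipeline and recovery tests.
"""

import numpy as np
import pandas as pd
import pytest

from ldsem import (
    GeneratorConfig,
    build_model_a,
    build_model_b,
    fit_model,
    residualize,
    simulate_cohort,
)

#: cohort-scale seed for the shared recovery runs (birth year of the
#: emulated cohort; fixed once, never per-test)
RECOVERY_SEED = 1936


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort20k(config):
    """Residualized complete-case cohort of 20,000 subjects."""
    df = simulate_cohort(config, n=20000, seed=RECOVERY_SEED)
    return residualize(df)


@pytest.fixture(scope="session")
def fit_a20k(cohort20k):
    from ldsem.schema import model_variables
    cols, _ = model_variables("A")
    fit = fit_model(build_model_a(), cohort20k.loc[:, list(cols)],
                    starts=2, seed=1, compute_se=True)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def fit_b20k(cohort20k):
    from ldsem.schema import model_variables
    cols, _ = model_variables("B")
    fit = fit_model(build_model_b(), cohort20k.loc[:, list(cols)],
                    starts=2, seed=1, compute_se=True)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_cohort(config):
    """A modest cohort for pipeline plumbing tests."""
    from ldsem import flag_exclusions
    df = simulate_cohort(config, n=2500, seed=11)
    return flag_exclusions(df, config, seed=11)
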