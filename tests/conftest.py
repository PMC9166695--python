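import numpy as np
import pandas as pd
import pytest

import neuropls as npl


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized cohort with a planted rank-1 association."""
    return npl.generate_cohort(npl.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted association (singular strength 0)."""
    return npl.generate_cohort(npl.CohortConfig(seed=7, singular_strength=(0.0,)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def continuous_outcomes(cohort) -> pd.DataFrame:
    """The cohort's planted percent-change outcomes as an outcome table."""
    return pd.DataFrame(
        cohort.truth["planted_pct_change"],
        index=cohort.covariates.index,
        columns=cohort.clinical_baseline.columns,
    )
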