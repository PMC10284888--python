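import warnings

import numpy as np
import pandas as pd
import pytest

from bulkdecon import deconv, synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """One small but complete synthetic cohort shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = syn.simulate_cohort(
            design=syn.CohortDesign(n_healthy=8, n_mtx=10, n_tnfi=8, seed=11),
            n_genes=600,
            n_cell_types=10,
            markers_per_type=8,
            seed=11,
        )
    return sim


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return deconv.deconvolve(small_cohort.counts, small_cohort.reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_reference():
    """3-type reference with printed values for exhaustive marker checks."""
    return pd.DataFrame(
        {
            "A": [40.0, 2.0, 1.0, 5.0, 8.0, 0.0],
            "B": [5.0, 30.0, 1.0, 5.0, 2.0, 0.0],
            "C": [5.0, 2.0, 12.0, 5.0, 2.0, 9.0],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
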