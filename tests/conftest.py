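import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import plasmaqc as pq

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dilution_sim():
    """Default-condition platelet dilution series (2000 proteins, 200 planted)."""
    return pq.simulate_contamination_series(seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast dilution series for structural tests."""
    return pq.simulate_contamination_series(
        n_plasma_proteins=300, n_planted=60, noise_cv=0.1, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise- and censoring-free series: exact mixture arithmetic holds."""
    return pq.simulate_contamination_series(
        n_plasma_proteins=300, n_planted=60, noise_cv=0.0, lod_quantile=0.0, seed=7
    )


@pytest.fixture(scope="session")
def paired_sim():
    """Default paired plasma/serum design (10 donors, 40 planted, fold 8)."""
    return pq.simulate_paired_plasma_serum(seed=5)


@pytest.fixture
def tiny_matrix():
    """3 proteins x 3 samples with one missing cell."""
    values = pd.DataFrame(
        {
            "S1": [200.0, 300.0, 500.0],
            "S2": [10.0, np.nan, 40.0],
            "S3": [1.0, 2.0, 3.0],
        },
        index=["M1", "M2", "OTHER"],
    )
    return pq.ProteinMatrix(values, pd.Series(["PF4", "ITGB1", "ALB"], index=values.index))
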