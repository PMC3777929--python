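import numpy as np
import pandas as pd
import pytest

import cranesig as cs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_binarized():
    """4 genes x 8 samples with a hand-built state structure."""
    states = pd.DataFrame(
        {
            "s1": [1, 1, 0, 0],
            "s2": [1, 1, 0, 0],
            "s3": [0, 0, 1, 1],
            "s4": [0, 0, 1, 1],
            "s5": [1, 0, 1, 0],
            "s6": [0, 1, 0, 1],
            "s7": [0, 0, 0, 0],
            "s8": [1, 1, 1, 1],
        },
        index=["A", "B", "C", "D"],
        dtype=bool,
    )
    return cs.BinarizedMatrix(states)


@pytest.fixture
def tiny_labels():
    labels = pd.Series(
        ["LTS", "LTS", "STS", "STS", "LTS", "STS", "LTS", "STS"],
        index=[f"s{i}" for i in range(1, 9)],
    )
    return cs.PhenotypeLabels(labels, cutoff_low_days=225, cutoff_high_days=635)


@pytest.fixture
def clinical_8():
    """8 deceased patients, survival 1..8 days."""
    return cs.ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(1, 9)],
                "survival_days": list(range(1, 9)),
                "vital_status": "dead",
                "pretreated": False,
                "prior_glioma": False,
            }
        )
    )


@pytest.fixture(scope="session")
def cohort_sim():
    """A small planted cohort shared across tests (expensive to build)."""
    cfg = cs.CohortSimConfig(
        n_genes=300,
        n_sts=50,
        n_lts=50,
        n_middle=100,
        planted=[cs.two_state_design(8, 0.44, 0.0) for _ in range(3)],
        seed=7,
    )
    return cs.simulate_cohort(cfg)
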