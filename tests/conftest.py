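import numpy as np
import pandas as pd
import pytest

from qrs.features import build_presence_matrix
from qrs.synthetic import CohortSpec, simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects=800, n_relevant=20, n_noise=60, seed=11)


@pytest.fixture(scope="session")
def cohort(small_spec):
    """One simulated cohort shared across read-only tests."""
    records, labels, staging, util, liability = simulate_cohort(small_spec)
    return {
        "spec": small_spec,
        "records": records,
        "labels": labels,
        "staging": staging,
        "utilization": util,
        "liability": liability,
    }


@pytest.fixture(scope="session")
def presence(cohort):
    spec = cohort["spec"]
    return build_presence_matrix(
        cohort["records"],
        roster=list(cohort["labels"].index),
        features=spec.relevant_phecodes + spec.noise_phecodes,
    )


@pytest.fixture(scope="session")
def genotype_blocks(small_spec):
    blocks, increment = simulate_genotypes(small_spec)
    return blocks, increment


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_records():
    rows = [
        ("A", "585.3", 50.0),
        ("A", "585.3", 51.0),
        ("A", "250.2", 60.0),
        ("B", "585.3", 40.0),
        ("B", "401.1", 40.0),
        ("B", "401.1", 40.5),
        ("B", "401.1", 41.0),
    ]
    return pd.DataFrame(rows, columns=["subject_id", "phecode", "age_at_observation"])
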