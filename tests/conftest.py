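import numpy as np
import pandas as pd
import pytest

import qmriage as q


@pytest.fixture(scope="session")
def cohort293():
    """Study-sized cohort: 293 subjects, decade-stratified ages 18-79."""
    return q.generate_cohort(q.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def design293(cohort293):
    return q.build_design(cohort293)


@pytest.fixture(scope="session")
def strong_region(cohort293, design293):
    """One cGM region simulated from the default R1-like library, with truth."""
    lib = q.default_trajectory_library("R1", n_cgm=1, n_swm=0, n_bundles=0, seed=3)
    spec = lib.specs[0]
    df = q.generate_region_metrics(cohort293, lib, seed=4)
    wide = df.pivot_table(index="subject_id", columns=["tissue", "region_id"], values="value")
    y = wide[(spec.tissue, spec.region_id)]
    return spec, y


@pytest.fixture()
def tiny_cohort():
    rng = np.random.default_rng(0)
    n = 40
    return pd.DataFrame(
        {
            "subject_id": [f"T{i:03d}" for i in range(n)],
            "age": rng.uniform(18, 79, n),
            "sex": rng.choice(["female", "male"], n),
            "education": rng.choice(["low", "medium", "high"], n),
            "moca": rng.integers(24, 31, n),
        }
    )
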