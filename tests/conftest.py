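import numpy as np
import pandas as pd
import pytest

from cortexlink.atlas import left_regions, region_names
from cortexlink.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(**overrides) -> SyntheticConfig:
    """A fast, small synthetic study for unit tests."""
    params = dict(
        n_patients=14, n_controls=8, n_dropout=2, n_genes=40,
        probes_per_gene=2, n_donors=3, samples_per_region_per_donor=1,
        n_cpg_per_gene=3, n_driven_genes=8, seed=7,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def reference_cohort():
    """One full default-size cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture
def atlas34():
    return left_regions(region_names(68))


def make_ct_table(rng, ids, regions, group="patient_0w"):
    """Random but well-conditioned CT table for phenotype unit tests."""
    tab = pd.DataFrame({
        "subject_id": ids,
        "group": group,
        "age": rng.uniform(18, 45, len(ids)),
        "sex": rng.integers(0, 2, len(ids)),
        "tiv": rng.normal(1.45e6, 1e5, len(ids)),
    })
    ct = pd.DataFrame(2.5 + 0.1 * rng.standard_normal((len(ids), len(regions))),
                      columns=regions)
    return pd.concat([tab, ct], axis=1)
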