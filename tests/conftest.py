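import numpy as np
import pandas as pd
import pytest

from clonalshift.clonal_dynamics import load_driver_genes
from clonalshift.synthetic_cohort import SimConfig, simulate_cohort, simulate_patient


@pytest.fixture(scope="session")
def drivers():
    return load_driver_genes()


@pytest.fixture(scope="session")
def study_config():
    """Study conditions used by the classification experiments."""
    return SimConfig(seed=101, excluded_fraction=0.0, purity_pre=0.6,
                     purity_post=0.6, purity_jitter=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-patient cohort at default study conditions."""
    return simulate_cohort(SimConfig(n_patients=8, seed=202))


@pytest.fixture(scope="session")
def bottleneck_patient(study_config):
    return simulate_patient(0, "bottleneck", study_config)


def make_variant_row(**kw):
    """One flat-schema variant row with clean defaults."""
    row = {
        "chrom": "1", "pos": 1000, "ref": "C", "alt": "T", "gene": ".",
        "context96": 40,
        "normal_depth": 60, "normal_alt": 0,
        "pre_depth": 100, "pre_alt": 10,
        "post_depth": 100, "post_alt": 10,
        "population_frequency": 0.0, "panel_of_normals_hit": False,
        "segdup_region": False, "mappability": 1.0, "total_cn": 2.0,
    }
    row.update(kw)
    return row


@pytest.fixture
def variant_table_factory():
    def make(rows):
        return pd.DataFrame([make_variant_row(**r) for r in rows])

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
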