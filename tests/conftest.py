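import logging

import pytest

from pallidyn import io, simulate
from pallidyn.features import FeatureConfig, featurize_cohort

logging.getLogger("pallidyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def profiles():
    return io.load_gene_profiles()


@pytest.fixture(scope="session")
def clinical_records():
    return io.load_clinical_fixture()


@pytest.fixture(scope="session")
def cohort_table(profiles):
    """Featurized synthetic cohort (40 neurons/gene, oscillation testing off)
    shared by the statistics, embedding and decoding tests."""
    trains = simulate.gen_cohort(profiles, n_per_gene=40, duration=20.0, seed=11)
    return featurize_cohort(trains, FeatureConfig(compute_oscillations=False))
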