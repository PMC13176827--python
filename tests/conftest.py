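import pytest

from tbstrat.config import SimConfig
from tbstrat import markers as mk
from tbstrat import synthetic as syn


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sc_dataset(default_config):
    """Default three-population count matrix with ground truth."""
    return syn.gen_sc_dataset(default_config)


@pytest.fixture(scope="session")
def normalized_sc(sc_dataset):
    """QC-filtered, log-normalized version of the default dataset."""
    adata, truth = sc_dataset
    return mk.log_normalize(mk.qc_filter(adata)), truth


@pytest.fixture(scope="session")
def ihc_cohort(default_config):
    return syn.gen_ihc_cohort(default_config)


@pytest.fixture(scope="session")
def viability_screen(default_config):
    return syn.gen_viability_screen(default_config)


@pytest.fixture(scope="session")
def survival_cohort(default_config):
    return syn.gen_survival_cohort(default_config)
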