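import numpy as np
import pytest

from phyloprof.alphabet import blosum62
from phyloprof.pipeline_runner import PipelineConfig, run_study
from phyloprof.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def scoring():
    return blosum62()


@pytest.fixture(scope="session")
def dataset():
    """The default 12-taxon, 7-family synthetic study."""
    return generate_dataset(n_taxa=12, seed=1)


@pytest.fixture(scope="session")
def study(dataset):
    """One full pipeline run shared by pipeline and acceptance tests."""
    return run_study(PipelineConfig(seed=1), dataset=dataset)
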