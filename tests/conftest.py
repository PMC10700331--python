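import numpy as np
import pytest

from ketogene.association import GenotypeOutcomeTable
from ketogene.datasets import expand_counts_to_records, load_study_counts


@pytest.fixture(scope="session")
def study_table() -> GenotypeOutcomeTable:
    """The published 2x3 genotype-by-ketosis counts (n = 977)."""
    return load_study_counts()


@pytest.fixture(scope="session")
def study_records(study_table):
    """The counts table expanded into one pseudo-record per animal."""
    return expand_counts_to_records(study_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231206)
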