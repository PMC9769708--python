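import pytest

from cress_evolve import synth
from cress_evolve.seqio import STANDARD_CODE


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def small_families():
    """Four planted families of six 150-mers at 10% within-family divergence."""
    records, truth = synth.gen_protein_families(
        n_families=4, members_per_family=6, length=150, within_sub_prob=0.1, seed=101
    )
    return records, truth
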