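import pytest

from woolmap import fixtures as fx
from woolmap import mapping as mp


@pytest.fixture(scope="session")
def replica_locus():
    """The instantiated two-gene replica locus (seed fixed for the session)."""
    return fx.replica_locus(seed=0)


@pytest.fixture(scope="session")
def replica_panel():
    return fx.replica_panel()


@pytest.fixture(scope="session")
def replica_haplotypes(replica_panel):
    return mp.infer_transmitted_haplotypes(replica_panel)
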