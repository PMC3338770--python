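import pytest

from metafunc.pipeline import analyze_sample
from metafunc.simulate import CommunitySpec, simulate_community, simulate_hits

#: truth-table category -> classifier category
TRUTH_TO_CLASS = {
    "adaptor": "adaptor",
    "rrna": "rrna",
    "mouse_tx": "mouse",
    "mouse_genome": "mouse",
    "bact_nt": "bacterial_nt",
    "bact_peptide": "bacterial_peptide",
}


@pytest.fixture(scope="session")
def community():
    return simulate_community(CommunitySpec(n_reads=4000, seed=11))


@pytest.fixture(scope="session")
def evidence(community):
    return simulate_hits(community)


@pytest.fixture(scope="session")
def analysis(community, evidence):
    return analyze_sample(community, evidence)
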