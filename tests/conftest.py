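import pytest

from terpmine.miner import mine
from terpmine.synthetic_data import (
    anchor_query_protein,
    plant_genome,
    two_cluster_spec,
)


@pytest.fixture(scope="session")
def anchor_query() -> dict[str, str]:
    return {"GGDPS_query": anchor_query_protein()}


@pytest.fixture(scope="session")
def planted_genome():
    """One deterministic two-cluster genome with its truth set."""
    return plant_genome(two_cluster_spec(rng_seed=7))


@pytest.fixture(scope="session")
def mined_candidates(planted_genome, anchor_query):
    contigs, _ = planted_genome
    return mine(contigs, anchor_query)
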