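import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from readrescue import align, synthetic_data as sd  # noqa: E402


@pytest.fixture(scope="session")
def host_genome():
    return sd.generate_genome(60_000, 0.41, 2, seed=7, name="host",
                              taxon_id="h_sapiens")


@pytest.fixture(scope="session")
def host_index(host_genome):
    return align.build_index(host_genome, 12)


@pytest.fixture(scope="session")
def toy_tree():
    return sd.toy_taxonomy()


@pytest.fixture(scope="session")
def contaminant_genome():
    return sd.generate_genome(30_000, 0.52, 1, seed=8, name="ecoli",
                              taxon_id="e_coli")
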