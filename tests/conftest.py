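import numpy as np
import pytest

from gagclust.seq_core import SequenceRecord
from gagclust.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(id, residues, species="Bacteroides testus", family="PL8", **kw):
    return SequenceRecord(id=id, residues=residues, species=species, family=family, **kw)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """One default-condition dataset shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=7, mixed_na_fraction=0.25))


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for fast CLI / pipeline round trips."""
    from gagclust.synthetic_data import FamilySpec

    return SimulationConfig(
        n_species=12,
        families=(FamilySpec("PL8", 3), FamilySpec("GH88", 3)),
        pathway_archetypes=frozenset({("PL8", 0), ("GH88", 0)}),
        protein_length=120,
        seed=3,
    )
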