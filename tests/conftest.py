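import numpy as np
import pytest

from itsfunc.kmers import count_kmers
from itsfunc.refdb import RAVRecord, ReferenceDatabase
from itsfunc.simulate import SimulationConfig, simulate_reference


def make_db(entries, profiles, catalog=None, k=2, amplicon_class="concatenate"):
    """Build a small in-memory database from (genome_id, sequence) pairs.

    ``profiles`` maps genome_id -> profile vector (already normalized).
    """
    ravs = [
        RAVRecord(gid, amplicon_class, seq, count_kmers(seq, k=k, record_id=gid))
        for gid, seq in entries
    ]
    profs = {gid: np.asarray(p, dtype=float) for gid, p in profiles.items()}
    L = len(next(iter(profs.values())))
    if catalog is None:
        catalog = [f"fn{j}" for j in range(L)]
    return ReferenceDatabase(amplicon_class, ravs, profs, catalog, k)


@pytest.fixture(scope="session")
def sim_db():
    """The default synthetic world: 64 genomes on a balanced binary tree."""
    return simulate_reference(SimulationConfig(seed=1))


@pytest.fixture
def tiny_db():
    """Three well-separated 2-mer worlds: poly-A, poly-C, and an A/C mix."""
    return make_db(
        entries=[("gA", "AAAAAA"), ("gC", "CCCCCC"), ("gM", "ACACAC")],
        profiles={
            "gA": [1.0, 0.0, 0.0],
            "gC": [0.0, 1.0, 0.0],
            "gM": [0.0, 0.0, 1.0],
        },
        k=2,
    )
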