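from __future__ import annotations

import numpy as np
import pytest

from lakevir.alignment_core import find_orfs
from lakevir.synthetic_community import SimulationConfig, simulate_community


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def small_community():
    """Small but complete synthetic community shared across test modules."""
    cfg = SimulationConfig(
        seed=5,
        n_host_genomes=4,
        n_viral_populations=4,
        members_per_population=3,
        host_length_range=(50_000, 100_000),
        viral_length_range=(15_000, 30_000),
        n_decoys=8,
        host_link_fraction=1.0,
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def small_viral_genes(small_community):
    vir = {
        v: small_community.scaffolds[v] for v in small_community.truth.viral_ids()
    }
    return {v: find_orfs(s, scaffold_id=v) for v, s in vir.items()}
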