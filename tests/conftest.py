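from __future__ import annotations

import numpy as np
import pytest

from vicinitycover import (
    Gene,
    GeneIndex,
    SyntheticConfig,
    build_sets,
    simulate_layout,
)


def make_uniform(n: int, length: int = 1500, gap: int = 1000,
                 chromosome: str = "chrU") -> GeneIndex:
    """Evenly spaced genes: gene k (1-based) spans [(k-1)(L+g), (k-1)(L+g)+L)."""
    pitch = length + gap
    genes = [
        Gene(
            id=f"u{k:03d}",
            chromosome=chromosome,
            left=(k - 1) * pitch,
            right=(k - 1) * pitch + length,
            strand="+",
        )
        for k in range(1, n + 1)
    ]
    return GeneIndex(chromosome=chromosome, genes=genes)


def random_geometric_instance(rng: np.random.Generator, n_min: int = 4,
                              n_max: int = 20, t_min: int = 1500,
                              t_max: int = 12000):
    """Random small gene layout plus its vicinity sets at a random threshold."""
    n = int(rng.integers(n_min, n_max + 1))
    cfg = SyntheticConfig(
        seed=int(rng.integers(2**31 - 1)),
        n_genes=n,
        length_model=(3000.0, 2000.0),
        gap_model=(2000.0, 1500.0),
        overlap_fraction=0.1,
        min_gene_length=100,
    )
    index = simulate_layout(cfg)
    t = int(rng.integers(t_min, t_max + 1))
    sets, _ = build_sets(index, t)
    return index, t, sets


@pytest.fixture
def uniform9() -> GeneIndex:
    return make_uniform(9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
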