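"""Synthetic gene layouts and distance-correlated expression matrices.

The generator emulates the two data features the method rests on: genes laid
out along a chromosome with realistic lengths, gaps, occasional overlaps and
mixed strands; and expression profiles whose pairwise correlation decays with
genomic distance.  The latent tissue field uses an exponential covariance
exp(-d / lambda) over gene midpoints.  That kernel is Markov along the gene
ordering, so each tissue's field is drawn exactly by the AR(1) recursion

    x_1 = z_1,    x_k = rho_k x_{k-1} + sqrt(1 - rho_k^2) z_k,
    rho_k = exp(-d_k / lambda)

with d_k the midpoint distance between consecutive genes — O(n) per tissue
and no covariance factorization.  TPM values are a lognormal envelope over
the latent field plus independent noise, so absolute levels span orders of
magnitude while profile *shapes* stay distance-correlated.

Fixed worked-example instances (the five-gene membership pattern, the
greedy-suboptimal family, the forced-terminal trap, identical neighbor sets,
and the tied-predecessor chain) are exposed by name for tests and docs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation import Gene, GeneIndex
from .cover import IntervalSet
from .expression import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "simulate_layout",
    "simulate_expression",
    "worked_example_instance",
    "WORKED_EXAMPLES",
]

SizeModel = Union[int, float, tuple[float, float]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic genome and expression generator.

    Defaults describe a gene-dense chromosome arm: ~20 kb genes separated by
    ~10 kb gaps (so neighboring midpoints sit ~30 kb apart), a correlation
    length of 60 kb — matching the range over which neighboring genes' tissue
    profiles are reported to stay similar — 54 tissues as in the human
    genotype-tissue expression resource, half the genes antisense, and a few
    percent of gene pairs overlapping so the t = 0 edge case is exercised.
    """

    seed: int = 0
    n_genes: int = 200
    length_model: SizeModel = (20_000.0, 15_000.0)
    gap_model: SizeModel = (10_000.0, 8_000.0)
    overlap_fraction: float = 0.05
    antisense_fraction: float = 0.5
    n_tissues: int = 54
    correlation_length: float = 60_000.0
    noise_sd: float = 0.7
    chromosome: str = "chrS"
    min_gene_length: int = 200

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.correlation_length > 0:
            raise ValueError("correlation_length must be positive")
        for name in ("overlap_fraction", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_sizes(
    model: SizeModel, size: int, rng: np.random.Generator, minimum: int
) -> np.ndarray:
    """Draw integer sizes from a fixed value or a clipped normal (mean, sd)."""
    if isinstance(model, (int, float)):
        return np.full(size, max(int(model), minimum), dtype=np.int64)
    mean, sd = model
    draws = rng.normal(mean, sd, size=size)
    return np.maximum(np.round(draws).astype(np.int64), minimum)


_RESAMPLE_CAP = 100


def simulate_layout(cfg: SyntheticConfig) -> GeneIndex:
    """Lay genes left to right with sampled lengths and gaps.

    An ``overlap_fraction`` of the inter-gene gaps is replaced by a negative
    offset (the next gene starts inside the previous one, possibly nested),
    sized by rejection so the ordering by left coordinate stays strict;
    ``antisense_fraction`` of strands are flipped.  Same seed, same layout.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = _sample_sizes(cfg.length_model, cfg.n_genes, rng, cfg.min_gene_length)
    gaps = _sample_sizes(cfg.gap_model, max(0, cfg.n_genes - 1), rng, 0)
    overlap_mask = rng.random(max(0, cfg.n_genes - 1)) < cfg.overlap_fraction
    strands = np.where(rng.random(cfg.n_genes) < cfg.antisense_fraction, "-", "+")

    genes: list[Gene] = []
    cursor = 0
    width = len(str(cfg.n_genes))
    for k in range(cfg.n_genes):
        if k > 0:
            if overlap_mask[k - 1]:
                prev_len = lengths[k - 1]
                offset = None
                for _ in range(_RESAMPLE_CAP):
                    cand = int(rng.integers(1, max(2, prev_len)))
                    if cand < prev_len:  # keep left coordinates strictly increasing
                        offset = -cand
                        break
                if offset is None:
                    raise RuntimeError(
                        f"could not place an overlap after gene {k}: "
                        f"previous gene too short ({prev_len} bp)"
                    )
                cursor += offset
            else:
                cursor += int(gaps[k - 1])
        left = cursor
        right = left + int(lengths[k])
        genes.append(
            Gene(
                id=f"g{k + 1:0{width}d}",
                chromosome=cfg.chromosome,
                left=left,
                right=right,
                strand=str(strands[k]),
            )
        )
        cursor = right
    return GeneIndex(chromosome=cfg.chromosome, genes=genes)


def simulate_expression(index: GeneIndex, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Draw a genes x tissues TPM matrix with distance-decaying correlation.

    Per tissue, a unit-variance latent field over gene midpoints with
    covariance exp(-d / correlation_length) is drawn by the exact AR(1)
    recursion; independent N(0, noise_sd^2) noise is added; TPM is the
    exponential of (per-gene lognormal baseline + latent + noise).  Expected
    pairwise PCC is decreasing in midpoint distance, reaching ~0 for genes
    many correlation lengths apart.
    """
    # Seed offset keeps the expression stream independent of the layout
    # stream while remaining a pure function of cfg.seed.
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    n, T = index.n, cfg.n_tissues
    mids = np.array([g.midpoint for g in index], dtype=float)
    # nested genes can put a midpoint left of its predecessor's; the kernel
    # depends on the absolute distance
    d = np.abs(np.diff(mids))
    lam = float(cfg.correlation_length)
    rho = np.exp(-d / lam) if math.isfinite(lam) else np.ones_like(d)

    z = rng.standard_normal((n, T))
    x = np.empty((n, T))
    x[0] = z[0]
    for k in range(1, n):
        x[k] = rho[k - 1] * x[k - 1] + math.sqrt(max(0.0, 1.0 - rho[k - 1] ** 2)) * z[k]

    baseline = rng.normal(loc=2.0, scale=1.5, size=n)  # natural-log TPM level
    noise = cfg.noise_sd * rng.standard_normal((n, T))
    tpm = np.exp(baseline[:, None] + x + noise)

    df = pd.DataFrame(
        tpm,
        index=[g.id for g in index],
        columns=[f"tissue_{t + 1:02d}" for t in range(T)],
    )
    return ExpressionMatrix(values=df)


# ---------------------------------------------------------------------------
# worked examples


def _five_gene_vicinity_instance() -> tuple[GeneIndex, list[IntervalSet]]:
    """Five genes at t = 1000 whose first three vicinity sets are
    {1,2}, {1,2,3} and {2,3,4,5} — the canonical membership pattern."""
    coords = [(0, 500), (1200, 1700), (2500, 3000), (3500, 4000), (3900, 4400)]
    genes = [
        Gene(id=f"g{k + 1}", chromosome="chrE", left=l, right=r, strand="+")
        for k, (l, r) in enumerate(coords)
    ]
    sets = [IntervalSet(1, 2), IntervalSet(1, 3), IntervalSet(2, 5)]
    return GeneIndex(chromosome="chrE", genes=genes), sets


WORKED_EXAMPLES = ("five_gene_vicinity", "greedy_gap", "terminal_trap", "identical_neighbors",
                   "tied_predecessors")


def worked_example_instance(
    name: str,
) -> tuple[Optional[GeneIndex], list[IntervalSet]]:
    """Deterministic fixture instances for documented solver properties.

    ``five_gene_vicinity``
        Five real genes (t = 1000) realizing the membership pattern
        g1={1,2}, g2={1,2,3}, g3={2,3,4,5}; minimum cover size 2.
    ``greedy_gap``
        Intervals {1..3}, {2..7}, {4..8} over eight elements: greedy takes
        three sets where two suffice.  Not realizable by any gene layout
        (facing-gap membership is symmetric), so no GeneIndex.
    ``terminal_trap``
        The next-to-last set already covers everything; forcing the chain
        through the last set costs one extra reference.
    ``identical_neighbors``
        Two bit-identical sets (genes with identical neighborhoods) giving
        two tied minimum covers.
    ``tied_predecessors``
        Nine sets whose minimum chain lengths run 1,2,2,2,2,3,... with four
        equally short predecessors feeding the sixth set.
    """
    if name == "five_gene_vicinity":
        return _five_gene_vicinity_instance()
    if name == "greedy_gap":
        return None, [IntervalSet(1, 3), IntervalSet(2, 7), IntervalSet(4, 8)]
    if name == "terminal_trap":
        return None, [
            IntervalSet(1, 2),
            IntervalSet(2, 3),
            IntervalSet(1, 4),
            IntervalSet(3, 4),
        ]
    if name == "identical_neighbors":
        return None, [IntervalSet(1, 2), IntervalSet(1, 2), IntervalSet(2, 3)]
    if name == "tied_predecessors":
        return None, [
            IntervalSet(1, 3),
            IntervalSet(2, 5),
            IntervalSet(3, 6),
            IntervalSet(4, 7),
            IntervalSet(4, 8),
            IntervalSet(5, 9),
            IntervalSet(6, 9),
            IntervalSet(7, 9),
            IntervalSet(8, 9),
        ]
    raise ValueError(f"unknown worked example {name!r}; choose one of {WORKED_EXAMPLES}")
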