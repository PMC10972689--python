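"""Index of dispersion of deleterious load across haplotypes.

The number of deleterious alleles carried per haplotype (a haplotype is
all chromosomes inherited from one parent, so a diploid carries two) is
a count variable; its index of dispersion — sample variance divided by
mean — is 1 when sites evolve independently (Poisson), and falls below
1 when segregating deleterious sites are negatively correlated across
haplotypes, the genome-wide signature of nonindependent evolution that
unlinked background selection produces at high mutation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Population, SimulationParams, run_simulation

__all__ = [
    "DispersionResult",
    "ReplicateDispersion",
    "index_of_dispersion",
    "dispersion_from_counts",
    "replicate_dispersion",
]


@dataclass(frozen=True)
class DispersionResult:
    """Variance/mean of deleterious allele counts over 2N haplotypes."""

    n_haplotypes: int
    mean_count: float
    variance_count: float  # sample variance, denominator 2N - 1
    index: float
    replicate_id: int | None = None
    params: dict | None = None


def dispersion_from_counts(
    counts, replicate_id: int | None = None, params: dict | None = None
) -> DispersionResult:
    """Index of dispersion of an explicit per-haplotype count vector."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size < 2:
        raise ValueError("need at least 2 haplotypes")
    mean = float(counts.mean())
    if mean == 0.0:
        raise ValueError(
            "index of dispersion undefined: no deleterious alleles (zero mean)"
        )
    var = float(counts.var(ddof=1))
    return DispersionResult(
        n_haplotypes=counts.size,
        mean_count=mean,
        variance_count=var,
        index=var / mean,
        replicate_id=replicate_id,
        params=params,
    )


def index_of_dispersion(
    pop: Population, replicate_id: int | None = None
) -> DispersionResult:
    """Index of dispersion of the population's deleterious load per haplotype."""
    return dispersion_from_counts(
        pop.deleterious_load(), replicate_id=replicate_id
    )


@dataclass(frozen=True)
class ReplicateDispersion:
    """Mean index of dispersion over replicate simulations, with its SE."""

    mean_index: float
    se_index: float
    n_replicates: int
    results: tuple = field(default_factory=tuple)


def replicate_dispersion(
    params: SimulationParams,
    n_replicates: int,
    seeds=None,
    log_every: int = 0,
) -> ReplicateDispersion:
    """Run independent replicate simulations and aggregate final-generation indices.

    Replicate r uses seed ``params.seed + r`` unless an explicit seed
    sequence is supplied.  Reports the mean index and the standard error
    of the mean, sd/sqrt(n).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if seeds is None:
        seeds = [params.seed + r for r in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")
    results = []
    for r, seed in enumerate(seeds):
        p = SimulationParams(
            N=params.N,
            U=params.U,
            dfe=params.dfe,
            architecture=params.architecture,
            neutral_mu_per_unit=params.neutral_mu_per_unit,
            generations=params.generations,
            seed=int(seed),
            purge_every=params.purge_every,
        )
        pop, _ = run_simulation(p, log_every=log_every)
        results.append(index_of_dispersion(pop, replicate_id=r))
    idx = np.array([r.index for r in results])
    return ReplicateDispersion(
        mean_index=float(idx.mean()),
        se_index=float(idx.std(ddof=1) / np.sqrt(n_replicates)),
        n_replicates=n_replicates,
        results=tuple(results),
    )
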