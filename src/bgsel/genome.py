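"""Genome architecture, mutation placement, and the distribution of fitness effects.

The simulated genome is a set of equally long chromosomes measured in
continuous genomic "units" (no base-pair grid: under the infinite-sites
assumption every mutation lands at a fresh real-valued coordinate, so
collisions are measure-zero).  Internally positions are *global*
coordinates on the concatenated genome; chromosome ``c`` occupies
``[c*L, (c+1)*L)``.

Deleterious mutations fall either uniformly over the core chromosomes
("uniform" mode) or only inside regularly interspersed genes ("genic"
mode).  An optional extra chromosome of the same length receives
neutral mutations and crossovers but never deleterious mutations,
isolating purely unlinked background selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "GenomeArchitecture",
    "DFEModel",
    "Mutation",
    "build_architecture",
    "draw_effect",
    "sample_mutation_positions",
    "sample_positions_global",
    "mean_sh_from_scaled_dfe",
    "MAX_SH_MAG",
]

#: Cap on |sh| so the homozygote fitness factor 1 + s = 1 + sh/h stays positive
#: (with the additive default h = 0.5, s = 2*sh must exceed -1).
MAX_SH_MAG = 0.499999


@dataclass(frozen=True)
class GenomeArchitecture:
    """Layout of the simulated genome.

    Parameters
    ----------
    n_chromosomes : int
        Number of core chromosomes eligible for deleterious mutations.
    chromosome_length : float
        Length of every chromosome in genomic units.
    crossovers_per_chromosome : int
        Number of crossover points per transmitted chromosome (fixed 2
        in the study design; configurable for testing).
    deleterious_mode : str
        ``"uniform"`` — deleterious mutations uniform over the core
        chromosomes; ``"genic"`` — restricted to gene intervals.
    n_genes, genic_fraction :
        Number of genes and the fraction of the core genome they cover
        (genic mode only).
    has_neutral_chromosome : bool
        Add one extra chromosome receiving neutral mutations and
        crossovers but no deleterious mutations.
    """

    n_chromosomes: int = 23
    chromosome_length: float = 100.0
    crossovers_per_chromosome: int = 2
    deleterious_mode: str = "uniform"
    n_genes: int = 1000
    genic_fraction: float = 0.10
    has_neutral_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")
        if self.crossovers_per_chromosome < 0:
            raise ValueError("crossovers_per_chromosome must be >= 0")
        if self.deleterious_mode not in ("uniform", "genic"):
            raise ValueError(
                f"deleterious_mode must be 'uniform' or 'genic', "
                f"got {self.deleterious_mode!r}"
            )
        if self.deleterious_mode == "genic":
            if not 0 < self.genic_fraction < 1:
                raise ValueError("genic_fraction must be in (0, 1)")
            if self.n_genes < 1:
                raise ValueError("n_genes must be >= 1 in genic mode")

    # ---- derived layout -------------------------------------------------

    @property
    def n_total_chromosomes(self) -> int:
        return self.n_chromosomes + int(self.has_neutral_chromosome)

    @property
    def core_length(self) -> float:
        """Total length of the deleterious-eligible (core) chromosomes."""
        return self.n_chromosomes * self.chromosome_length

    @property
    def total_length(self) -> float:
        """Total genome length including any neutral chromosome."""
        return self.n_total_chromosomes * self.chromosome_length

    @property
    def deleterious_length(self) -> float:
        """Total length eligible to receive deleterious mutations."""
        if self.deleterious_mode == "genic":
            return self.genic_fraction * self.core_length
        return self.core_length

    @property
    def map_length_morgans(self) -> float:
        """Map length of the core chromosomes in Morgans (crossovers per gamete)."""
        return float(self.n_chromosomes * self.crossovers_per_chromosome)

    @property
    def chromosome_offsets(self) -> np.ndarray:
        """Global start coordinate of each chromosome (incl. neutral)."""
        return np.arange(self.n_total_chromosomes) * self.chromosome_length

    def gene_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """Global gene start coordinates and lengths (genic mode).

        Genes are apportioned across chromosomes as evenly as possible,
        then evenly spaced and centred within each chromosome so that no
        gene straddles a chromosome end and each chromosome's genic
        fraction equals ``genic_fraction`` exactly.
        """
        if self.deleterious_mode != "genic":
            raise ValueError("gene_intervals() requires genic mode")
        return _gene_intervals(
            self.n_chromosomes,
            self.chromosome_length,
            self.n_genes,
            self.genic_fraction,
        )

    def chromosome_of(self, position: np.ndarray | float):
        """Chromosome index of a global position."""
        return np.floor_divide(position, self.chromosome_length).astype(np.int64)

    def local_position(self, position: np.ndarray | float):
        """Within-chromosome coordinate of a global position."""
        return np.mod(position, self.chromosome_length)


@lru_cache(maxsize=32)
def _gene_intervals(
    n_chromosomes: int, chromosome_length: float, n_genes: int, genic_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    per_chrom = np.diff(
        np.round(np.linspace(0, n_genes, n_chromosomes + 1))
    ).astype(int)
    starts = []
    lengths = []
    for c, m in enumerate(per_chrom):
        if m == 0:
            continue
        span = chromosome_length / m  # spacing between consecutive gene starts
        glen = genic_fraction * span
        j = np.arange(m)
        starts.append(c * chromosome_length + j * span + (span - glen) / 2.0)
        lengths.append(np.full(m, glen))
    s = np.concatenate(starts)
    ln = np.concatenate(lengths)
    s.setflags(write=False)
    ln.setflags(write=False)
    return s, ln


def build_architecture(config: dict | None = None, **overrides) -> GenomeArchitecture:
    """Assemble a :class:`GenomeArchitecture` from a config mapping.

    Recognised keys mirror the dataclass fields; unknown keys raise.
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    valid = set(GenomeArchitecture.__dataclass_fields__)
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown architecture config keys: {sorted(unknown)}")
    arch = GenomeArchitecture(**cfg)
    if arch.deleterious_mode == "genic":
        arch.gene_intervals()  # force validation of the layout
    return arch


# ---------------------------------------------------------------------------
# Distribution of fitness effects


@dataclass(frozen=True)
class DFEModel:
    """Distribution of heterozygous fitness effects of new deleterious mutations.

    ``constant`` always yields ``sh = -mean_sh_mag``; ``gamma`` draws
    |sh| from a gamma distribution with mean ``mean_sh_mag`` and shape
    ``shape`` (scale = mean/shape) and negates it.  Draws are capped at
    :data:`MAX_SH_MAG` so the homozygote fitness factor stays positive.
    The dominance coefficient ``h`` scales the heterozygous effect:
    ``s = sh / h``, additive by default (h = 0.5, s = 2*sh).
    """

    kind: str = "constant"
    mean_sh_mag: float = 0.01
    shape: float = 0.169
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gamma"):
            raise ValueError(f"DFE kind must be 'constant' or 'gamma', got {self.kind!r}")
        if not 0 < self.mean_sh_mag <= MAX_SH_MAG:
            raise ValueError(f"mean_sh_mag must be in (0, {MAX_SH_MAG}]")
        if self.shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if not 0 < self.h <= 1:
            raise ValueError("h must be in (0, 1]")


def draw_effect(dfe: DFEModel, rng: np.random.Generator, size: int | None = None):
    """Draw signed heterozygous effects sh (negative for deleterious).

    Returns a scalar when ``size`` is None, else an array of ``size`` draws.
    """
    n = 1 if size is None else int(size)
    if dfe.kind == "constant":
        out = np.full(n, -dfe.mean_sh_mag)
    else:
        mags = rng.gamma(dfe.shape, dfe.mean_sh_mag / dfe.shape, size=n)
        out = -np.minimum(mags, MAX_SH_MAG)
    return out[0] if size is None else out


def mean_sh_from_scaled_dfe(
    mean_s_ne: float = -224.33, two_ne: float = 23_646.0, h: float = 0.5
) -> float:
    """Mean heterozygous effect sh from a population-scaled DFE estimate.

    Given the estimated mean scaled selection coefficient ``s*Ne`` and
    ``2*Ne`` of the estimating population, the unscaled homozygous
    effect is ``s = mean_s_ne / (two_ne / 2)`` and ``sh = h*s``.  The
    defaults (a human non-synonymous DFE) give sh ~ -0.01.
    """
    if two_ne <= 0:
        raise ValueError("two_ne must be > 0")
    return h * mean_s_ne / (two_ne / 2.0)


# ---------------------------------------------------------------------------
# Mutation placement


@dataclass(frozen=True)
class Mutation:
    """A single mutation in the population registry."""

    id: int
    chromosome: int
    position: float  # within-chromosome coordinate, in units
    sh: float  # signed heterozygous effect; 0.0 for the neutral class
    kind: str  # "deleterious" | "neutral"
    origin_generation: int


def sample_positions_global(
    arch: GenomeArchitecture, kind: str, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample mutation positions as global coordinates.

    Deleterious positions are uniform over the eligible set (core
    chromosomes, or gene intervals in genic mode); neutral positions
    are uniform over the entire genome including any neutral chromosome.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if kind == "neutral":
        return rng.uniform(0.0, arch.total_length, size=count)
    if kind != "deleterious":
        raise ValueError(f"kind must be 'deleterious' or 'neutral', got {kind!r}")
    if arch.deleterious_length <= 0:
        raise ValueError("no deleterious-eligible sequence in this architecture")
    if arch.deleterious_mode == "uniform":
        return rng.uniform(0.0, arch.core_length, size=count)
    starts, lengths = arch.gene_intervals()
    cum = np.cumsum(lengths)
    u = rng.uniform(0.0, cum[-1], size=count)
    idx = np.searchsorted(cum, u, side="right")
    prev = np.where(idx > 0, cum[idx - 1], 0.0) if count else np.empty(0)
    return starts[idx] + (u - prev)


def sample_mutation_positions(
    arch: GenomeArchitecture, kind: str, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``count`` positions, returned as (chromosome, local position) arrays."""
    g = sample_positions_global(arch, kind, count, rng)
    return arch.chromosome_of(g), arch.local_position(g)
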