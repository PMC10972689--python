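"""Neutral diversity and effective population size, whole-genome and by region.

Two mutation-model conventions are supported, matching how each genomic
comparison is usually made:

* **infinite alleles** — the genome is partitioned into short loci
  (0.1 genomic units by default); the allele of a haplotype at a locus
  is the exact set of neutral mutations it carries there.  Expected
  heterozygosity H relates to the scaled mutation rate by
  ``H = theta/(1+theta)`` with ``theta = 4*Ne*mu`` (mu per locus),
  inverted as ``Ne = H / (4*mu*(1-H))``.  Used for whole-genome
  estimates.  The locus must be short enough that ``theta`` is well
  below 1 *and* intra-locus recombination is negligible — the
  ``theta/(1+theta)`` identity probability assumes a single coalescent
  tree per locus, and a recombining window mixes genealogies, pushing
  heterozygosity toward ``1 - exp(-theta)`` and inflating the inverted
  Ne as theta grows.
* **infinite sites** — per-site pairwise diversity summed over
  segregating sites and divided by region length, with
  ``theta = 4*Ne*mu`` inverted as ``Ne = theta/(4*mu)``.  Used for
  genic / intergenic / neutral-chromosome comparisons, where finite
  allele bookkeeping inside short gene intervals would be awkward.

Both estimators apply the unbiased ``2N/(2N-1)`` sample correction, so
hand-built fixture populations reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Population
from .genome import GenomeArchitecture

__all__ = [
    "REGIONS",
    "DEFAULT_LOCUS_LENGTH",
    "DiversityEstimate",
    "region_length",
    "region_local_coord",
    "unit_heterozygosity",
    "pairwise_diversity",
    "ne_from_theta_infinite_alleles",
    "ne_from_theta_infinite_sites",
    "regional_ne_report",
]

REGIONS = ("whole", "genic", "intergenic", "neutral_chromosome")

#: Infinite-alleles locus length in genomic units.  Short enough that
#: 4*Ne*mu per locus stays well below 1 at the census sizes this package
#: simulates, and that recombination within a locus is negligible.
DEFAULT_LOCUS_LENGTH = 0.1


@dataclass(frozen=True)
class DiversityEstimate:
    """theta and inferred Ne for one genomic region class."""

    region: str
    model: str  # "infinite_alleles" | "infinite_sites"
    theta: float
    mu: float  # per unit-locus neutral rate used in the inversion
    Ne: float
    Ne_over_N: float


def _check_region(arch: GenomeArchitecture, region: str) -> None:
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if region in ("genic", "intergenic") and arch.deleterious_mode != "genic":
        raise ValueError(f"region {region!r} requires a genic-mode architecture")
    if region == "neutral_chromosome" and not arch.has_neutral_chromosome:
        raise ValueError("architecture has no neutral chromosome")


def region_length(arch: GenomeArchitecture, region: str) -> float:
    """Length of a region class in genomic units."""
    _check_region(arch, region)
    if region == "whole":
        return arch.core_length
    if region == "neutral_chromosome":
        return arch.chromosome_length
    genic = float(arch.gene_intervals()[1].sum())
    return genic if region == "genic" else arch.core_length - genic


def region_local_coord(
    arch: GenomeArchitecture, positions: np.ndarray, region: str
) -> tuple[np.ndarray, np.ndarray]:
    """(membership mask, region-local coordinate) for global positions.

    The local coordinate concatenates the region's intervals, so a
    region of total length L maps onto [0, L); it is what the
    unit-locus partition of the infinite-alleles estimator uses.
    """
    _check_region(arch, region)
    positions = np.asarray(positions, dtype=np.float64)
    if region == "whole":
        mask = positions < arch.core_length
        return mask, positions[mask]
    if region == "neutral_chromosome":
        mask = positions >= arch.core_length
        return mask, positions[mask] - arch.core_length
    starts, lengths = arch.gene_intervals()
    cum = np.concatenate(([0.0], np.cumsum(lengths)))
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx_c = np.clip(idx, 0, starts.size - 1)
    in_gene = (idx >= 0) & (positions < starts[idx_c] + lengths[idx_c])
    core = positions < arch.core_length
    if region == "genic":
        mask = in_gene & core
        return mask, cum[idx_c[mask]] + (positions[mask] - starts[idx_c[mask]])
    mask = core & ~in_gene
    p = positions[mask]
    # genic length preceding p: full genes before, plus the part of no gene
    ends = starts + lengths
    genic_before = cum[np.searchsorted(ends, p, side="right")]
    return mask, p - genic_before


def _neutral_entries(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    hap, pos, eff, _ = pop.flat_entries()
    keep = eff == 0.0
    return hap[keep], pos[keep]


def unit_heterozygosity(
    pop: Population,
    region: str = "whole",
    locus_length: float = DEFAULT_LOCUS_LENGTH,
) -> float:
    """Mean per-locus expected heterozygosity (infinite alleles).

    The region is partitioned into loci of ``locus_length`` units on its
    local coordinate; at each locus a haplotype's allele is the exact
    set of neutral mutations it carries there, and haplotypes with none
    share the ancestral allele.  Returns the across-loci mean of
    ``(2N/(2N-1)) * (1 - sum p_i^2)`` including variation-free loci.
    """
    arch = pop.architecture
    rlen = region_length(arch, region)
    if rlen <= 0:
        raise ValueError(f"region {region!r} is empty")
    if locus_length <= 0:
        raise ValueError("locus_length must be > 0")
    n_loci = int(np.ceil(rlen / locus_length - 1e-9))
    two_n = pop.n_haplotypes
    hap, pos = _neutral_entries(pop)
    mask, local = region_local_coord(arch, pos, region)
    hap = hap[mask]
    if hap.size == 0:
        return 0.0
    locus = np.floor(local / locus_length).astype(np.int64)
    # order by (locus, haplotype, position); allele = that haplotype's
    # position tuple within the locus
    order = np.lexsort((local, hap, locus))
    locus, hap, local = locus[order], hap[order], local[order]
    corr = two_n / (two_n - 1.0)
    total_h = 0.0
    # group boundaries of (locus, hap) runs
    newgrp = np.ones(hap.size, dtype=bool)
    newgrp[1:] = (locus[1:] != locus[:-1]) | (hap[1:] != hap[:-1])
    grp_starts = np.flatnonzero(newgrp)
    grp_ends = np.append(grp_starts[1:], hap.size)
    grp_locus = locus[grp_starts]
    # contiguous blocks of groups sharing a locus (grp_locus is sorted)
    block_edges = np.concatenate(
        ([0], np.flatnonzero(np.diff(grp_locus)) + 1, [grp_locus.size])
    )
    for b in range(block_edges.size - 1):
        alleles: dict[tuple, int] = {}
        for k in range(block_edges[b], block_edges[b + 1]):
            key = tuple(local[grp_starts[k] : grp_ends[k]])
            alleles[key] = alleles.get(key, 0) + 1
        carriers = sum(alleles.values())
        sum_p2 = ((two_n - carriers) / two_n) ** 2
        for c in alleles.values():
            sum_p2 += (c / two_n) ** 2
        total_h += corr * (1.0 - sum_p2)
    return total_h / n_loci


def pairwise_diversity(pop: Population, region: str = "whole") -> float:
    """Per-unit pairwise neutral diversity (infinite sites).

    Sums the unbiased per-site heterozygosity
    ``(2N/(2N-1)) * 2p(1-p)`` over segregating neutral sites in the
    region and divides by the region length in units.
    """
    arch = pop.architecture
    rlen = region_length(arch, region)
    if rlen <= 0:
        raise ValueError(f"region {region!r} is empty")
    two_n = pop.n_haplotypes
    _, pos = _neutral_entries(pop)
    mask, _ = region_local_coord(arch, pos, region)
    pos = pos[mask]
    if pos.size == 0:
        return 0.0
    _, cnt = np.unique(pos, return_counts=True)
    p = cnt / two_n
    corr = two_n / (two_n - 1.0)
    return float(np.sum(corr * 2.0 * p * (1.0 - p)) / rlen)


def ne_from_theta_infinite_alleles(theta: float, mu: float) -> float:
    """Invert ``theta = 4*Ne*mu / (1 + 4*Ne*mu)``: Ne = theta/(4*mu*(1-theta))."""
    if not 0 <= theta < 1:
        raise ValueError(f"infinite-alleles theta must be in [0, 1), got {theta}")
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return theta / (4.0 * mu * (1.0 - theta))


def ne_from_theta_infinite_sites(theta: float, mu: float) -> float:
    """Invert ``theta = 4*Ne*mu``: Ne = theta/(4*mu)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return theta / (4.0 * mu)


def regional_ne_report(
    pop: Population,
    census_n: int | None = None,
    neutral_mu_per_unit: float = 1e-4,
    regions: tuple[str, ...] | None = None,
    locus_length: float = DEFAULT_LOCUS_LENGTH,
) -> list[DiversityEstimate]:
    """Ne estimates for each requested region class.

    The whole-genome estimate uses the infinite-alleles inversion on
    per-locus heterozygosity (mu per locus = per-unit rate x locus
    length); genic, intergenic and neutral-chromosome estimates use the
    infinite-sites inversion on per-unit pairwise diversity.
    ``regions=None`` selects every region the architecture supports;
    explicitly requesting an unsupported region raises.
    """
    arch = pop.architecture
    n = pop.N if census_n is None else census_n
    if regions is None:
        regions = ["whole"]
        if arch.deleterious_mode == "genic":
            regions += ["genic", "intergenic"]
        if arch.has_neutral_chromosome:
            regions += ["neutral_chromosome"]
    out = []
    for region in regions:
        _check_region(arch, region)
        if region == "whole":
            theta = unit_heterozygosity(pop, region, locus_length)
            ne = ne_from_theta_infinite_alleles(
                theta, neutral_mu_per_unit * locus_length
            )
            model = "infinite_alleles"
        else:
            theta = pairwise_diversity(pop, region)
            ne = ne_from_theta_infinite_sites(theta, neutral_mu_per_unit)
            model = "infinite_sites"
        out.append(
            DiversityEstimate(
                region=region,
                model=model,
                theta=theta,
                mu=neutral_mu_per_unit,
                Ne=ne,
                Ne_over_N=ne / n,
            )
        )
    return out
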