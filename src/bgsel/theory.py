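"""Closed-form predictions for the reduction in effective population size.

Background selection — the purging of deleterious alleles — depresses
neutral diversity, conventionally summarised as a reduction in the
effective population size Ne relative to the census size N.  Three
classical approximations are implemented here:

* a *linked* window model, in which a neutral site sits at the centre of
  a genomic window of map length ``Rw`` receiving deleterious mutations
  at rate ``Uw``:  ``Ne/N = exp(-Uw / (2*sh + Rw))``;
* its large-window limit ``Ne/N = exp(-u/r)``, where ``u/r`` is the
  ratio of the deleterious mutation rate to the recombination rate;
* an *unlinked* (free-recombination) model,
  ``Ne/N = exp(-8*U*sh)``, where ``U`` is the genome-wide diploid
  deleterious mutation rate.

A joint model multiplies the linked and unlinked reductions, subtracting
from the unlinked term those mutations that fall inside the focal
window so they are not counted twice:

    Ne/N = exp(-8*(U - Uw)*sh) * exp(-u/r)

The genome is split into ``n_windows`` windows (20,000 by default,
roughly the number of human genes); because the joint model uses the
ratio ``Uw/Rw = U/L`` its default variant is insensitive to the window
count.  All formulas consume the *magnitude* of the heterozygous
selection coefficient sh; user-facing entry points accept the
conventional negative sign and convert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TheoryInputs",
    "ne_ratio_linked_window",
    "ne_ratio_linked",
    "ne_ratio_unlinked",
    "ne_ratio_joint",
    "estimate_genomewide_deleterious_rate",
]


@dataclass(frozen=True)
class TheoryInputs:
    """Parameters feeding the linked/unlinked/joint Ne/N formulas.

    Parameters
    ----------
    U : float
        Diploid genome-wide deleterious mutation rate per generation
        (expected new deleterious mutations per diploid offspring).
    sh_mag : float
        Magnitude of the heterozygous selection coefficient (> 0).
    total_map_length : float
        Genome map length in Morgans.  The default corresponds to a
        23-chromosome genome with exactly two crossovers per transmitted
        chromosome: 23 x 2 = 46 M.
    n_windows : int
        Number of linked-selection windows the genome is partitioned
        into for the joint model (default 20,000).
    """

    U: float
    sh_mag: float
    total_map_length: float = 46.0
    n_windows: int = 20_000

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError(f"U must be >= 0, got {self.U}")
        if self.sh_mag <= 0:
            raise ValueError(f"sh_mag must be > 0, got {self.sh_mag}")
        if self.total_map_length <= 0:
            raise ValueError(
                f"total_map_length must be > 0, got {self.total_map_length}"
            )
        if self.n_windows < 1:
            raise ValueError(f"n_windows must be >= 1, got {self.n_windows}")

    @classmethod
    def from_signed_sh(cls, U: float, sh: float, **kwargs) -> "TheoryInputs":
        """Build inputs from the conventional negative sh of a deleterious allele."""
        return cls(U=U, sh_mag=abs(sh), **kwargs)

    @property
    def Uw(self) -> float:
        """Per-window diploid deleterious mutation rate, U / n_windows."""
        return self.U / self.n_windows

    @property
    def Rw(self) -> float:
        """Per-window map length in Morgans, total_map_length / n_windows."""
        return self.total_map_length / self.n_windows

    @property
    def u_over_r(self) -> float:
        """Ratio of deleterious mutation rate to recombination rate.

        Under a homogeneous genome this is window-count free:
        (U/n) / (L/n) = U/L.
        """
        return self.U / self.total_map_length


def ne_ratio_linked_window(Uw: float, sh_mag: float, Rw: float) -> float:
    """Ne/N for a neutral site inside a window of linked deleterious sites.

    ``exp(-Uw / (2*sh_mag + Rw))`` where ``Uw`` is the total diploid
    deleterious mutation rate across the window and ``Rw`` the window
    map length.  Valid when deleterious variants within the window are
    at linkage equilibrium and the window map is additive.
    """
    if Uw < 0:
        raise ValueError(f"Uw must be >= 0, got {Uw}")
    if sh_mag < 0 or Rw < 0:
        raise ValueError("sh_mag and Rw must be >= 0")
    denom = 2.0 * sh_mag + Rw
    if denom == 0.0:
        if Uw == 0.0:
            return 1.0  # 0/0 resolved: no deleterious input, no reduction
        raise ValueError("need sh_mag > 0 or Rw > 0 when Uw > 0")
    return math.exp(-Uw / denom)


def ne_ratio_linked(u_over_r: float) -> float:
    """Large-window limit ``exp(-u/r)`` of the linked window model."""
    if u_over_r < 0:
        raise ValueError(f"u_over_r must be >= 0, got {u_over_r}")
    return math.exp(-u_over_r)


def ne_ratio_unlinked(U: float, sh_mag: float) -> float:
    """Ne/N under free recombination, ``exp(-8*U*sh_mag)``.

    Unlike the linked model, the reduction *grows* with the selection
    coefficient: faster purging removes more unlinked diversity.
    """
    if U < 0:
        raise ValueError(f"U must be >= 0, got {U}")
    if sh_mag < 0:
        raise ValueError(f"sh_mag must be >= 0, got {sh_mag}")
    return math.exp(-8.0 * U * sh_mag)


def ne_ratio_joint(inputs: TheoryInputs, variant: str = "eq2_based") -> float:
    """Joint linked x unlinked Ne/N prediction.

    The unlinked factor excludes the mutations that land inside the
    focal window (rate ``Uw``) to avoid double counting:

    * ``eq2_based`` (default): ``exp(-8*(U-Uw)*sh) * exp(-u/r)``
    * ``eq1_based``: the linked factor is the finite-window formula
      ``exp(-Uw/(2*sh+Rw))`` instead of the ``u/r`` limit.
    """
    unlinked = ne_ratio_unlinked(inputs.U - inputs.Uw, inputs.sh_mag)
    if variant == "eq2_based":
        linked = ne_ratio_linked(inputs.u_over_r)
    elif variant == "eq1_based":
        linked = ne_ratio_linked_window(inputs.Uw, inputs.sh_mag, inputs.Rw)
    else:
        raise ValueError(f"unknown joint-model variant: {variant!r}")
    return unlinked * linked


def estimate_genomewide_deleterious_rate(
    point_mutation_rate: float = 1.1e-8,
    diploid_genome_size: float = 6e9,
    constrained_fraction: float = 0.55,
    relative_constrained_rate: float = 0.943,
) -> float:
    """Genome-wide diploid deleterious mutation rate U from human-like inputs.

    U = (point mutation rate) x (diploid genome size) x (fraction of the
    genome under selective constraint) x (fraction of mutations in that
    region that are removed by selection, i.e. 1 - the relative
    evolutionary rate of the constrained region).  The defaults give
    U ~ 2.1 new deleterious mutations per diploid per generation.
    """
    for name, v in (
        ("point_mutation_rate", point_mutation_rate),
        ("diploid_genome_size", diploid_genome_size),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    if not 0 < constrained_fraction <= 1:
        raise ValueError("constrained_fraction must be in (0, 1]")
    if not 0 <= relative_constrained_rate <= 1:
        raise ValueError("relative_constrained_rate must be in [0, 1]")
    return (
        point_mutation_rate
        * diploid_genome_size
        * constrained_fraction
        * (1.0 - relative_constrained_rate)
    )
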