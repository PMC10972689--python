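"""Forward-time Wright-Fisher simulation with selection, mutation and recombination.

Each generation, N diploid offspring are produced by sampling two
parents per offspring (independently, with replacement, probability
proportional to multiplicative fitness); each parent transmits one
recombined gamete — per chromosome a random starting strand and exactly
``crossovers_per_chromosome`` crossover points, i.i.d. uniform along the
chromosome — to which new deleterious (Poisson, rate U/2 per gamete) and
neutral (Poisson, per-unit rate x genome length) mutations are added
under the infinite-sites model.

Deleterious and neutral mutations are held in two separate per-haplotype
stores sharing the same crossover realisations, so fitness evaluation
touches only the deleterious store while diversity estimation touches
only the neutral one.  Fixed mutations are purged periodically: a fixed
deleterious mutation multiplies every individual's fitness by the same
constant, so dropping it leaves relative fitness unchanged, and fixed
neutral mutations are divergence rather than diversity.  Populations
start mutation-free and run for 10N generations (the burn-in the
measurement conventions assume).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _kernels
from .genome import DFEModel, GenomeArchitecture, Mutation, draw_effect, sample_positions_global

__all__ = [
    "SimulationParams",
    "Population",
    "Gamete",
    "RunRecord",
    "SimulationError",
    "initialize_population",
    "fitness",
    "draw_gamete",
    "apply_mutations",
    "wright_fisher_generation",
    "run_simulation",
]


class SimulationError(RuntimeError):
    """Raised when the simulation reaches an unusable state."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one forward simulation.

    ``U`` is the diploid genome-wide deleterious mutation rate per
    generation (so Poisson(U/2) new deleterious mutations per gamete);
    ``neutral_mu_per_unit`` is the per-gamete neutral rate per genomic
    unit (1e-4 by default, i.e. 0.23 per haploid genome on the default
    23 x 100-unit architecture).  ``generations`` defaults to 10N.
    """

    N: int
    U: float
    dfe: DFEModel = field(default_factory=DFEModel)
    architecture: GenomeArchitecture = field(default_factory=GenomeArchitecture)
    neutral_mu_per_unit: float = 1e-4
    generations: int | None = None
    seed: int = 0
    purge_every: int = 25

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.U < 0 or self.neutral_mu_per_unit < 0:
            raise ValueError("mutation rates must be >= 0")
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.purge_every < 1:
            raise ValueError("purge_every must be >= 1")

    @property
    def n_generations(self) -> int:
        return 10 * self.N if self.generations is None else self.generations


class Gamete(NamedTuple):
    """One transmitted haploid genome: parallel sorted-by-position arrays."""

    positions: np.ndarray
    effects: np.ndarray
    born: np.ndarray


class _Store:
    """Ragged CSR over 2N haplotypes for one mutation class."""

    __slots__ = ("starts", "counts", "pos", "eff", "born")

    def __init__(self, n_haplotypes: int):
        self.starts = np.zeros(n_haplotypes, dtype=np.int64)
        self.counts = np.zeros(n_haplotypes, dtype=np.int64)
        self.pos = np.empty(0, dtype=np.float64)
        self.eff = np.empty(0, dtype=np.float32)
        self.born = np.empty(0, dtype=np.int32)

    def slice(self, h: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, c = self.starts[h], self.counts[h]
        return self.pos[s : s + c], self.eff[s : s + c], self.born[s : s + c]

    def flat(self):
        """(haplotype id, pos, eff, born) over all entries."""
        total = int(self.counts.sum())
        if total == 0:
            e = np.empty(0)
            return np.empty(0, dtype=np.int64), e, e.copy(), np.empty(0, dtype=np.int64)
        idx = np.concatenate(
            [np.arange(s, s + c) for s, c in zip(self.starts, self.counts) if c]
        )
        hap = np.repeat(np.arange(self.starts.size), self.counts)
        return hap, self.pos[idx], self.eff[idx], self.born[idx]

    def set_from(self, hap_ids, positions, effects, born):
        n_hap = self.starts.size
        order = np.lexsort((positions, hap_ids))
        self.pos = np.ascontiguousarray(positions[order], dtype=np.float64)
        self.eff = np.ascontiguousarray(effects[order], dtype=np.float32)
        self.born = np.ascontiguousarray(born[order], dtype=np.int32)
        self.counts = np.bincount(hap_ids, minlength=n_hap).astype(np.int64)
        self.starts = np.concatenate(([0], np.cumsum(self.counts)[:-1]))

    def purge_shared(self) -> np.ndarray:
        """Remove positions carried by every haplotype; returns them."""
        if self.counts.min() == 0:
            return np.empty(0)
        fixed = _kernels.shared_by_all(self.starts, self.counts, self.pos)
        if fixed.size:
            _kernels.remove_positions(
                self.starts, self.counts, self.pos, self.eff, self.born, fixed
            )
        return fixed


class Population:
    """2N haplotypes grouped into N diploids, with per-haplotype mutation lists.

    Haplotypes ``2i`` and ``2i+1`` form diploid ``i``.  Deleterious and
    neutral mutations live in separate stores (``deleterious``,
    ``neutral``), each a ragged CSR of (position, effect, origin
    generation) triples sorted by position within a haplotype.  A
    mutation is identified by its continuous global position (unique
    under infinite sites); :meth:`registry` assigns snapshot ordinal ids.
    """

    def __init__(
        self,
        N: int,
        architecture: GenomeArchitecture,
        seed: int | None = 0,
        generation: int = 0,
    ):
        if N < 1:
            raise ValueError(f"N must be >= 1, got {N}")
        self.N = N
        self.architecture = architecture
        self.generation = generation
        self.deleterious = _Store(2 * N)
        self.neutral = _Store(2 * N)
        self.n_fixed_deleterious = 0
        self.n_fixed_neutral = 0
        # the single shared deleterious effect, if there is one ("empty"
        # until a deleterious mutation exists, "mixed" once effects vary);
        # lets the generation step use a count-based fitness kernel safely
        self._uniform_eff: float | str = "empty"
        self.reseed(seed)

    # ---- randomness -----------------------------------------------------

    def reseed(self, seed: int | None) -> None:
        """(Re)initialise the named RNG streams from a master seed."""
        ss = np.random.SeedSequence(0 if seed is None else seed)
        kids = ss.spawn(3)
        self.rng_parent = np.random.default_rng(kids[0])
        self.rng_recomb = np.random.default_rng(kids[1])
        self.rng_mutation = np.random.default_rng(kids[2])

    # ---- views ----------------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.N

    def haplotype(self, h: int) -> Gamete:
        """Merged (deleterious + neutral) sorted view of one haplotype."""
        dp, de, db = self.deleterious.slice(h)
        np_, ne, nb = self.neutral.slice(h)
        pos = np.concatenate([dp, np_])
        eff = np.concatenate([de, ne])
        born = np.concatenate([db, nb])
        order = np.argsort(pos, kind="mergesort")
        return Gamete(pos[order], eff[order], born[order])

    def flat_entries(self):
        """All (haplotype id, position, effect, born) entries, both stores."""
        hd, pd_, ed, bd = self.deleterious.flat()
        hn, pn, en, bn = self.neutral.flat()
        return (
            np.concatenate([hd, hn]),
            np.concatenate([pd_, pn]),
            np.concatenate([ed, en]),
            np.concatenate([bd, bn]),
        )

    def deleterious_load(self) -> np.ndarray:
        """Deleterious mutation count per haplotype (length 2N)."""
        return self.deleterious.counts.copy()

    def segregating_summary(self) -> dict:
        """Counts of active segregating mutations by class."""
        n_del = int(np.unique(self.deleterious.pos[_flat_idx(self.deleterious)]).size)
        n_neu = int(np.unique(self.neutral.pos[_flat_idx(self.neutral)]).size)
        return {
            "n_segregating": n_del + n_neu,
            "n_segregating_deleterious": n_del,
            "n_segregating_neutral": n_neu,
        }

    def registry(self) -> dict[int, Mutation]:
        """Snapshot mutation registry: ordinal id -> :class:`Mutation`.

        Ids are ordinals of the position-sorted active mutations; they
        are stable for a given state but not across generations (the
        durable identity of a mutation is its position).
        """
        arch = self.architecture
        _, pos, eff, born = self.flat_entries()
        upos, first = np.unique(pos, return_index=True)
        out = {}
        for i, p in enumerate(upos):
            e = eff[first[i]]
            out[i] = Mutation(
                id=i,
                chromosome=int(p // arch.chromosome_length),
                position=float(p % arch.chromosome_length),
                sh=float(e),
                kind="deleterious" if e < 0 else "neutral",
                origin_generation=int(born[first[i]]),
            )
        return out

    def carrier_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique positions, carrier count) over all active mutations."""
        _, pos, _, _ = self.flat_entries()
        return np.unique(pos, return_counts=True)

    # ---- maintenance -----------------------------------------------------

    def purge_fixed(self) -> tuple[int, int]:
        """Remove mutations carried by every haplotype; returns (#del, #neutral)."""
        n_del = int(self.deleterious.purge_shared().size)
        n_neu = int(self.neutral.purge_shared().size)
        self.n_fixed_deleterious += n_del
        self.n_fixed_neutral += n_neu
        return (n_del, n_neu)

    def check_invariants(self, purged: bool = False) -> None:
        """Raise AssertionError if structural invariants are violated."""
        for store, sign in ((self.deleterious, -1), (self.neutral, 0)):
            assert store.starts.shape == (2 * self.N,)
            assert store.counts.shape == (2 * self.N,)
            for h in range(self.n_haplotypes):
                p, e, _ = store.slice(h)
                if p.size:
                    assert np.all(np.diff(p) > 0), f"haplotype {h} not strictly sorted"
                    assert np.all((p >= 0) & (p < self.architecture.total_length))
                    assert np.all(e < 0) if sign else np.all(e == 0)
        if purged:
            _, cnt = self.carrier_counts()
            assert cnt.size == 0 or (
                cnt.min() >= 1 and cnt.max() <= self.n_haplotypes - 1
            ), "carrier count outside [1, 2N-1] after purging"

    # ---- construction / persistence ---------------------------------------

    @classmethod
    def from_entries(
        cls,
        N: int,
        architecture: GenomeArchitecture,
        hap_ids,
        positions,
        effects,
        born=None,
        seed: int | None = 0,
        generation: int = 0,
    ) -> "Population":
        """Build a population from explicit (haplotype, mutation) entries.

        ``positions`` are global coordinates; entries need not be sorted.
        Entries with a negative effect go to the deleterious store,
        zero-effect entries to the neutral store.
        """
        pop = cls(N, architecture, seed=seed, generation=generation)
        hap_ids = np.asarray(hap_ids, dtype=np.int64)
        positions = np.asarray(positions, dtype=np.float64)
        effects = np.asarray(effects, dtype=np.float64)
        if born is None:
            born = np.zeros(hap_ids.size, dtype=np.int64)
        born = np.asarray(born, dtype=np.int64)
        if np.any((hap_ids < 0) | (hap_ids >= 2 * N)):
            raise ValueError("haplotype id outside [0, 2N)")
        if np.any(effects > 0):
            raise ValueError("effects must be <= 0 (0 marks the neutral class)")
        is_del = effects < 0
        pop.deleterious.set_from(
            hap_ids[is_del], positions[is_del], effects[is_del], born[is_del]
        )
        pop.neutral.set_from(
            hap_ids[~is_del], positions[~is_del], effects[~is_del], born[~is_del]
        )
        uniq = np.unique(pop.deleterious.eff)
        if uniq.size == 1:
            pop._uniform_eff = float(uniq[0])
        elif uniq.size > 1:
            pop._uniform_eff = "mixed"
        return pop

    def to_table(self) -> pd.DataFrame:
        """Line-oriented haplotype-mutation table (the state-file format)."""
        arch = self.architecture
        hap, pos, eff, born = self.flat_entries()
        order = np.lexsort((pos, hap))
        hap, pos, eff, born = hap[order], pos[order], eff[order], born[order]
        upos = np.unique(pos)
        mid = np.searchsorted(upos, pos)
        return pd.DataFrame(
            {
                "haplotype_id": hap,
                "mutation_id": mid,
                "chromosome": (pos // arch.chromosome_length).astype(int),
                "position": pos % arch.chromosome_length,
                "kind": np.where(eff < 0, "deleterious", "neutral"),
                "sh": eff,
                "origin_generation": born,
            }
        )

    def save_state(self, path) -> None:
        # %.17g guarantees byte-exact float round trips; positions are
        # mutation identities, so precision loss would corrupt the state
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load_state(
        cls, path, N: int, architecture: GenomeArchitecture, seed: int | None = 0
    ) -> "Population":
        # positions are identities: parse floats with correct rounding
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        pos = (
            df["chromosome"].to_numpy(dtype=np.float64)
            * architecture.chromosome_length
            + df["position"].to_numpy(dtype=np.float64)
        )
        born = (
            df["origin_generation"].to_numpy(dtype=np.int64)
            if "origin_generation" in df
            else None
        )
        return cls.from_entries(
            N,
            architecture,
            df["haplotype_id"].to_numpy(),
            pos,
            df["sh"].to_numpy(dtype=np.float64),
            born=born,
            seed=seed,
        )


def _flat_idx(store: _Store) -> np.ndarray:
    if store.counts.sum() == 0:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(
        [np.arange(s, s + c) for s, c in zip(store.starts, store.counts) if c]
    )


# ---------------------------------------------------------------------------
# Operations


def initialize_population(params: SimulationParams) -> Population:
    """Mutation-free population of N diploids at generation 0."""
    return Population(params.N, params.architecture, seed=params.seed)


def fitness(pop: Population, dfe: DFEModel | None = None) -> np.ndarray:
    """Absolute multiplicative fitness of each diploid.

    w = prod over heterozygous sites (1 + sh) x prod over homozygous
    sites (1 + sh/h); a mutation-free diploid has w = 1.
    """
    h = dfe.h if dfe is not None else 0.5
    d = pop.deleterious
    logw = np.empty(pop.N)
    _kernels.diploid_log_fitness(d.starts, d.counts, d.pos, d.eff, 1.0 / h, logw)
    if not np.all(np.isfinite(logw)):
        raise SimulationError("non-finite fitness encountered")
    return np.exp(logw)


def _crossover_draws(
    arch: GenomeArchitecture, n_gametes: int, rng: np.random.Generator
):
    """Random crossover coordinates and starting strands for a batch of gametes."""
    c = arch.n_total_chromosomes
    offs = arch.chromosome_offsets
    n_xo = arch.crossovers_per_chromosome
    if n_xo > 2:
        raise NotImplementedError(
            "the engine supports at most 2 crossovers per chromosome"
        )
    if n_xo > 0:
        draws = rng.random((n_gametes, c, n_xo)) * arch.chromosome_length
        draws += offs[None, :, None]
        if n_xo > 1:
            d0 = np.ascontiguousarray(draws[:, :, 0])
            d1 = np.ascontiguousarray(draws[:, :, 1])
            xo_a = np.minimum(d0, d1)
            xo_b = np.maximum(d0, d1)
        else:
            xo_a = np.ascontiguousarray(draws[:, :, 0])
            xo_b = np.full_like(xo_a, np.inf)
    else:
        xo_a = np.full((n_gametes, c), np.inf)
        xo_b = np.full((n_gametes, c), np.inf)
    start = rng.integers(0, 2, size=(n_gametes, c), dtype=np.int64)
    return xo_a, xo_b, start


def _transmit_store(
    store: _Store,
    parents: np.ndarray,
    xo_a,
    xo_b,
    start,
    arch: GenomeArchitecture,
    new_counts,
    new_off,
    new_pos,
    new_eff,
    gen_now: int,
) -> _Store:
    """Run the transmission kernel for one store; returns the offspring store."""
    n_g = parents.size
    ub = store.counts[2 * parents] + store.counts[2 * parents + 1] + new_counts
    out = _Store(n_g)
    out.starts = np.concatenate(([0], np.cumsum(ub)[:-1])).astype(np.int64)
    total = int(ub.sum())
    out.pos = np.empty(total)
    out.eff = np.empty(total, dtype=np.float32)
    out.born = np.empty(total, dtype=np.int32)
    out.counts = np.empty(n_g, dtype=np.int64)
    _kernels.make_offspring(
        store.starts,
        store.counts,
        store.pos,
        store.eff,
        store.born,
        parents,
        xo_a,
        xo_b,
        start,
        arch.chromosome_length,
        arch.n_total_chromosomes,
        new_off,
        new_pos,
        new_eff,
        gen_now,
        out.starts,
        out.pos,
        out.eff,
        out.born,
        out.counts,
    )
    return out


def _sorted_per_gamete(n_gametes, counts, pos, eff):
    """Sort flat new-mutation arrays within each gamete's block."""
    gam = np.repeat(np.arange(n_gametes), counts)
    order = np.lexsort((pos, gam))
    off = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return off, pos[order], eff[order].astype(np.float32)


def _draw_new_deleterious(params, n_gametes, rng):
    if params.U <= 0:
        z = np.zeros(n_gametes, dtype=np.int64)
        return z, np.zeros(n_gametes + 1, dtype=np.int64), np.empty(0), np.empty(0, np.float32)
    n = rng.poisson(params.U / 2.0, n_gametes)
    pos = sample_positions_global(params.architecture, "deleterious", int(n.sum()), rng)
    eff = np.asarray(draw_effect(params.dfe, rng, size=int(n.sum())), dtype=np.float64)
    off, pos, eff = _sorted_per_gamete(n_gametes, n, pos, eff)
    return n.astype(np.int64), off, pos, eff


def _draw_new_neutral(params, n_gametes, rng):
    mu_tot = params.neutral_mu_per_unit * params.architecture.total_length
    if mu_tot <= 0:
        z = np.zeros(n_gametes, dtype=np.int64)
        return z, np.zeros(n_gametes + 1, dtype=np.int64), np.empty(0), np.empty(0, np.float32)
    n = rng.poisson(mu_tot, n_gametes)
    pos = sample_positions_global(params.architecture, "neutral", int(n.sum()), rng)
    eff = np.zeros(pos.size)
    off, pos, eff = _sorted_per_gamete(n_gametes, n, pos, eff)
    return n.astype(np.int64), off, pos, eff


def draw_gamete(
    pop: Population, parent: int, rng: np.random.Generator | None = None
) -> Gamete:
    """One recombined (un-mutated) gamete from diploid ``parent``."""
    if not 0 <= parent < pop.N:
        raise ValueError("parent index out of range")
    rng = pop.rng_recomb if rng is None else rng
    arch = pop.architecture
    xo_a, xo_b, start = _crossover_draws(arch, 1, rng)
    parents = np.array([parent], dtype=np.int64)
    zero = np.zeros(1, dtype=np.int64)
    parts = []
    for store in (pop.deleterious, pop.neutral):
        out = _transmit_store(
            store, parents, xo_a, xo_b, start, arch,
            zero, np.zeros(2, dtype=np.int64), np.empty(0), np.empty(0, np.float32),
            pop.generation,
        )
        parts.append(out.slice(0))
    pos = np.concatenate([parts[0][0], parts[1][0]])
    eff = np.concatenate([parts[0][1], parts[1][1]])
    born = np.concatenate([parts[0][2], parts[1][2]])
    order = np.argsort(pos, kind="mergesort")
    return Gamete(pos[order].copy(), eff[order].copy(), born[order].copy())


def apply_mutations(
    gamete: Gamete,
    params: SimulationParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> Gamete:
    """Add new Poisson-distributed deleterious and neutral mutations to a gamete."""
    _, _, dpos, deff = _draw_new_deleterious(params, 1, rng)
    _, _, npos, neff = _draw_new_neutral(params, 1, rng)
    new_pos = np.concatenate([dpos, npos])
    new_eff = np.concatenate([deff, neff])
    if new_pos.size == 0:
        return gamete
    ins = np.searchsorted(gamete.positions, new_pos)
    return Gamete(
        np.insert(gamete.positions, ins, new_pos),
        np.insert(gamete.effects, ins, new_eff),
        np.insert(gamete.born, ins, generation),
    )


def wright_fisher_generation(pop: Population, params: SimulationParams) -> Population:
    """Advance the population by one Wright-Fisher generation, in place."""
    n = pop.N
    h2 = 2 * n
    arch = params.architecture
    d = pop.deleterious
    logw = np.empty(n)
    dfe = params.dfe
    target = float(np.float32(-dfe.mean_sh_mag))
    # the count-based kernel is only valid when every stored deleterious
    # effect equals the constant DFE's effect
    if dfe.kind == "constant" and pop._uniform_eff in ("empty", target):
        sh = -dfe.mean_sh_mag
        _kernels.diploid_log_fitness_constant(
            d.starts, d.counts, d.pos, np.log1p(sh), np.log1p(sh / dfe.h), logw
        )
    else:
        _kernels.diploid_log_fitness(
            d.starts, d.counts, d.pos, d.eff, 1.0 / dfe.h, logw
        )
    if not np.all(np.isfinite(logw)):
        raise SimulationError(
            "all-zero or non-finite fitness: mutational meltdown guard"
        )
    w = np.exp(logw - logw.max())
    parents = pop.rng_parent.choice(n, size=h2, p=w / w.sum()).astype(np.int64)

    xo_a, xo_b, start = _crossover_draws(arch, h2, pop.rng_recomb)
    dn, doff, dpos, deff = _draw_new_deleterious(params, h2, pop.rng_mutation)
    nn, noff, npos, neff = _draw_new_neutral(params, h2, pop.rng_mutation)

    if dpos.size:
        if dfe.kind == "constant" and pop._uniform_eff in ("empty", target):
            pop._uniform_eff = target
        elif not (pop._uniform_eff == "empty" and np.unique(deff).size == 1):
            pop._uniform_eff = "mixed"
        else:
            pop._uniform_eff = float(deff[0])

    gen_now = pop.generation + 1
    pop.deleterious = _transmit_store(
        pop.deleterious, parents, xo_a, xo_b, start, arch,
        dn, doff, dpos, deff, gen_now,
    )
    pop.neutral = _transmit_store(
        pop.neutral, parents, xo_a, xo_b, start, arch,
        nn, noff, npos, neff, gen_now,
    )
    pop.generation = gen_now
    return pop


@dataclass
class RunRecord:
    """Provenance of one simulation run."""

    params: dict
    seed: int
    generations: int
    runtime_seconds: float
    n_fixed_deleterious: int
    n_fixed_neutral: int
    log: list = field(default_factory=list)


def run_simulation(
    params: SimulationParams, log_every: int = 1000
) -> tuple[Population, RunRecord]:
    """Run the forward simulation for ``params.n_generations`` generations.

    Fixed mutations are purged every ``params.purge_every`` generations
    and at the end, so the returned population carries only segregating
    mutations.  The provenance record logs mean log-fitness and
    segregating-site counts every ``log_every`` generations.
    """
    t0 = time.perf_counter()
    pop = initialize_population(params)
    gens = params.n_generations
    log: list[dict] = []
    for t in range(1, gens + 1):
        wright_fisher_generation(pop, params)
        if t % params.purge_every == 0:
            pop.purge_fixed()
        if log_every and t % log_every == 0:
            logw = np.log(fitness(pop, params.dfe))
            entry = {"generation": t, "mean_log_fitness": float(logw.mean())}
            entry.update(pop.segregating_summary())
            log.append(entry)
    pop.purge_fixed()
    record = RunRecord(
        params={
            "N": params.N,
            "U": params.U,
            "dfe_kind": params.dfe.kind,
            "mean_sh": -params.dfe.mean_sh_mag,
            "dfe_shape": params.dfe.shape,
            "h": params.dfe.h,
            "deleterious_mode": params.architecture.deleterious_mode,
            "has_neutral_chromosome": params.architecture.has_neutral_chromosome,
            "neutral_mu_per_unit": params.neutral_mu_per_unit,
        },
        seed=params.seed,
        generations=gens,
        runtime_seconds=time.perf_counter() - t0,
        n_fixed_deleterious=pop.n_fixed_deleterious,
        n_fixed_neutral=pop.n_fixed_neutral,
        log=log,
    )
    return pop, record
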