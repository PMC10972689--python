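"""Parameter sweeps, run summaries, and hand-built fixture populations.

``run_sweep`` drives grids over the deleterious rate U, the selection
coefficient sh, the census size N and the genome mode, one CSV row per
(cell, replicate), with a deterministic cell-to-seed mapping so a sweep
is reproducible bit for bit from its spec.  ``compare_to_theory`` joins
the closed-form linked / unlinked / joint Ne/N predictions onto a sweep
table.  ``make_fixture`` builds tiny explicit populations whose
diversity and dispersion statistics are known in closed form at
construction, used to pin the estimators exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import dispersion_from_counts
from .diversity import regional_ne_report
from .engine import Population, RunRecord, SimulationParams, run_simulation
from .genome import DFEModel, GenomeArchitecture
from .theory import TheoryInputs, ne_ratio_joint, ne_ratio_linked, ne_ratio_unlinked

__all__ = [
    "SweepSpec",
    "FixturePopulation",
    "run_sweep",
    "summarize_run",
    "compare_to_theory",
    "make_fixture",
    "plot_sweep",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a simulation sweep.

    Cells are the cross product of the grids; replicate ``r`` of cell
    ``i`` runs with seed ``base_seed + i * replicates + r``.  ``scale``
    divides every N in the grid (desk-scale runs); generations remain
    10x the scaled N unless ``generations`` is set.
    """

    U_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 4.0)
    sh_grid: tuple[float, ...] = (-0.01,)
    N_grid: tuple[int, ...] = (500,)
    modes: tuple[str, ...] = ("uniform",)
    dfe_kinds: tuple[str, ...] = ("constant",)
    neutral_chromosome: bool = False
    replicates: int = 1
    base_seed: int = 0
    scale: int = 1
    generations: int | None = None
    neutral_mu_per_unit: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("U_grid", "sh_grid", "N_grid", "modes", "dfe_kinds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def cells(self):
        """Yield (cell index, params dict) over the grid cross product."""
        i = 0
        for n in self.N_grid:
            for u in self.U_grid:
                for sh in self.sh_grid:
                    for mode in self.modes:
                        for kind in self.dfe_kinds:
                            yield i, {
                                "N": max(2, n // self.scale),
                                "U": u,
                                "sh": sh,
                                "mode": mode,
                                "dfe": kind,
                            }
                            i += 1

    def params_for(self, cell: dict, seed: int) -> SimulationParams:
        arch = GenomeArchitecture(
            deleterious_mode=cell["mode"],
            has_neutral_chromosome=self.neutral_chromosome,
        )
        dfe = DFEModel(kind=cell["dfe"], mean_sh_mag=abs(cell["sh"]))
        return SimulationParams(
            N=cell["N"],
            U=cell["U"],
            dfe=dfe,
            architecture=arch,
            neutral_mu_per_unit=self.neutral_mu_per_unit,
            generations=self.generations,
            seed=seed,
        )


def summarize_run(
    pop: Population, params: SimulationParams, record: RunRecord | None = None
) -> dict:
    """One result row for a finished simulation."""
    arch = params.architecture
    est = {
        e.region: e
        for e in regional_ne_report(
            pop, params.N, neutral_mu_per_unit=params.neutral_mu_per_unit
        )
    }
    whole = est["whole"]
    load = pop.deleterious_load()
    try:
        disp = dispersion_from_counts(load).index
    except ValueError:
        disp = np.nan
    seg = pop.segregating_summary()
    return {
        "N": params.N,
        "U": params.U,
        "sh": -params.dfe.mean_sh_mag,
        "dfe": params.dfe.kind,
        "mode": arch.deleterious_mode,
        "seed": params.seed,
        "generations": params.n_generations,
        "theta_whole": whole.theta,
        "Ne_whole": whole.Ne,
        "Ne_over_N": whole.Ne_over_N,
        "theta_genic": est["genic"].theta if "genic" in est else np.nan,
        "theta_intergenic": est["intergenic"].theta if "intergenic" in est else np.nan,
        "theta_neutral_chrom": (
            est["neutral_chromosome"].theta if "neutral_chromosome" in est else np.nan
        ),
        "dispersion_index": disp,
        "mean_deleterious_load": float(load.mean()),
        "n_segregating_deleterious": seg["n_segregating_deleterious"],
        "n_fixed_deleterious": pop.n_fixed_deleterious,
    }


def run_sweep(
    spec: SweepSpec, out_csv: str | Path | None = None, progress: bool = False
) -> pd.DataFrame:
    """Run every (cell, replicate) of a sweep; one summary row each.

    If ``out_csv`` exists, rows already present (matched on the cell
    parameters and seed) are skipped and the new rows appended, so an
    interrupted sweep can resume.  A failing cell is logged into the
    ``error`` column and does not abort the sweep.
    """
    done: set[tuple] = set()
    prior: pd.DataFrame | None = None
    if out_csv is not None and Path(out_csv).exists():
        prior = pd.read_csv(out_csv)
        done = {
            (r.N, r.U, r.sh, r.mode, r.dfe, r.seed) for r in prior.itertuples()
        }
    rows = []
    for i, cell in spec.cells():
        for r in range(spec.replicates):
            seed = spec.base_seed + i * spec.replicates + r
            params = spec.params_for(cell, seed)
            key = (params.N, params.U, -params.dfe.mean_sh_mag,
                   cell["mode"], cell["dfe"], seed)
            if key in done:
                continue
            if progress:
                print(f"cell {i} replicate {r}: {cell} seed={seed}", flush=True)
            try:
                pop, record = run_simulation(params)
                row = summarize_run(pop, params, record)
                row["replicate"] = r
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - partial failure is logged
                row = {**cell, "seed": seed, "replicate": r, "error": str(exc)}
            rows.append(row)
    df = pd.DataFrame(rows)
    if prior is not None:
        df = pd.concat([prior, df], ignore_index=True)
    if out_csv is not None and len(df):
        df.to_csv(out_csv, index=False)
    return df


def compare_to_theory(
    df: pd.DataFrame, total_map_length: float = 46.0, n_windows: int = 20_000
) -> pd.DataFrame:
    """Join linked/unlinked/joint Ne/N predictions and residuals onto a sweep table."""
    out = df.copy()
    linked, unlinked, joint = [], [], []
    for r in out.itertuples():
        sh_mag = abs(r.sh)
        if r.U == 0:
            linked.append(1.0)
            unlinked.append(1.0)
            joint.append(1.0)
            continue
        ti = TheoryInputs(
            U=r.U,
            sh_mag=sh_mag,
            total_map_length=total_map_length,
            n_windows=n_windows,
        )
        linked.append(ne_ratio_linked(ti.u_over_r))
        unlinked.append(ne_ratio_unlinked(r.U, sh_mag))
        joint.append(ne_ratio_joint(ti))
    out["linked_ratio"] = linked
    out["unlinked_ratio"] = unlinked
    out["joint_ratio"] = joint
    if "Ne_over_N" in out:
        out["residual"] = out["Ne_over_N"] - out["joint_ratio"]
    return out


# ---------------------------------------------------------------------------
# Fixture populations


@dataclass(frozen=True)
class FixturePopulation:
    """A tiny hand-built population with closed-form expected statistics."""

    population: Population
    expected: dict


def make_fixture(kind: str, **kwargs) -> FixturePopulation:
    """Deterministic fixture populations for estimator tests.

    ``two_allele_locus``  — 2N=4 haplotypes split 2/2 between two neutral
    alleles at one infinite-alleles locus; locus heterozygosity
    (4/3)*0.5 = 2/3.

    ``equal_loads(count)`` — every haplotype carries ``count`` private
    deleterious mutations; dispersion index 0.

    ``poisson_loads(lam, two_n, seed)`` — per-haplotype deleterious
    counts drawn i.i.d. Poisson(lam); the stored expectation is the
    exact two-pass variance/mean of the drawn counts (close to 1).

    ``regional`` — genic-mode architecture with a neutral chromosome;
    one neutral site at frequency 1/2 inside a gene, one intergenic and
    one on the neutral chromosome; per-region infinite-sites theta
    known in closed form.
    """
    if kind == "two_allele_locus":
        from .diversity import DEFAULT_LOCUS_LENGTH

        arch = GenomeArchitecture()
        ll = DEFAULT_LOCUS_LENGTH
        pop = Population.from_entries(
            N=2,
            architecture=arch,
            hap_ids=[0, 1, 2, 3],
            # both alleles inside the first locus
            positions=[0.25 * ll, 0.25 * ll, 0.75 * ll, 0.75 * ll],
            effects=[0.0, 0.0, 0.0, 0.0],
        )
        h = (4 / 3) * (1 - 2 * 0.25)
        n_loci = round(arch.core_length / ll)
        return FixturePopulation(
            pop,
            {
                "unit_heterozygosity_locus0": h,
                "unit_heterozygosity_whole": h / n_loci,
            },
        )
    if kind == "equal_loads":
        count = int(kwargs.get("count", 3))
        two_n = int(kwargs.get("two_n", 6))
        arch = GenomeArchitecture()
        hap_ids = np.repeat(np.arange(two_n), count)
        # private positions, spread across the core genome
        positions = np.linspace(0.5, arch.core_length - 0.5, two_n * count)
        pop = Population.from_entries(
            N=two_n // 2,
            architecture=arch,
            hap_ids=hap_ids,
            positions=positions,
            effects=np.full(two_n * count, -0.01),
        )
        return FixturePopulation(
            pop, {"dispersion_index": 0.0, "mean_count": float(count)}
        )
    if kind == "poisson_loads":
        lam = float(kwargs.get("lam", 5.0))
        two_n = int(kwargs.get("two_n", 10_000))
        seed = int(kwargs.get("seed", 0))
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam, two_n)
        arch = GenomeArchitecture()
        hap_ids = np.repeat(np.arange(two_n), counts)
        positions = rng.uniform(0, arch.core_length, int(counts.sum()))
        pop = Population.from_entries(
            N=two_n // 2,
            architecture=arch,
            hap_ids=hap_ids,
            positions=positions,
            effects=np.full(int(counts.sum()), -0.01),
        )
        mean = counts.mean()
        var = counts.var(ddof=1)
        return FixturePopulation(
            pop,
            {
                "dispersion_index": float(var / mean),
                "mean_count": float(mean),
                "poisson_lambda": lam,
            },
        )
    if kind == "regional":
        arch = GenomeArchitecture(
            deleterious_mode="genic", has_neutral_chromosome=True
        )
        starts, lengths = arch.gene_intervals()
        genic_pos = starts[0] + lengths[0] / 2.0
        intergenic_pos = starts[0] + 2 * lengths[0]  # past gene 0, before gene 1
        neutral_pos = arch.core_length + 50.0
        two_n = 4
        hap_ids = [0, 1, 0, 1, 0, 1]
        positions = [genic_pos] * 2 + [intergenic_pos] * 2 + [neutral_pos] * 2
        pop = Population.from_entries(
            N=2,
            architecture=arch,
            hap_ids=hap_ids,
            positions=positions,
            effects=[0.0] * 6,
        )
        corr = two_n / (two_n - 1)
        site_h = corr * 2 * 0.5 * 0.5  # one site at p = 1/2
        genic_len = float(lengths.sum())
        return FixturePopulation(
            pop,
            {
                "theta_genic": site_h / genic_len,
                "theta_intergenic": site_h / (arch.core_length - genic_len),
                "theta_neutral_chromosome": site_h / arch.chromosome_length,
            },
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def plot_sweep(df: pd.DataFrame, out_path: str | Path | None = None):
    """Ne/N against U, simulations as points and model curves as lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    annotated = compare_to_theory(df)
    for sh, sub in annotated.groupby("sh"):
        sub = sub.sort_values("U")
        ax.plot(sub["U"], sub["Ne_over_N"], "o", label=f"simulated, sh={sh}")
        ax.plot(sub["U"], sub["linked_ratio"], "-", color="gray", alpha=0.7)
        ax.plot(sub["U"], sub["unlinked_ratio"], "--", color="gray", alpha=0.7)
        ax.plot(sub["U"], sub["joint_ratio"], "-.", color="black", alpha=0.9)
    ax.set_xlabel("genome-wide deleterious rate U")
    ax.set_ylabel("Ne / N")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
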