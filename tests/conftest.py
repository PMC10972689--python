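"""Shared fixtures.

The heavy session-scoped fixtures run the scaled study conditions once
and are shared across test modules: equilibrium requires 10N
generations of forward simulation, so these are minutes, not seconds.
"""

import numpy as np
import pytest

from bgsel import (
    DFEModel,
    GenomeArchitecture,
    SimulationParams,
    ne_from_theta_infinite_alleles,
    replicate_dispersion,
    run_simulation,
    unit_heterozygosity,
)
from bgsel.diversity import DEFAULT_LOCUS_LENGTH, regional_ne_report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def arch_default():
    return GenomeArchitecture()


@pytest.fixture
def arch_genic():
    return GenomeArchitecture(deleterious_mode="genic")


def _whole_genome_ne_over_n(pop, n):
    theta = unit_heterozygosity(pop, "whole")
    return ne_from_theta_infinite_alleles(theta, 1e-4 * DEFAULT_LOCUS_LENGTH) / n


@pytest.fixture(scope="session")
def u4_dispersion_replicates():
    """Ten scaled replicates of the high-rate regime: N=500, U=4, sh=-0.01.

    Neutral mutations never touch fitness, parent sampling or
    deleterious transmission (independent RNG streams), so the
    deleterious-load distribution is unaffected by switching neutral
    bookkeeping off; these load-only replicates run without it.
    """
    params = SimulationParams(N=500, U=4.0, neutral_mu_per_unit=0.0, seed=9000)
    return replicate_dispersion(params, 10)


@pytest.fixture(scope="session")
def u1_effective_sel_replicates():
    """Three replicates at U=1 with effective selection (2N*sh=50).

    sh=-0.05 keeps 2N*sh at full-scale strength; with the default
    sh=-0.01 at N=500, weakly selected sites drift to appreciable
    frequencies and depress the index below 1 even at low U, which
    would confound the independence-regime check.
    """
    params = SimulationParams(
        N=500,
        U=1.0,
        dfe=DFEModel(mean_sh_mag=0.05),
        neutral_mu_per_unit=0.0,
        seed=9100,
    )
    return replicate_dispersion(params, 3)


@pytest.fixture(scope="session")
def low_u_effective_sel_replicates():
    """Three replicates of the independence regime U=0.1, 2N*sh=50."""
    params = SimulationParams(
        N=500,
        U=0.1,
        dfe=DFEModel(mean_sh_mag=0.05),
        neutral_mu_per_unit=0.0,
        seed=9200,
    )
    return replicate_dispersion(params, 3)


@pytest.fixture(scope="session")
def neutral_calibration_ne():
    """Whole-genome Ne estimates from 20 neutral (U=0) runs at N=50.

    The calibration that pins all rate conventions: with selection off,
    the inferred Ne must recover the census size.
    """
    out = []
    for r in range(20):
        params = SimulationParams(N=50, U=0.0, seed=9300 + r)
        pop, _ = run_simulation(params, log_every=0)
        out.append(_whole_genome_ne_over_n(pop, 50) * 50)
    return np.array(out)


@pytest.fixture(scope="session")
def n_independence_runs():
    """Whole-genome Ne/N at U=2, sh=-0.01 for N=500 (x3) and N=1000 (x1)."""
    out = {}
    for n, reps, base in [(500, 3, 9400), (1000, 1, 9500)]:
        vals = []
        for r in range(reps):
            params = SimulationParams(N=n, U=2.0, seed=base + r)
            pop, _ = run_simulation(params, log_every=0)
            vals.append(_whole_genome_ne_over_n(pop, n))
        out[n] = np.array(vals)
    return out


@pytest.fixture(scope="session")
def genic_regional_runs():
    """Genic-mode replicates (N=250, U=2) with a neutral chromosome."""
    arch = GenomeArchitecture(deleterious_mode="genic", has_neutral_chromosome=True)
    rows = []
    for r in range(2):
        params = SimulationParams(N=250, U=2.0, architecture=arch, seed=9600 + r)
        pop, _ = run_simulation(params, log_every=0)
        rows.append({e.region: e for e in regional_ne_report(pop, 250)})
    return rows
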