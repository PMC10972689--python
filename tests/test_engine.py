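"""Wright-Fisher engine: structure, determinism, and stochastic oracles."""

import numpy as np
import pytest

from bgsel.engine import (
    Population,
    SimulationParams,
    apply_mutations,
    draw_gamete,
    fitness,
    initialize_population,
    run_simulation,
    wright_fisher_generation,
)
from bgsel.genome import DFEModel, GenomeArchitecture


def _neutral_free_params(n, seed=0, generations=10):
    return SimulationParams(
        N=n, U=0.0, neutral_mu_per_unit=0.0, generations=generations, seed=seed
    )


class TestInitialization:
    def test_empty_population(self):
        params = SimulationParams(N=10, U=1.0, seed=1)
        pop = initialize_population(params)
        assert pop.N == 10
        assert pop.n_haplotypes == 20
        assert all(pop.haplotype(h).positions.size == 0 for h in range(20))
        assert pop.generation == 0

    def test_invalid_census(self):
        with pytest.raises(ValueError):
            SimulationParams(N=0, U=1.0)
        with pytest.raises(ValueError):
            SimulationParams(N=1, U=1.0)

    def test_determinism_same_seed_same_state(self):
        params = SimulationParams(N=20, U=1.0, generations=50, seed=77)
        pop1, _ = run_simulation(params, log_every=0)
        pop2, _ = run_simulation(params, log_every=0)
        assert pop1.to_table().equals(pop2.to_table())

    def test_different_seeds_differ(self):
        p1 = SimulationParams(N=20, U=1.0, generations=50, seed=1)
        p2 = SimulationParams(N=20, U=1.0, generations=50, seed=2)
        pop1, _ = run_simulation(p1, log_every=0)
        pop2, _ = run_simulation(p2, log_every=0)
        assert not pop1.to_table().equals(pop2.to_table())


class TestFitness:
    """Multiplicative fitness against enumeration oracles on explicit diploids."""

    @pytest.mark.parametrize(
        "hapA, hapB, expected",
        [
            ([], [], 1.0),
            ([10.0], [], 0.99),  # one heterozygous site, sh = -0.01
            ([10.0], [10.0], 0.98),  # one homozygous site: 1 + 2*sh
            ([10.0, 20.0], [], 0.99 * 0.99),  # two heterozygous sites
            ([10.0], [20.0], 0.99 * 0.99),
            ([10.0, 30.0], [10.0, 40.0], 0.98 * 0.99 * 0.99),
        ],
    )
    def test_enumeration_oracle(self, arch_default, hapA, hapB, expected):
        entries_h = [0] * len(hapA) + [1] * len(hapB)
        entries_p = list(hapA) + list(hapB)
        pop = Population.from_entries(
            N=2,
            architecture=arch_default,
            hap_ids=entries_h + [2, 3][:0],
            positions=entries_p,
            effects=[-0.01] * len(entries_p),
        )
        w = fitness(pop, DFEModel(mean_sh_mag=0.01))
        assert w[0] == pytest.approx(expected, rel=1e-6)
        assert w[1] == 1.0  # untouched diploid

    def test_constant_fast_path_matches_general_kernel(self, arch_default):
        # one WF step under the constant DFE uses a count-based fitness
        # kernel; it must agree with the general per-effect kernel
        from bgsel import _kernels

        params = SimulationParams(N=40, U=3.0, generations=120, seed=17)
        pop, _ = run_simulation(params, log_every=0)
        d = pop.deleterious
        general = np.empty(pop.N)
        _kernels.diploid_log_fitness(d.starts, d.counts, d.pos, d.eff, 2.0, general)
        const = np.empty(pop.N)
        _kernels.diploid_log_fitness_constant(
            d.starts, d.counts, d.pos, np.log1p(-0.01), np.log1p(-0.02), const
        )
        np.testing.assert_allclose(const, general, rtol=1e-4)

    def test_general_kernel_matches_python_product(self, arch_default, rng):
        # random mixed-effect diploid, brute-force product oracle
        effs = -rng.uniform(0.001, 0.3, size=12)
        posA = rng.uniform(0, 2300, 8)
        posB = np.concatenate([posA[:4], rng.uniform(0, 2300, 4)])
        hap_ids = [0] * 8 + [1] * 8
        pos = np.concatenate([posA, posB])
        eff_map = dict(zip(pos[:8], effs[:8]))
        for p, e in zip(pos[8:], effs[4:]):
            eff_map.setdefault(p, e)
        eff = np.array([eff_map[p] for p in pos])
        pop = Population.from_entries(
            N=1, architecture=arch_default, hap_ids=hap_ids, positions=pos, effects=eff
        )
        shared = set(posA) & set(posB)
        w_expect = 1.0
        for p in set(pos):
            e = np.float32(eff_map[p])  # engine stores effects in float32
            w_expect *= (1 + 2 * e) if p in shared else (1 + e)
        w = fitness(pop, DFEModel(kind="gamma"))
        assert w[0] == pytest.approx(w_expect, rel=1e-5)


class TestRecombination:
    def _marker_parent(self, arch, n_markers=120):
        """Diploid 0 with dense neutral markers on chromosome 0 of haplotype 0."""
        pos = np.linspace(0.2, 99.8, n_markers)
        return Population.from_entries(
            N=2,
            architecture=arch,
            hap_ids=[0] * n_markers,
            positions=pos,
            effects=[0.0] * n_markers,
            seed=5,
        )

    def test_two_strand_switches_at_most(self, arch_default):
        pop = self._marker_parent(arch_default)
        markers = np.linspace(0.2, 99.8, 120)
        for _ in range(50):
            g = draw_gamete(pop, 0)
            present = np.isin(markers, g.positions)
            switches = int(np.sum(present[1:] != present[:-1]))
            assert switches <= 2

    def test_homozygous_parent_transmits_identically(self, arch_default):
        pos = np.sort(np.random.default_rng(3).uniform(0, 2300, 40))
        pop = Population.from_entries(
            N=2,
            architecture=arch_default,
            hap_ids=[0] * 40 + [1] * 40,
            positions=np.concatenate([pos, pos]),
            effects=[0.0] * 80,
            seed=6,
        )
        g = draw_gamete(pop, 0)
        assert np.array_equal(g.positions, pos)

    def test_start_strand_is_fair_coin(self, arch_default):
        # first marker sits at the chromosome start; inheriting it means the
        # gamete started on haplotype 0 for that chromosome
        pop = Population.from_entries(
            N=2,
            architecture=arch_default,
            hap_ids=[0],
            positions=[1e-6],
            effects=[0.0],
            seed=7,
        )
        n = 4000
        hits = sum(draw_gamete(pop, 0).positions.size for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se


class TestMutationInflux:
    def test_no_rates_no_change(self, arch_default, rng):
        params = _neutral_free_params(5)
        pop = initialize_population(SimulationParams(N=5, U=1.0, seed=1))
        g = draw_gamete(pop, 0)
        g2 = apply_mutations(g, params, rng)
        assert g2.positions.size == 0

    def test_poisson_rates(self, arch_default, rng):
        params = SimulationParams(N=5, U=2.0, seed=1)
        pop = initialize_population(params)
        g = draw_gamete(pop, 0)
        n_reps = 4000
        n_del = np.empty(n_reps)
        n_neu = np.empty(n_reps)
        for i in range(n_reps):
            g2 = apply_mutations(g, params, rng)
            n_del[i] = np.sum(g2.effects < 0)
            n_neu[i] = np.sum(g2.effects == 0)
        # deleterious: Poisson(U/2 = 1) per gamete
        assert abs(n_del.mean() - 1.0) < 3 * np.sqrt(1.0 / n_reps)
        # neutral: 1e-4 per unit x 2300 units = 0.23 per gamete
        assert abs(n_neu.mean() - 0.23) < 3 * np.sqrt(0.23 / n_reps)

    def test_new_mutations_keep_gamete_sorted(self, arch_default, rng):
        params = SimulationParams(N=5, U=20.0, seed=1)
        pop = initialize_population(params)
        g = apply_mutations(draw_gamete(pop, 0), params, rng)
        assert np.all(np.diff(g.positions) > 0)


class TestGenerationStep:
    def test_census_is_conserved(self):
        params = SimulationParams(N=30, U=1.0, generations=20, seed=3)
        pop, _ = run_simulation(params, log_every=0)
        assert pop.N == 30
        assert pop.deleterious.counts.size == 60
        pop.check_invariants(purged=True)

    def test_neutral_population_stays_empty(self):
        params = _neutral_free_params(10, generations=30)
        pop, _ = run_simulation(params, log_every=0)
        assert pop.carrier_counts()[0].size == 0

    def test_selection_limit_single_fit_parent(self, arch_default):
        # every diploid except the first is loaded with near-lethal mutations
        n = 10
        bad = []
        for d in range(1, n):
            for h in (2 * d, 2 * d + 1):
                # three homozygous near-lethal sites: w = 0.002^3 per diploid
                for base in (100.0, 200.0, 300.0):
                    bad.append((h, base + d))
        hap_ids = [h for h, _ in bad]
        positions = [p for _, p in bad]
        pop = Population.from_entries(
            N=n,
            architecture=arch_default,
            hap_ids=hap_ids,
            positions=positions,
            effects=[-0.499] * len(bad),
            seed=11,
        )
        params = _neutral_free_params(n, generations=1)
        wright_fisher_generation(pop, params)
        # all offspring descend from diploid 0, which carries nothing
        assert int(pop.deleterious.counts.sum()) == 0

    def test_neutral_fixation_probability_matches_initial_frequency(self):
        # 50/50 standing neutral variant: fixation probability 1/2
        n, reps = 30, 400
        fixed = 0
        for r in range(reps):
            pop = Population.from_entries(
                N=n,
                architecture=GenomeArchitecture(),
                hap_ids=list(range(n)),  # haplotypes 0..N-1 of 2N carry it
                positions=[0.5] * n,
                effects=[0.0] * n,
                seed=50_000 + r,
            )
            params = _neutral_free_params(n, generations=1)
            while True:
                wright_fisher_generation(pop, params)
                c = int(pop.neutral.counts.sum())
                if c == 0:
                    break
                if c == 2 * n:
                    fixed += 1
                    break
        se = np.sqrt(0.25 / reps)
        assert abs(fixed / reps - 0.5) < 3 * se

    def test_load_reaches_stationarity_within_burn_in(self):
        # scaled run: mean deleterious load stabilises well inside 10N generations
        params = SimulationParams(N=200, U=2.0, seed=21)
        pop = initialize_population(params)
        means = []
        for t in range(params.n_generations):
            wright_fisher_generation(pop, params)
            if t % params.purge_every == 0:
                pop.purge_fixed()
            if t % 50 == 0:
                means.append(pop.deleterious_load().mean())
        q = len(means) // 4
        last, prev = np.mean(means[-q:]), np.mean(means[-2 * q : -q])
        assert abs(last - prev) / last < 0.1

    def test_run_records_provenance(self):
        params = SimulationParams(N=20, U=1.0, generations=60, seed=4)
        pop, rec = run_simulation(params, log_every=30)
        assert rec.generations == 60
        assert len(rec.log) == 2
        assert rec.params["U"] == 1.0
        assert {"generation", "mean_log_fitness", "n_segregating"} <= set(
            rec.log[0]
        )


class TestStateRoundTrip:
    def test_table_round_trip(self, tmp_path):
        params = SimulationParams(N=15, U=1.5, generations=80, seed=8)
        pop, _ = run_simulation(params, log_every=0)
        path = tmp_path / "state.tsv"
        pop.save_state(path)
        pop2 = Population.load_state(path, N=15, architecture=params.architecture)
        assert pop.to_table().drop(columns="sh").equals(
            pop2.to_table().drop(columns="sh")
        )
        np.testing.assert_allclose(
            pop.to_table()["sh"], pop2.to_table()["sh"], rtol=1e-6
        )

    def test_registry_view(self, arch_default):
        pop = Population.from_entries(
            N=2,
            architecture=arch_default,
            hap_ids=[0, 1, 2],
            positions=[150.5, 150.5, 7.25],
            effects=[-0.02, -0.02, 0.0],
            born=[3, 3, 5],
        )
        reg = pop.registry()
        assert len(reg) == 2
        kinds = {m.kind for m in reg.values()}
        assert kinds == {"deleterious", "neutral"}
        m = [m for m in reg.values() if m.kind == "deleterious"][0]
        assert m.chromosome == 1
        assert m.position == pytest.approx(50.5)
        assert m.origin_generation == 3
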