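import numpy as np
import pytest
from scipy import stats

from guildsim import (
    Agent,
    EpochConfig,
    Genotype,
    MovementParams,
    MutationSchedule,
    Ploidy,
    ReproductionMode,
    mutate_value,
    mutation_scale,
    reproduce_averaging,
    reproduce_clonal,
    reproduce_diploid,
    run_epoch,
    select_fittest,
)
from guildsim.analysis import genotype_counts, hw_expected_counts


def haploid(i, alpha, delta, rho, biomass=0.0):
    return Agent(i, -1, biomass, MovementParams(alpha, delta, rho),
                 Genotype(Ploidy.HAPLOID, values=np.array([alpha, delta, rho])))


def diploid(i, alleles, tags):
    g = Genotype(Ploidy.DIPLOID, alleles=np.asarray(alleles, dtype=float),
                 tags=np.asarray(tags, dtype=np.int64))
    return Agent(i, -1, 0.0, g.phenotype(), g)


class TestMutationSchedule:
    def test_initial_value_is_mu0(self):
        assert mutation_scale(0, MutationSchedule()) == pytest.approx(0.1)

    def test_halfway_at_psi(self):
        # mu(psi) = (mu0 - mu_inf) / 2 + mu_inf
        assert mutation_scale(50, MutationSchedule()) == pytest.approx(0.0505)

    def test_hand_value_at_100(self):
        assert mutation_scale(100, MutationSchedule()) == pytest.approx(0.099 / 9 + 0.001)

    def test_asymptote_is_mu_inf(self):
        assert mutation_scale(1e9, MutationSchedule()) == pytest.approx(0.001)

    def test_strictly_decreasing_and_bounded(self):
        sched = MutationSchedule()
        T = np.arange(0, 500)
        mu = np.array([mutation_scale(t, sched) for t in T])
        assert (np.diff(mu) < 0).all()
        assert mu[0] == 0.1 and (mu > 0.001).all()

    def test_negative_generation_rejected(self):
        with pytest.raises(ValueError):
            mutation_scale(-1, MutationSchedule())

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            MutationSchedule(mu0=0.001, mu_inf=0.1)
        with pytest.raises(ValueError):
            MutationSchedule(psi=0)


class TestSelection:
    def test_fittest_half_by_biomass(self):
        agents = [haploid(i, 0, 0, 0.5, biomass=b) for i, b in enumerate([5, 3, 2, 1])]
        parents = select_fittest(agents)
        assert [p.biomass for p in parents] == [5, 3]

    def test_ties_broken_by_id(self):
        agents = [haploid(i, 0, 0, 0.5, biomass=1.0) for i in range(4)]
        assert [p.id for p in select_fittest(agents)] == [0, 1]

    def test_nan_fitness_is_an_error(self):
        agents = [haploid(0, 0, 0, 0.5, biomass=float("nan")),
                  haploid(1, 0, 0, 0.5, biomass=1.0)]
        with pytest.raises(ValueError):
            select_fittest(agents)

    def test_empty_population_is_an_error(self):
        with pytest.raises(ValueError):
            select_fittest([])


class TestMutateValue:
    def test_zero_scale_is_identity(self, rng):
        assert mutate_value(0.42, 0.0, rng) == 0.42

    def test_bounded_perturbation(self, rng):
        for _ in range(500):
            assert 0.4 <= mutate_value(0.5, 0.1, rng) <= 0.6

    def test_unbiased(self):
        rng = np.random.default_rng(8)
        draws = np.array([mutate_value(0.0, 0.1, rng) for _ in range(100_000)])
        se = (0.1 / np.sqrt(3)) / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se


class TestReproduceClonal:
    def test_exact_cloning_without_mutation(self, rng):
        sched = MutationSchedule(mu0=1e-12, mu_inf=1e-13)
        parents = [haploid(i, 0.1 * i, 0.2, 0.5) for i in range(4)]
        children = reproduce_clonal(parents, 1, sched, rng)
        assert len(children) == 8
        triples = sorted((a.phenotype.alpha, a.phenotype.delta, a.phenotype.rho)
                         for a in children)
        expected = sorted([(0.1 * i, 0.2, 0.5) for i in range(4)] * 2)
        assert np.allclose(triples, expected, atol=1e-11)

    def test_clones_stay_within_mutation_bound(self):
        rng = np.random.default_rng(3)
        sched = MutationSchedule()
        parents = [haploid(i, 0.5, 0.5, 0.5) for i in range(4)]
        for T in (1, 50, 150):
            mu = mutation_scale(T, sched)
            for _ in range(100):
                children = reproduce_clonal(parents, T, sched, rng)
                for child in children[4:]:
                    for trait in ("alpha", "delta", "rho"):
                        assert abs(getattr(child.phenotype, trait) - 0.5) <= mu

    def test_parents_carried_unchanged(self, rng):
        parents = [haploid(i, 0.3, 0.4, 0.5) for i in range(2)]
        children = reproduce_clonal(parents, 5, MutationSchedule(), rng)
        for child in children[:2]:
            assert (child.phenotype.alpha, child.phenotype.delta,
                    child.phenotype.rho) == (0.3, 0.4, 0.5)


class TestReproduceAveraging:
    def test_identical_parents_are_a_fixed_point(self, rng):
        sched = MutationSchedule(mu0=1e-12, mu_inf=1e-13)
        parents = [haploid(i, 0.3, 0.4, 0.5) for i in range(4)]
        children = reproduce_averaging(parents, 1, sched, rng)
        assert len(children) == 8
        for c in children:
            assert c.phenotype.rho == pytest.approx(0.5, abs=1e-11)

    def test_progeny_traits_are_parental_means(self, rng):
        sched = MutationSchedule(mu0=1e-12, mu_inf=1e-13)
        parents = [haploid(0, 0, 0, 0.2), haploid(1, 0, 0, 0.6)]
        children = reproduce_averaging(parents, 1, sched, rng)
        assert len(children) == 4
        for c in children:
            assert c.phenotype.rho == pytest.approx(0.4, abs=1e-11)

    def test_70_parents_give_140_progeny(self, rng):
        parents = [haploid(i, 0.1, 0.1, 0.5) for i in range(70)]
        assert len(reproduce_averaging(parents, 1, MutationSchedule(), rng)) == 140

    def test_odd_parent_count_rejected(self, rng):
        parents = [haploid(i, 0, 0, 0.5) for i in range(3)]
        with pytest.raises(ValueError):
            reproduce_averaging(parents, 1, MutationSchedule(), rng)


class TestReproduceDiploid:
    TINY = MutationSchedule(mu0=1e-12, mu_inf=1e-13)

    def test_homozygote_transmits_its_allele(self, rng):
        parents = [diploid(0, [[0.2, 0.2]] * 3, [[0, 0]] * 3),
                   diploid(1, [[0.8, 0.8]] * 3, [[1, 1]] * 3)]
        children = reproduce_diploid(parents, 1, self.TINY, rng)
        assert len(children) == 4
        for c in children:
            assert sorted(c.genotype.tags[0]) == [0, 1]
            assert c.phenotype.alpha == pytest.approx(0.5, abs=1e-11)

    def test_codominant_phenotype_is_allele_mean(self):
        a = diploid(0, [[0.045, 0.645], [0.0, 0.0], [0.2, 0.2]],
                    [[0, 1], [2, 2], [3, 3]])
        assert a.phenotype.alpha == pytest.approx(0.345)

    def test_mendelian_segregation_frequencies(self):
        # (a,b) x (c,d): genotypes ac, ad, bc, bd each with probability 1/4
        rng = np.random.default_rng(21)
        parents = [diploid(0, [[0.1, 0.2]] * 3, [[0, 1]] * 3),
                   diploid(1, [[0.3, 0.4]] * 3, [[2, 3]] * 3)]
        counts = {}
        n_rounds = 2500  # 10_000 progeny
        for _ in range(n_rounds):
            for c in reproduce_diploid(parents, 1, self.TINY, rng):
                key = tuple(sorted(c.genotype.tags[0]))
                counts[key] = counts.get(key, 0) + 1
        assert set(counts) == {(0, 2), (0, 3), (1, 2), (1, 3)}
        observed = np.array([counts[k] for k in sorted(counts)])
        chi2 = ((observed - 2500.0) ** 2 / 2500.0).sum()
        assert stats.chi2.sf(chi2, df=3) > 1e-4

    def test_inherited_alleles_are_mutated_but_tagged_by_lineage(self):
        rng = np.random.default_rng(2)
        sched = MutationSchedule()
        parents = [diploid(0, [[0.5, 0.5]] * 3, [[0, 0]] * 3),
                   diploid(1, [[0.5, 0.5]] * 3, [[1, 1]] * 3)]
        mu = mutation_scale(1, sched)
        for c in reproduce_diploid(parents, 1, sched, rng):
            assert (np.abs(c.genotype.alleles - 0.5) <= mu).all()
            assert sorted(c.genotype.tags[0]) == [0, 1]

    def test_haploid_parents_rejected(self, rng):
        parents = [haploid(i, 0, 0, 0.5) for i in range(2)]
        with pytest.raises(TypeError):
            reproduce_diploid(parents, 1, MutationSchedule(), rng)

    def test_neutral_reproduction_conserves_allele_frequencies_in_expectation(self):
        # fixed parent pool, no selection: across replicate progeny sets the
        # mean change in allele frequency is zero within Monte-Carlo error
        rng = np.random.default_rng(13)
        parents = [diploid(i, [[0.1, 0.9]] * 3, [[0, 1]] * 3) if i % 2
                   else diploid(i, [[0.1, 0.1]] * 3, [[0, 0]] * 3)
                   for i in range(20)]
        parent_freq = 0.75  # 30 copies of allele 0 among 40
        freqs = []
        for _ in range(300):
            children = reproduce_diploid(parents, 1, self.TINY, rng)
            tags = np.array([c.genotype.tags[0] for c in children])
            freqs.append((tags == 0).mean())
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - parent_freq) < 4 * se + 1e-3


class TestEpoch:
    def small_config(self, **kw):
        defaults = dict(
            n_agents=4,
            n_ticks=10,
            n_generations=5,
            grid=__import__("guildsim").GridSpec(5, 5),
        )
        defaults.update(kw)
        return EpochConfig(**defaults)

    def test_single_generation_epoch(self):
        res = run_epoch(self.small_config(n_generations=1), seed=0)
        assert len(res.records) == 1
        assert len(res.final_agents) == 4

    def test_fixed_seed_bit_identical(self):
        a = run_epoch(self.small_config(), seed=7)
        b = run_epoch(self.small_config(), seed=7)
        assert (a.records_frame().to_numpy() == b.records_frame().to_numpy()).all()
        assert (a.final_frame()[["alpha", "delta", "rho"]].to_numpy()
                == b.final_frame()[["alpha", "delta", "rho"]].to_numpy()).all()

    @pytest.mark.parametrize("mode", list(ReproductionMode))
    def test_population_size_constant_every_generation(self, mode):
        res = run_epoch(self.small_config(mode=mode, n_generations=6), seed=3)
        for rec in res.records:
            assert len(rec.fitness) == 4

    def test_clonal_requires_even_population(self):
        with pytest.raises(ValueError):
            self.small_config(n_agents=5)

    def test_sexual_modes_require_multiple_of_four(self):
        with pytest.raises(ValueError):
            self.small_config(n_agents=6, mode=ReproductionMode.DIPLOID_RANDOM)

    def test_density_arithmetic(self):
        cfg = EpochConfig(n_agents=10)
        assert cfg.density == pytest.approx(0.025)

    def test_snapshots_taken_at_requested_generations(self):
        res = run_epoch(self.small_config(snapshot_generations=(1, 3)), seed=2)
        assert set(res.snapshots) == {1, 3}
        assert len(res.snapshots[1]) == 4

    def test_mean_fitness_rises_then_plateaus(self):
        # scaled version of the qualitative trajectory shape: selection
        # lifts mean fitness well above the initial random-phenotype level
        cfg = EpochConfig(n_agents=10, n_ticks=100, n_generations=50)
        res = run_epoch(cfg, seed=4)
        means = [r.fitness_mean for r in res.records]
        assert np.mean(means[35:]) > means[0]

    def test_hardy_weinberg_proportions_in_progeny_of_random_mating(self):
        """Random mating + random segregation put progeny in HW proportions.

        Chi-square on 10^4 progeny of a fixed parent pool, non-significant
        at alpha = 0.01 in >= 95% of replicates.  The sample takes one
        progeny per mated pair: full families of 4 siblings share parents,
        which inflates genotype-count variance relative to the multinomial
        chi-square null even though each gamete union is exactly HW.
        """
        rng = np.random.default_rng(42)
        tiny = MutationSchedule(mu0=1e-12, mu_inf=1e-13)
        pool_rng = np.random.default_rng(0)
        allele_values = {0: 0.1, 1: 0.5, 2: 0.9}
        parents = []
        for i in range(20_000):
            t = pool_rng.choice(3, size=(3, 2), p=[0.5, 0.3, 0.2])
            alleles = np.vectorize(allele_values.get)(t)
            parents.append(diploid(i, alleles, t))
        ok = 0
        n_rep = 40
        for _ in range(n_rep):
            children = reproduce_diploid(parents, 1, tiny, rng)
            counts = genotype_counts(children[::4], "alpha")  # one per family
            res = hw_expected_counts(counts)
            if res.p_value > 0.01:
                ok += 1
        assert ok >= int(0.95 * n_rep)
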