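"""Wright-Fisher machinery: meiosis, generations, engines, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import ks_2samp, mannwhitneyu

from zwturnover.simulate import (
    EXTINCT,
    Haplotype,
    Individual,
    SimParams,
    effective_recombination_rate,
    initialize_population,
    meiosis,
    run_batch,
    run_replicate,
    step_generation,
)
from zwturnover.stats import segregating_sites


def params_for(gene_model, **kw) -> SimParams:
    base = dict(gene_model=gene_model, mu=0.0, r0=0.0, pop_chromosomes=20,
                generations=100, seed=1)
    base.update(kw)
    return SimParams(**base)


class TestRecombinationRate:
    def test_undiverged_recombines_at_baseline(self):
        assert effective_recombination_rate(1e-6, 0.03, 0) == 1e-6

    def test_linear_suppression(self):
        assert effective_recombination_rate(1e-6, 0.03, 10) == pytest.approx(7e-7)

    def test_clamped_at_zero_beyond_34_differences(self):
        assert effective_recombination_rate(1e-6, 0.03, 34) == 0.0
        assert effective_recombination_rate(1e-6, 0.03, 100) == 0.0

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            effective_recombination_rate(1e-6, 0.03, -1)


class TestInitialization:
    def test_smallest_population(self, gene_model):
        state = initialize_population(params_for(gene_model, pop_chromosomes=4))
        sexes = sorted(ind.sex for ind in state.individuals)
        assert sexes == ["F", "M"]

    def test_chromosome_classes_at_2n_100(self, gene_model):
        state = initialize_population(params_for(gene_model, pop_chromosomes=100))
        haps = [h for ind in state.individuals for h in ind.haplotypes]
        n_w = sum(h.functional for h in haps)
        assert (n_w, len(haps) - n_w) == (25, 75)

    def test_z_haplotypes_carry_single_splice_change(self, gene_model):
        state = initialize_population(params_for(gene_model, pop_chromosomes=10))
        for ind in state.individuals:
            for h in ind.haplotypes:
                if not h.functional:
                    assert len(h.diffs) == 1
                    (pos, base), = h.diffs
                    assert pos == gene_model.initial_sd_site
                    assert gene_model.classify(pos, base).category.value == "splice_site"

    def test_odd_individual_count_rounds_females_up(self, gene_model):
        state = initialize_population(params_for(gene_model, pop_chromosomes=6))
        f, m = state.sex_counts()
        assert (f, m) == (2, 1)


class TestMeiosis:
    def test_no_events_copies_a_parental_haplotype(self, gene_model):
        p = params_for(gene_model)
        state = initialize_population(p)
        female = next(ind for ind in state.individuals if ind.is_female)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(40):
            g = meiosis(female, p, rng)
            assert g in female.haplotypes
            seen.add(g.functional)
        assert seen == {True, False}  # both parental haplotypes transmitted

    def test_homozygous_parent_transmits_identically_even_with_crossover(self, gene_model):
        p = params_for(gene_model, r0=1.0)  # forces a crossover every meiosis
        male = Individual(
            (Haplotype.from_diffs({gene_model.initial_sd_site: "A"}, gene_model),) * 2
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert meiosis(male, p, rng) == male.haplotypes[0]

    def test_crossover_recombines_flanking_diffs(self, gene_model):
        gm = gene_model

        def neutral_at(rng_positions):
            for pos in rng_positions:
                for b in "ACGT":
                    if b != gm.reference_sequence[pos] and not gm.is_lof(pos, b):
                        return (pos, b)
            raise AssertionError("no neutral change found")

        neutral = [
            neutral_at(range(gm.total_length // 3)),
            neutral_at(range(gm.total_length - 1, 2 * gm.total_length // 3, -1)),
        ]
        h1 = Haplotype.from_diffs(dict(neutral[:1]), gm)
        h2 = Haplotype.from_diffs(dict(neutral[1:]), gm)
        p = params_for(gm, r0=1.0)
        rng = np.random.default_rng(2)
        products = {meiosis(Individual((h1, h2)), p, rng).diffs for _ in range(200)}
        both = tuple(sorted(dict(neutral).items()))
        assert both in products  # left-of-one + right-of-other
        assert () in products

    def test_mutation_count_matches_poisson_mean(self, gene_model):
        mu = 1e-5
        p = params_for(gene_model, mu=mu)
        ref = Individual((Haplotype.from_diffs({}, gene_model),) * 2)
        rng = np.random.default_rng(3)
        n = 100_000
        total = sum(len(meiosis(ref, p, rng).diffs) for _ in range(n))
        lam = mu * gene_model.total_length
        se = np.sqrt(lam / n)
        assert abs(total / n - lam) < 3 * se


class TestGenerationStep:
    def test_population_size_conserved(self, gene_model):
        p = params_for(gene_model, mu=1e-4, r0=1e-4)
        state = initialize_population(p)
        rng = np.random.default_rng(4)
        nxt = step_generation(state, p, rng)
        assert len(nxt.individuals) == len(state.individuals)
        assert nxt.generation == 1

    def test_without_mutation_only_founder_genotypes_appear(self, gene_model):
        p = params_for(gene_model, pop_chromosomes=4)
        state = initialize_population(p)
        rng = np.random.default_rng(5)
        for _ in range(20):
            f, m = state.sex_counts()
            if f == 0 or m == 0:
                break
            state = step_generation(state, p, rng)
            for ind in state.individuals:
                n_func = sum(h.functional for h in ind.haplotypes)
                assert n_func in (0, 1)  # W/Z or Z/Z only

    def test_single_sex_population_rejected(self, gene_model):
        p = params_for(gene_model)
        z = Haplotype.from_diffs(
            {gene_model.initial_sd_site: gene_model.initial_sd_alt_base}, gene_model
        )
        males_only = initialize_population(p)
        males_only.individuals = [Individual((z, z))] * 10
        with pytest.raises(ValueError):
            step_generation(males_only, p, np.random.default_rng(0))

    def test_offspring_sex_ratio_is_binomial_half(self, gene_model):
        """With one segregating LOF site, each offspring is female w.p. 1/2."""
        p = params_for(gene_model, pop_chromosomes=20)
        n = p.n_individuals
        state = initialize_population(p)
        rng = np.random.default_rng(6)
        females = []
        gens = 400
        for _ in range(gens):
            f, m = state.sex_counts()
            if f == 0 or m == 0:
                state = initialize_population(p)
                continue
            state = step_generation(state, p, rng)
            females.append(state.sex_counts()[0])
        frac = np.mean(females) / n
        se = np.sqrt(0.25 / (n * len(females)))
        assert abs(frac - 0.5) < 3 * se


class TestReplicates:
    def test_zero_generations_returns_initial_state(self, gene_model):
        for engine in ("naive", "counts"):
            r = run_replicate(params_for(gene_model, generations=0), engine=engine)
            assert r.generations_run == 0
            assert r.census.fixed_lof == (gene_model.initial_sd_site,)
            assert r.census.nonfixed_lof == {}
            assert not r.census.turnover

    @pytest.mark.parametrize("engine", ["naive", "counts"])
    def test_no_mutation_means_no_turnover_and_no_new_sites(self, gene_model, engine):
        p = params_for(gene_model, pop_chromosomes=20, generations=300, seed=11)
        r = run_replicate(p, engine=engine)
        assert r.census.fixed_lof == (gene_model.initial_sd_site,)
        assert not r.census.turnover
        assert segregating_sites(r.haplotypes) <= 1

    @pytest.mark.parametrize("engine", ["naive", "counts"])
    def test_bit_identical_reproducibility(self, gene_model, engine):
        p = params_for(
            gene_model, mu=1e-5, r0=1e-5, pop_chromosomes=30, generations=400, seed=42
        )
        a = run_replicate(p, engine=engine)
        b = run_replicate(p, engine=engine)
        assert a.termination_status == b.termination_status
        assert a.generations_run == b.generations_run
        assert a.census == b.census
        assert a.diversity == b.diversity
        assert sorted(map(repr, a.haplotypes)) == sorted(map(repr, b.haplotypes))

    def test_batch_first_replicate_matches_run_replicate(self, gene_model):
        p = params_for(gene_model, mu=1e-5, generations=200)
        batch = run_batch(p, 1, base_seed=77)
        single = run_replicate(replace(p, seed=77))
        assert batch.replicates[0].census == single.census
        assert batch.replicates[0].diversity == single.diversity

    def test_batch_seed_policy(self, gene_model):
        p = params_for(gene_model, generations=10)
        batch = run_batch(p, 3, base_seed=100)
        assert [r.seed for r in batch.replicates] == [100, 101, 102]

    def test_extinction_recorded_not_raised(self, gene_model):
        # 2N=4: each generation goes single-sex with probability 1/2
        p = params_for(gene_model, pop_chromosomes=4, generations=200, seed=3)
        for engine in ("naive", "counts"):
            r = run_replicate(p, engine=engine)
            assert r.termination_status == EXTINCT
            assert r.generations_run < p.generations


@pytest.fixture(scope="module")
def summaries(gene_model):
    """200 replicates per engine at 2N=20, 500 generations, elevated rates."""
    out = {}
    n_reps = 200
    for engine, base_seed in (("naive", 10_000), ("counts", 20_000)):
        p = SimParams(
            gene_model=gene_model, mu=2e-5, r0=1e-5, pop_chromosomes=20,
            generations=500,
        )
        batch = run_batch(p, n_reps, base_seed, engine=engine)
        out[engine] = {
                "female_frac": np.array(
                    [
                        sum(c for d, f, c in r.haplotypes if f)  # = #females (W count)
                        / r.params.pop_chromosomes
                        for r in batch.replicates
                    ]
                ),
                "pi_all": np.array([r.diversity.pi_all for r in batch.replicates]),
                "seg_sites": np.array(
                    [segregating_sites(r.haplotypes) for r in batch.replicates]
                ),
                "extinct": np.array(
                    [r.termination_status == EXTINCT for r in batch.replicates]
                ),
            }
    return out


class TestEngineEquivalence:
    """The counts engine must match the naive engine in distribution."""

    def test_sex_ratio_distribution_matches(self, summaries):
        a, b = summaries["naive"], summaries["counts"]
        assert ks_2samp(a["female_frac"], b["female_frac"]).pvalue > 0.01

    def test_diversity_distribution_matches(self, summaries):
        a, b = summaries["naive"], summaries["counts"]
        assert ks_2samp(a["pi_all"], b["pi_all"]).pvalue > 0.01

    def test_segregating_sites_distribution_matches(self, summaries):
        a, b = summaries["naive"], summaries["counts"]
        assert mannwhitneyu(a["seg_sites"], b["seg_sites"]).pvalue > 0.01

    def test_extinction_rates_match(self, summaries):
        a = summaries["naive"]["extinct"].mean()
        b = summaries["counts"]["extinct"].mean()
        se = np.sqrt(a * (1 - a) / 200 + b * (1 - b) / 200)
        assert abs(a - b) < 3 * max(se, 0.01)
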