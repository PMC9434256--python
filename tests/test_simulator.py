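"""Unit and property tests for the forward population simulator."""

import numpy as np
import pytest

from pedbench import (ExtinctionError, GenomeMap, SimulationConfig,
                      assortative_mating_step, default_genome_map, gamete,
                      make_founders, make_trait, migration_step, phenotype,
                      random_mating_step, simulate)
from pedbench.simulator import Population, TraitModel


def _cfg(**kw):
    base = dict(n_founders=30, n_generations=4, n_snps=400, n_chromosomes=4,
                seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestFounders:
    def test_shape_and_single_subpopulation(self):
        cfg = _cfg(n_founders=100, n_snps=600)
        rng = np.random.default_rng(0)
        pop = make_founders(cfg, default_genome_map(cfg), rng)
        assert pop.n == 100
        assert pop.haplotypes.shape == (100, 2, 600)
        assert set(np.unique(pop.haplotypes)) <= {0, 1}
        assert np.all(pop.subpop == 0)
        assert np.all(pop.sires == 0) and np.all(pop.dams == 0)

    def test_single_founder_is_valid(self):
        cfg = _cfg(n_founders=1)
        pop = make_founders(cfg, default_genome_map(cfg), np.random.default_rng(0))
        assert pop.n == 1

    def test_allele_frequency_near_half(self):
        # mean frequency over many Bernoulli(0.5) draws: binomial SE
        cfg = _cfg(n_founders=100, n_snps=2000)
        pop = make_founders(cfg, default_genome_map(cfg), np.random.default_rng(3))
        freq = pop.haplotypes.mean()
        se = 0.5 / np.sqrt(100 * 2 * 2000)
        assert abs(freq - 0.5) < 5 * se


class TestGamete:
    def test_homozygous_parent_transmits_exactly(self):
        cfg = _cfg()
        gm = default_genome_map(cfg)
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=cfg.n_snps, dtype=np.uint8)
        g = gamete(np.stack([hap, hap]), gm, rng)
        assert np.array_equal(g, hap)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            GenomeMap(chrom_lengths_bp=np.array([100]),
                      snp_chrom=np.array([], dtype=int),
                      snp_pos_bp=np.array([], dtype=int))

    def test_mendelian_segregation_and_crossover_rate(self):
        # fully heterozygous parent: per-site transmission ~ Bernoulli(0.5);
        # one 100 Mbp chromosome at 1 cM/Mbp ~ 1 observable crossover/gamete
        cfg = SimulationConfig(n_founders=2, n_snps=200, n_chromosomes=1,
                               chrom_length_mbp=100.0, seed=0)
        gm = default_genome_map(cfg)
        parent = np.stack([np.zeros(200, dtype=np.uint8),
                           np.ones(200, dtype=np.uint8)])
        rng = np.random.default_rng(5)
        n = 4000
        gams = np.stack([gamete(parent, gm, rng) for _ in range(n)])
        site_freq = gams.mean(axis=0)
        assert np.all(np.abs(site_freq - 0.5) < 5 * 0.5 / np.sqrt(n))
        switches = np.abs(np.diff(gams.astype(int), axis=1)).sum(axis=1)
        # expected observable switches ~= map length in Morgans (edges lose a bit)
        assert abs(switches.mean() - 1.0) < 0.15


class TestMatingSteps:
    def _founder_pop(self, n, n_snps=100, seed=0):
        cfg = SimulationConfig(n_founders=n, n_snps=n_snps, n_chromosomes=2,
                               seed=seed)
        gm = default_genome_map(cfg)
        return cfg, gm, make_founders(cfg, gm, np.random.default_rng(seed))

    def test_random_mating_pairing_and_offspring_counts(self):
        cfg, gm, pop = self._founder_pop(100)
        off = random_mating_step(pop, cfg, gm, next_id=101,
                                 rng=np.random.default_rng(1))
        # 50 pairs, k ~ uniform{1..4}: offspring in [50, 200], around 125
        assert 50 <= off.n <= 200
        assert np.all(off.sires != off.dams)  # no self-mating
        assert set(off.sires) <= set(pop.ids) and set(off.dams) <= set(pop.ids)
        assert off.generation == 1
        # monogamy: each parent appears with exactly one partner
        partner = {}
        for s, d in zip(off.sires, off.dams):
            assert partner.setdefault(s, d) == d
            assert partner.setdefault(d, s) == s

    def test_two_individuals_one_pair(self):
        cfg, gm, pop = self._founder_pop(2)
        off = random_mating_step(pop, cfg, gm, 3, np.random.default_rng(0))
        assert len(set(zip(off.sires.tolist(), off.dams.tolist()))) == 1

    def test_singleton_subpopulation_warns_no_offspring(self):
        cfg, gm, pop = self._founder_pop(3)
        pop.subpop = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="1 member"):
            off = random_mating_step(pop, cfg, gm, 4, np.random.default_rng(0))
        assert np.all(off.subpop == 0)

    def test_mendelian_consistency_of_offspring(self):
        # every transmitted haplotype must sitewise match one of the two
        # parental haplotypes wherever the parent is homozygous
        cfg, gm, pop = self._founder_pop(40, n_snps=300)
        off = random_mating_step(pop, cfg, gm, 41, np.random.default_rng(2))
        id_to_row = {i: k for k, i in enumerate(pop.ids)}
        for j in range(off.n):
            for hap, parent in ((0, off.sires[j]), (1, off.dams[j])):
                ph = pop.haplotypes[id_to_row[parent]]
                child = off.haplotypes[j, hap]
                ok = (child == ph[0]) | (child == ph[1])
                assert ok.all()

    def test_expected_offspring_mean_random(self):
        # 50 pairs x mean(uniform{1..4}) = 125 expected offspring
        counts = []
        for seed in range(30):
            cfg, gm, pop = self._founder_pop(100, seed=seed)
            off = random_mating_step(pop, cfg, gm, 101,
                                     np.random.default_rng(1000 + seed))
            counts.append(off.n)
        se = 50 * np.sqrt(1.25) / np.sqrt(30)  # var(uniform{1..4}) = 1.25
        assert abs(np.mean(counts) - 125) < 4 * se


class TestTraitAndSelection:
    def test_phenotype_trivial_cases(self):
        trait = TraitModel(qtn_indices=np.arange(10),
                           qtn_effects=np.ones(10), env_sd=0.0)
        rng = np.random.default_rng(0)
        zero = phenotype(np.zeros((1, 20)), trait, rng)
        assert zero[0] == 0.0
        full = phenotype(np.full((1, 20), 2.0), trait, rng)
        assert full[0] == 2 * 10

    def test_h2_calibration(self):
        # founder-generation Var(G)/Var(P) ~ 0.5 over many phenotype draws
        cfg = SimulationConfig(n_founders=400, n_snps=500, n_qtn=10, h2=0.5,
                               seed=9)
        gm = default_genome_map(cfg)
        rng = np.random.default_rng(9)
        pop = make_founders(cfg, gm, rng)
        trait = make_trait(cfg, pop, rng)
        g = trait.genetic_value(pop.dosage())
        phen = np.concatenate(
            [phenotype(pop.dosage(), trait, rng) for _ in range(25)])
        ratio = np.var(g) / np.var(phen)
        assert abs(ratio - 0.5) < 0.05

    def test_selection_retains_top_genetic_values(self):
        cfg = SimulationConfig(n_founders=60, n_snps=200, mating="assortative",
                               seed=4)
        gm = default_genome_map(cfg)
        rng = np.random.default_rng(4)
        pop = make_founders(cfg, gm, rng)
        trait = TraitModel(qtn_indices=np.arange(10),
                           qtn_effects=np.abs(np.random.default_rng(0).standard_normal(10)),
                           env_sd=0.0)
        off = assortative_mating_step(pop, cfg, trait, gm, 61, rng)
        g = trait.genetic_value(pop.dosage())
        cutoff = np.sort(g)[::-1][29]  # top 50% of 60
        id_to_row = {i: k for k, i in enumerate(pop.ids)}
        parents = set(off.sires) | set(off.dams)
        for p in parents:
            assert g[id_to_row[p]] >= cutoff
        # selection differential: parents' mean QTN dosage >= population mean
        par_rows = [id_to_row[p] for p in parents]
        assert (pop.dosage()[par_rows][:, :10].mean()
                >= pop.dosage()[:, :10].mean())

    def test_assortative_offspring_counts(self):
        cfg = SimulationConfig(n_founders=100, n_snps=100, mating="assortative",
                               seed=2)
        gm = default_genome_map(cfg)
        rng = np.random.default_rng(2)
        pop = make_founders(cfg, gm, rng)
        trait = make_trait(cfg, pop, rng)
        off = assortative_mating_step(pop, cfg, trait, gm, 101, rng)
        # 25 pairs x uniform{2..8}: offspring in [50, 200], around 125
        assert 50 <= off.n <= 200
        assert len(set(off.sires) | set(off.dams)) <= 50


class TestMigration:
    def _pop(self, n=100, seed=0):
        cfg = _cfg(n_founders=n, migration_prob=1.0)
        gm = default_genome_map(cfg)
        return cfg, make_founders(cfg, gm, np.random.default_rng(seed))

    def test_prob_zero_is_identity(self):
        cfg, pop = self._pop()
        cfg0 = SimulationConfig(**{**cfg.__dict__, "migration_prob": 0.0})
        out = migration_step(pop, cfg0, np.random.default_rng(0))
        assert np.array_equal(out.subpop, pop.subpop)

    def test_prob_one_splits_in_half(self):
        cfg, pop = self._pop(100)
        out = migration_step(pop, cfg, np.random.default_rng(0))
        labels, counts = np.unique(out.subpop, return_counts=True)
        assert len(labels) == 2
        assert sorted(counts.tolist()) == [50, 50]

    def test_fission_rate(self):
        cfg, pop = self._pop(20)
        cfg3 = SimulationConfig(**{**cfg.__dict__, "migration_prob": 0.3})
        rng = np.random.default_rng(11)
        n_trials = 300
        fissions = sum(
            np.unique(migration_step(pop, cfg3, rng).subpop).size > 1
            for _ in range(n_trials))
        se = np.sqrt(0.3 * 0.7 / n_trials)
        assert abs(fissions / n_trials - 0.3) < 4 * se


class TestSimulate:
    def test_default_growth_and_population_size(self):
        res = simulate(SimulationConfig(seed=123))
        # 100 founders x growth ~1.25/generation for 10 generations ~ 931,
        # with wide branching-process spread and odd-subpop losses
        assert 350 <= res.genotypes.n_individuals <= 2200

    def test_zero_generations_returns_founders(self):
        res = simulate(_cfg(n_generations=0))
        assert res.genotypes.n_individuals == 30
        assert all(s is None for s in res.pedigree.sires)

    def test_deterministic_from_seed(self):
        a = simulate(_cfg(seed=55))
        b = simulate(_cfg(seed=55))
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert a.pedigree.ids == b.pedigree.ids
        assert a.pedigree.sires == b.pedigree.sires
        assert np.array_equal(a.subpop_labels, b.subpop_labels)

    def test_no_migration_single_label(self):
        res = simulate(_cfg(migration_enabled=False))
        assert np.unique(res.subpop_labels).size == 1
        assert np.unique(res.pedigree.subpopulation).size == 1

    def test_generation_stratified_pedigree(self, tiny_sim):
        ped = tiny_sim.pedigree
        gen = {i: g for i, g in zip(ped.ids, ped.generation)}
        for i, s, d in zip(ped.ids, ped.sires, ped.dams):
            for p in (s, d):
                if p is not None:
                    assert gen[p] == gen[i] - 1

    def test_genotype_is_haplotype_sum(self, tiny_sim):
        vals = tiny_sim.genotypes.values
        assert vals.min() >= 0 and vals.max() <= 2

    def test_extinction_reports_generation(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ExtinctionError, match="generation 0"):
                simulate(_cfg(n_founders=1, n_generations=2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_founders=0)
        with pytest.raises(ValueError):
            SimulationConfig(migration_prob=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(offspring_range_random=(4, 1))
        with pytest.raises(ValueError):
            SimulationConfig(mating="selfing")


class TestPopulationGenetics:
    def test_drift_is_symmetric_under_random_mating(self):
        # across replicate simulations the mean allele frequency stays ~0.5
        freqs = []
        for seed in range(25):
            res = simulate(SimulationConfig(
                n_founders=24, n_generations=4, n_snps=120, n_chromosomes=2,
                migration_enabled=False, seed=seed))
            freqs.append(res.genotypes.values.mean() / 2)
        assert abs(np.mean(freqs) - 0.5) < 0.02

    def test_assortative_more_differentiated_than_random(self):
        # selection on a shared trait accelerates between-deme divergence
        from pedbench import fst
        means = {}
        for mating in ("random", "assortative"):
            vals = []
            for seed in range(6):
                res = simulate(SimulationConfig(
                    n_founders=60, n_generations=6, n_snps=500,
                    n_chromosomes=4, mating=mating, seed=900 + seed))
                labels = res.subpop_labels
                uniq, counts = np.unique(labels, return_counts=True)
                keep = np.isin(labels, uniq[counts >= 2])
                if uniq[counts >= 2].size < 2:
                    continue
                vals.append(fst(res.genotypes.values[keep], labels[keep]))
            means[mating] = np.mean(vals)
        assert means["assortative"] > means["random"]
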