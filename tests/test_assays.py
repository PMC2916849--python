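"""Gene classification, mutational-effect spectra, fitness effects,
evolvability, adaptation benchmark."""

import numpy as np
import pytest

import grnsim as gs
from grnsim.assays import (classify_fitness_effect, classify_genes,
                           evolvability_index, mutation_effect_assay)
from grnsim.evolution import PopulationState, develop_genotype, make_rngs
from grnsim.mutation import BTL, CIS, DEL, DUP, TRA


class TestClassifyGenes:
    def test_fig1_like_classes(self, fig1_genome, cfg):
        cls = classify_genes(fig1_genome, cfg)
        assert cls.core == {"R1", "R2", "R3"}
        assert cls.pseudo_expression == {"R4"}
        assert cls.silent == {"R5"}

    def test_partition(self, founder, cfg):
        cls = classify_genes(founder, cfg)
        labels = {founder.genes[i].label for i in founder.regulatory_indices}
        assert cls.core | cls.pseudo_expression | cls.silent == labels
        assert cls.n_core + cls.n_psdexp + cls.n_silent == len(labels)
        assert not (cls.core & cls.pseudo_expression)
        assert not (cls.core & cls.silent)

    def test_invariant_to_gene_order(self, fig1_genome, cfg):
        rng = np.random.default_rng(0)
        shuffled = fig1_genome.copy()
        order = rng.permutation(len(shuffled.genes))
        shuffled.genes = [shuffled.genes[i] for i in order]
        a = classify_genes(fig1_genome, cfg)
        b = classify_genes(shuffled, cfg)
        assert (a.core, a.pseudo_expression, a.silent) == \
            (b.core, b.pseudo_expression, b.silent)

    def test_direct_targets_all_core(self, fig1_genome, cfg):
        # rewire R4 to target P1 directly: no pseudo-expression genes remain
        rewired = fig1_genome.copy()
        p1 = next(g for g in rewired.genes if g.label == "P1")
        p1.cis_numbers[2] = 4
        p1.coefficients[2] = 1.0
        cls = classify_genes(rewired, cfg)
        assert cls.pseudo_expression == set()
        assert "R4" in cls.core

    def test_nonviable_errors(self, oscillator_genome, cfg):
        with pytest.raises(ValueError):
            classify_genes(oscillator_genome, cfg)


class TestPhenotypeEffect:
    def test_identical_is_non_effect(self, founder_genotype, cfg):
        mutant = develop_genotype(founder_genotype.genome.copy(), cfg)
        assert gs.classify_phenotype_effect(founder_genotype, mutant, cfg) \
            == "none"

    def test_silencing_phenotypic_expression_is_loss(self, fig1_genome, cfg):
        parent = develop_genotype(fig1_genome, cfg)
        # deleting R2 removes the only activator of P2 -> P2 < 1e-2
        idx = next(i for i, g in enumerate(fig1_genome.genes)
                   if g.label == "R2")
        mutant_genome, _ = gs.delete_gene(fig1_genome, idx)
        mutant = develop_genotype(mutant_genome, cfg)
        assert gs.classify_phenotype_effect(parent, mutant, cfg) == "loss"

    def test_silent_gene_mutations_are_non_effect(self, fig1_genome, cfg):
        parent = develop_genotype(fig1_genome, cfg)
        idx = next(i for i, g in enumerate(fig1_genome.genes)
                   if g.label == "R5")
        rng = np.random.default_rng(1)
        for op in (lambda: gs.mutate_trans(fig1_genome, idx, rng),
                   lambda: gs.delete_gene(fig1_genome, idx),
                   lambda: gs.mutate_btl(fig1_genome, idx, -1)):
            mutant_genome, _ = op()
            mutant = develop_genotype(mutant_genome, cfg)
            assert gs.classify_phenotype_effect(parent, mutant, cfg) == "none"


class TestMutationEffectAssay:
    def test_proportions_sum_to_one_exactly(self, founder, cfg):
        pop = [develop_genotype(founder, cfg)]
        rng = make_rngs(5)["assay"]
        summary = mutation_effect_assay(pop, cfg, rng, n_individuals=40)
        for mtype in (BTL, CIS, TRA, DEL, DUP):
            n = summary.sample_size(mtype)
            assert n > 0
            counts = summary.counts[mtype]
            assert counts["loss"] + counts["none"] + counts["significant"] == n
            assert summary.P_L(mtype) + summary.P_N(mtype) + \
                summary.P_S(mtype) == pytest.approx(1.0, abs=0)

    def test_displacements_only_for_significant(self, founder, cfg):
        pop = [develop_genotype(founder, cfg)]
        rng = make_rngs(6)["assay"]
        summary = mutation_effect_assay(pop, cfg, rng, n_individuals=40,
                                        types=(TRA, DEL))
        for mtype in (TRA, DEL):
            assert len(summary.displacements[mtype]) == \
                summary.counts[mtype]["significant"]
            assert all(d > cfg.eps_same for d in summary.displacements[mtype])

    def test_unknown_type_rejected(self, founder, cfg):
        pop = [develop_genotype(founder, cfg)]
        with pytest.raises(ValueError):
            mutation_effect_assay(pop, cfg, make_rngs(7)["assay"],
                                  types=("XYZ",))


class TestFitnessEffectClassification:
    @pytest.mark.parametrize("dF, expected", [
        (0.0, "neutral"),
        (0.05, "beneficial"),
        (-0.05, "deleterious"),
        (0.009, "neutral"),
        (0.01, "beneficial"),
    ])
    def test_band(self, dF, expected):
        assert classify_fitness_effect(0.5 + dF, 0.5) == expected

    def test_band_sensitivity(self):
        # clearly beneficial/deleterious calls are stable across bands
        for band in (1e-4, 1e-3, 1e-2, 1e-1):
            assert classify_fitness_effect(0.9, 0.5, band) == "beneficial"
            assert classify_fitness_effect(0.1, 0.5, band) == "deleterious"

    def test_tracking_disabled_errors(self, founder):
        cfg = gs.SimulationConfig(Z=10, generations=2, seed=1,
                                  regime="static", d=0.0)
        summary = gs.run_simulation(cfg, founder=founder)
        with pytest.raises(ValueError):
            gs.track_fitness_effects(summary)

    def test_zero_rate_tracking_run_has_no_events(self, founder):
        cfg = gs.SimulationConfig(
            Z=10, generations=3, seed=1, regime="static", d=0.0, c=0.0,
            mu_BTL=0, mu_CIS=0, mu_TRA=0, mu_DUP=0, mu_DEL=0,
            track_fitness_effects=True, class_cadence=100)
        summary = gs.run_simulation(cfg, founder=founder)
        effects = gs.track_fitness_effects(summary)
        assert all(v == 0 for v in effects.Nt.values())

    def test_lethal_mutation_tracked_deleterious(self, founder, cfg):
        from grnsim.evolution import FitnessEffectEvent
        assert classify_fitness_effect(0.0, 0.8) == "deleterious"
        ev = FitnessEffectEvent(3, DEL, 0.8, 0.0)
        assert ev.delta == pytest.approx(-0.8)


class TestEvolvability:
    @pytest.mark.parametrize("n_core, P_S, expected", [
        (10, 0.0, 0.0), (10, 0.5, 5.0), (20, 0.5, 10.0),
    ])
    def test_index(self, n_core, P_S, expected):
        assert evolvability_index(n_core, P_S) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            evolvability_index(-1, 0.5)
        with pytest.raises(ValueError):
            evolvability_index(3, 1.5)


class TestAdaptationBenchmark:
    def test_d0_is_one_and_frozen_without_mutation(self, founder, cfg):
        gt = develop_genotype(founder, cfg)
        pop = PopulationState([gt] * 30, 0)
        bench_cfg = cfg.replace(
            Z=30, mu_BTL=0, mu_CIS=0, mu_TRA=0, mu_DUP=0, mu_DEL=0)
        rng = make_rngs(11)["assay"]
        traj = gs.adaptation_benchmark(pop, bench_cfg, rng, generations=30)
        assert traj.D0 == pytest.approx(1.0)
        # no heritable variation: the distance cannot change
        assert np.allclose(traj.D, 1.0)

    def test_adaptation_reduces_distance_with_mutation(self, founder, cfg):
        gt = develop_genotype(founder, cfg)
        pop = PopulationState([gt] * 60, 0)
        bench_cfg = cfg.replace(
            Z=60, c=0.0, mu_BTL=2e-3, mu_CIS=2e-3, mu_TRA=2e-3,
            mu_DUP=2e-3, mu_DEL=2e-3)
        rng = make_rngs(12)["assay"]
        traj = gs.adaptation_benchmark(pop, bench_cfg, rng, generations=300)
        assert traj.D_final < traj.D0
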