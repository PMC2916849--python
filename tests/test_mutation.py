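"""Mutation operators: semantics, purity, invariants, scheduling."""

import numpy as np
import pytest

import grnsim as gs
from grnsim.mutation import (BTL, CIS, DEL, DUP, HOR, TRA, MUTATION_TYPES,
                             MutationRates, apply_event, draw_mutations,
                             eligible_counts)

from conftest import random_genome


class TestOperators:
    @pytest.mark.parametrize("b0, direction, expected", [
        (1, -1, 0), (0, -1, 0), (0, +1, 1), (3, +1, 4),
    ])
    def test_btl(self, founder, b0, direction, expected):
        genome = founder.copy()
        genome.genes[2].basal = b0
        new, event = gs.mutate_btl(genome, 2, direction)
        assert new.genes[2].basal == expected
        assert event.no_op == (b0 == expected)
        assert genome.genes[2].basal == b0   # purity

    def test_cis_changes_one_number_keeps_coefficient(self, founder):
        rng = np.random.default_rng(0)
        new, event = gs.mutate_cis(founder, 1, 7, rng)
        assert np.array_equal(new.genes[1].coefficients,
                              founder.genes[1].coefficients)
        diff = new.genes[1].cis_numbers != founder.genes[1].cis_numbers
        assert diff.sum() <= 1          # redraw may coincide, never >1 site
        assert event.site_index == 7
        for i, g in enumerate(new.genes):
            if i != 1:
                assert g == founder.genes[i]

    def test_trans_changes_only_trans(self, founder):
        rng = np.random.default_rng(1)
        new, _ = gs.mutate_trans(founder, 3, rng)
        assert np.array_equal(new.genes[3].cis_numbers,
                              founder.genes[3].cis_numbers)
        assert new.genes[3].basal == founder.genes[3].basal

    def test_duplicate_then_delete_restores_dynamics(self, founder, cfg):
        idx = founder.regulatory_indices[4]
        dup, _ = gs.duplicate_gene(founder, idx)
        assert dup.n_genes == founder.n_genes + 1
        restored, _ = gs.delete_gene(dup, dup.n_genes - 1)
        for signal in (True, False):
            a = gs.develop(founder, signal, cfg, keep_trajectory=True)
            b = gs.develop(restored, signal, cfg, keep_trajectory=True)
            assert np.array_equal(a.trajectory, b.trajectory)
            assert a.steady_time == b.steady_time

    def test_receptor_protected(self, founder):
        r1 = founder.receptor_index
        with pytest.raises(ValueError):
            gs.duplicate_gene(founder, r1)
        with pytest.raises(ValueError):
            gs.delete_gene(founder, r1)

    def test_hor_adds_random_regulatory_gene(self, founder):
        rng = np.random.default_rng(2)
        new, event = gs.horizontal_transfer(founder, rng)
        assert new.n_genes == founder.n_genes + 1
        gene = new.genes[-1]
        assert gene.role == "regulatory" and not gene.is_receptor
        assert gene.basal == 0
        assert np.all((gene.cis_numbers >= 1) & (gene.cis_numbers <= founder.n))
        assert np.all(np.abs(gene.coefficients) <= 5)

    def test_hor_in_degree_matches_cmut(self, founder):
        """A transferred gene's expected in-degree is N_reg * C_mut."""
        rng = np.random.default_rng(3)
        expected = founder.n_regulatory * gs.cmut_from_L(founder.L, founder.n)
        hits = 0
        trials = 3000
        trans = [founder.genes[i].trans_number
                 for i in founder.regulatory_indices]
        for _ in range(trials):
            new, _ = gs.horizontal_transfer(founder, rng)
            gene = new.genes[-1]
            hits += sum(1 for t in trans if np.any(gene.cis_numbers == t))
        rate = hits / trials
        sigma = np.sqrt(expected / trials)    # ~Poisson counting error
        assert abs(rate - expected) < 4 * sigma


class TestInvariantsUnderFuzz:
    def test_random_operator_sequences_preserve_genome_invariants(self):
        rng = np.random.default_rng(4)
        genome = random_genome(rng, n_reg=5, L=6, n=30)
        for _ in range(2000):
            mtype = MUTATION_TYPES[rng.integers(0, 6)]
            if mtype in (DUP, DEL):
                targets = [i for i, g in enumerate(genome.genes)
                           if g.role == "regulatory" and not g.is_receptor]
                if not targets:
                    continue
                target = int(targets[rng.integers(0, len(targets))])
            elif mtype == HOR:
                target = None
            else:
                target = int(rng.integers(0, genome.n_genes))
            genome, _ = apply_event(genome, mtype, target, rng)
            assert sum(g.is_receptor for g in genome.genes) == 1
            assert sum(g.role == "phenotypic" for g in genome.genes) == 2
            for g in genome.genes:
                assert len(g.cis_numbers) == genome.L
                assert g.basal >= 0
                assert 1 <= g.trans_number <= genome.n
                assert np.all((g.cis_numbers >= 1) & (g.cis_numbers <= genome.n))


class TestScheduling:
    def test_zero_rates_no_events(self, founder):
        rng = np.random.default_rng(5)
        rates = MutationRates(0, 0, 0, 0, 0, 0, "per_gene")
        for _ in range(100):
            new, events = draw_mutations(founder, rates, rng)
            assert events == [] and new is founder

    def test_per_gene_event_counts_binomial(self, founder):
        """Realized CIS counts over many offspring match Binomial(n_genes, mu)."""
        rng = np.random.default_rng(6)
        mu = 5e-3
        rates = MutationRates(0, mu, 0, 0, 0, 0, "per_gene")
        n_off = 20_000
        total = 0
        for _ in range(n_off):
            _, events = draw_mutations(founder, rates, rng)
            total += sum(1 for e in events if e.type == CIS)
        expected = n_off * founder.n_genes * mu
        sigma = np.sqrt(expected)
        assert abs(total - expected) < 3 * sigma

    def test_per_individual_at_most_one_event(self, founder):
        rng = np.random.default_rng(7)
        rates = MutationRates(0.02, 0.02, 0.02, 0.02, 0.02, 0.0,
                              "per_individual")
        for _ in range(2000):
            _, events = draw_mutations(founder, rates, rng)
            assert len(events) <= 1

    def test_dup_del_never_hit_receptor(self, founder):
        rng = np.random.default_rng(8)
        rates = MutationRates(0, 0, 0, 0.5, 0.5, 0, "per_individual")
        r1_label = founder.genes[founder.receptor_index].label
        for _ in range(3000):
            _, events = draw_mutations(founder, rates, rng)
            for e in events:
                if e.type in (DUP, DEL) and not e.no_op:
                    assert e.gene_label != r1_label

    def test_constant_ps_only_significant(self, founder, cfg):
        from grnsim.evolution import _significance_test_factory, develop_genotype
        parent = develop_genotype(founder, cfg)
        sig = _significance_test_factory(parent, cfg)
        rng = np.random.default_rng(9)
        rates = MutationRates(0, 0, 0.1, 0.1, 0.1, 0, "constant_PS")
        seen = 0
        for _ in range(60):
            genome, events = draw_mutations(
                founder, rates, rng, significance_test=sig, redraw_cap=200)
            for e in events:
                if e.no_op or e.type not in (DUP, DEL, TRA):
                    continue
                mutant = develop_genotype(genome, cfg)
                assert gs.classify_phenotype_effect(parent, mutant, cfg) == \
                    "significant"
                seen += 1
        assert seen > 0

    def test_eligible_counts(self, founder):
        counts = eligible_counts(founder)
        n = founder.n_genes
        assert counts[BTL] == counts[CIS] == counts[TRA] == n
        assert counts[DUP] == counts[DEL] == founder.n_regulatory - 1
        # horizontal transfer inserts into the genome as a whole:
        # one trial per offspring, so insertion flux never outpaces
        # the per-gene deletion flux
        assert counts[HOR] == 1
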