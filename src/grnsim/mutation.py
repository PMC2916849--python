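"""The six mutation operators and mutation scheduling.

Mutation types (per-gene per-generation rates, standard value 1e-6 except
horizontal transfer, standard 0):

* BTL — basal transcription level +-1 (floored at 0), any gene;
* CIS — one uniformly chosen cis-site's cis-number redrawn uniformly on
  [1, n] (the coefficient is untouched), any gene;
* TRA — the coding region's trans-number redrawn uniformly on [1, n];
* DUP — one regulatory gene (never the receptor R1) copied whole;
* DEL — one regulatory gene (never R1) erased;
* HOR — a fully random new regulatory gene inserted (horizontal transfer).

All operators are pure: they return a new genome and never modify their
input.  Three scheduling modes exist: ``per_gene`` (independent Bernoulli
per gene x type), ``per_individual`` (one Bernoulli per type at 10x the
per-gene rate, at most the first success applied), and ``constant_PS``
(as per_individual, but DUP/DEL/TRA draws are re-targeted until the
mutation has a Significant phenotypic effect, making P_S = 1 for those
types without introducing multiple mutations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genome import COEFF_MAX, COEFF_MIN, Gene, Genome, REGULATORY

__all__ = ["BTL", "CIS", "TRA", "DUP", "DEL", "HOR", "MUTATION_TYPES",
           "MutationEvent", "MutationRates",
           "mutate_btl", "mutate_cis", "mutate_trans",
           "duplicate_gene", "delete_gene", "horizontal_transfer",
           "eligible_counts", "draw_mutations", "events_from_counts",
           "apply_event"]

BTL, CIS, TRA, DUP, DEL, HOR = "BTL", "CIS", "TRA", "DUP", "DEL", "HOR"
MUTATION_TYPES = (BTL, CIS, TRA, DUP, DEL, HOR)


@dataclass
class MutationEvent:
    type: str
    gene_index: int | None = None     # None for HOR
    gene_label: str | None = None
    site_index: int | None = None     # CIS only
    old_value: object = None
    new_value: object = None
    generation: int | None = None
    no_op: bool = False


@dataclass
class MutationRates:
    """Per-gene per-generation mutation probabilities plus the schedule mode."""

    mu_BTL: float = 1e-6
    mu_CIS: float = 1e-6
    mu_TRA: float = 1e-6
    mu_DUP: float = 1e-6
    mu_DEL: float = 1e-6
    mu_HOR: float = 0.0
    mode: str = "per_gene"

    @classmethod
    def from_config(cls, cfg) -> "MutationRates":
        return cls(cfg.mu_BTL, cfg.mu_CIS, cfg.mu_TRA, cfg.mu_DUP,
                   cfg.mu_DEL, cfg.mu_HOR, cfg.mutation_mode)

    def rate(self, mtype: str) -> float:
        return getattr(self, f"mu_{mtype}")


# ---------------------------------------------------------------------------
# Operators (pure)
# ---------------------------------------------------------------------------

def mutate_btl(genome: Genome, gene_index: int, direction: int
               ) -> tuple[Genome, MutationEvent]:
    """Shift a gene's basal transcription level by +-1, floored at 0."""
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    new = genome.copy()
    gene = new.genes[gene_index]
    old = gene.basal
    gene.basal = max(0, gene.basal + direction)
    event = MutationEvent(BTL, gene_index, gene.label, None, old, gene.basal,
                          no_op=(gene.basal == old))
    return new, event


def mutate_cis(genome: Genome, gene_index: int, site_index: int,
               rng: np.random.Generator) -> tuple[Genome, MutationEvent]:
    """Redraw one cis-site's cis-number uniformly on [1, n]."""
    if not 0 <= site_index < genome.L:
        raise ValueError(f"site index {site_index} outside [0, {genome.L})")
    new = genome.copy()
    gene = new.genes[gene_index]
    old = int(gene.cis_numbers[site_index])
    gene.cis_numbers[site_index] = int(rng.integers(1, genome.n + 1))
    return new, MutationEvent(CIS, gene_index, gene.label, site_index,
                              old, int(gene.cis_numbers[site_index]))


def mutate_trans(genome: Genome, gene_index: int, rng: np.random.Generator
                 ) -> tuple[Genome, MutationEvent]:
    """Redraw a gene's trans-number uniformly on [1, n]."""
    new = genome.copy()
    gene = new.genes[gene_index]
    old = gene.trans_number
    gene.trans_number = int(rng.integers(1, genome.n + 1))
    return new, MutationEvent(TRA, gene_index, gene.label, None,
                              old, gene.trans_number)


def _check_dup_del_target(genome: Genome, gene_index: int) -> Gene:
    gene = genome.genes[gene_index]
    if gene.role != REGULATORY or gene.is_receptor:
        raise ValueError(
            "duplication/deletion targets must be non-receptor regulatory genes")
    return gene


def duplicate_gene(genome: Genome, gene_index: int
                   ) -> tuple[Genome, MutationEvent]:
    """Append an exact copy of one regulatory gene (cis region + coding)."""
    _check_dup_del_target(genome, gene_index)
    new = genome.copy()
    copy = new.genes[gene_index].copy()
    copy.label = new.fresh_reg_label()
    new.genes.append(copy)
    return new, MutationEvent(DUP, gene_index, genome.genes[gene_index].label,
                              None, None, copy.label)


def delete_gene(genome: Genome, gene_index: int) -> tuple[Genome, MutationEvent]:
    """Erase one regulatory gene entirely."""
    _check_dup_del_target(genome, gene_index)
    new = genome.copy()
    removed = new.genes.pop(gene_index)
    return new, MutationEvent(DEL, gene_index, removed.label, None,
                              removed.label, None)


def horizontal_transfer(genome: Genome, rng: np.random.Generator,
                        basal: int = 0) -> tuple[Genome, MutationEvent]:
    """Insert a fully random regulatory gene (horizontal gene transfer)."""
    new = genome.copy()
    gene = Gene(
        role=REGULATORY,
        trans_number=int(rng.integers(1, genome.n + 1)),
        basal=basal,
        cis_numbers=rng.integers(1, genome.n + 1, size=genome.L).astype(np.int64),
        coefficients=rng.uniform(COEFF_MIN, COEFF_MAX, size=genome.L),
        label=new.fresh_reg_label(),
    )
    new.genes.append(gene)
    return new, MutationEvent(HOR, None, None, None, None, gene.label)


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

def eligible_counts(genome: Genome) -> dict[str, int]:
    """Number of Bernoulli trials per mutation type for one offspring.

    BTL/CIS/TRA act on every gene; DUP/DEL only on non-receptor
    regulatory genes.  Horizontal transfer is an insertion into the
    genome as a whole, so it gets a single trial per offspring.
    """
    n_genes = genome.n_genes
    n_dupdel = sum(1 for g in genome.genes
                   if g.role == REGULATORY and not g.is_receptor)
    return {BTL: n_genes, CIS: n_genes, TRA: n_genes,
            DUP: n_dupdel, DEL: n_dupdel, HOR: 1}


def _eligible_targets(genome: Genome, mtype: str) -> list[int]:
    if mtype in (BTL, CIS, TRA):
        return list(range(genome.n_genes))
    if mtype in (DUP, DEL):
        return [i for i, g in enumerate(genome.genes)
                if g.role == REGULATORY and not g.is_receptor]
    return []   # HOR has no target gene


def apply_event(genome: Genome, mtype: str, target: int | None,
                rng: np.random.Generator, hor_basal: int = 0
                ) -> tuple[Genome, MutationEvent]:
    """Apply one typed mutation at a given (already drawn) target."""
    if mtype == BTL:
        direction = +1 if rng.random() < 0.5 else -1
        return mutate_btl(genome, target, direction)
    if mtype == CIS:
        site = int(rng.integers(0, genome.L))
        return mutate_cis(genome, target, site, rng)
    if mtype == TRA:
        return mutate_trans(genome, target, rng)
    if mtype == DUP:
        return duplicate_gene(genome, target)
    if mtype == DEL:
        return delete_gene(genome, target)
    if mtype == HOR:
        return horizontal_transfer(genome, rng, basal=hor_basal)
    raise ValueError(f"unknown mutation type {mtype!r}")


def events_from_counts(genome: Genome, counts: dict[str, int],
                       rng: np.random.Generator, hor_basal: int = 0
                       ) -> tuple[Genome, list[MutationEvent]]:
    """Apply ``counts[type]`` mutations of each type, in fixed type order.

    Targets are uniform among the genes eligible at application time; a
    deletion that leaves no eligible target turns subsequent draws into
    recorded no-op events.  Returns (new genome, events); the input genome
    is untouched.
    """
    current = genome
    events: list[MutationEvent] = []
    for mtype in MUTATION_TYPES:
        for _ in range(counts.get(mtype, 0)):
            if mtype == HOR:
                current, ev = apply_event(current, mtype, None, rng, hor_basal)
            else:
                targets = _eligible_targets(current, mtype)
                if not targets:
                    events.append(MutationEvent(mtype, no_op=True))
                    continue
                target = int(targets[rng.integers(0, len(targets))])
                current, ev = apply_event(current, mtype, target, rng, hor_basal)
            events.append(ev)
    return current, events


def draw_mutations(genome: Genome, rates: MutationRates,
                   rng: np.random.Generator, hor_basal: int = 0,
                   significance_test: Callable[[Genome], bool] | None = None,
                   redraw_cap: int = 1000
                   ) -> tuple[Genome, list[MutationEvent]]:
    """Draw and apply this offspring's mutations under the configured mode.

    ``per_gene``: independent Bernoulli per eligible gene and type.
    ``per_individual``: one Bernoulli per type at 10x the per-gene rate;
    at most the first success (fixed type order) is applied.
    ``constant_PS``: as per_individual, but a DUP/DEL/TRA success is
    re-targeted until ``significance_test`` accepts the mutant (cap
    ``redraw_cap``, after which the event is dropped with a no-op record).
    """
    if rates.mode == "per_gene":
        counts = {t: int(rng.binomial(n, rates.rate(t))) if rates.rate(t) > 0 else 0
                  for t, n in eligible_counts(genome).items()}
        return events_from_counts(genome, counts, rng, hor_basal)

    if rates.mode not in ("per_individual", "constant_PS"):
        raise ValueError(f"unknown mutation mode {rates.mode!r}")

    hit = None
    for mtype in MUTATION_TYPES:
        p = min(1.0, 10.0 * rates.rate(mtype))
        if p > 0 and rng.random() < p:
            hit = mtype
            break
    if hit is None:
        return genome, []

    targets = _eligible_targets(genome, hit)
    if hit != HOR and not targets:
        return genome, [MutationEvent(hit, no_op=True)]

    redraw = (rates.mode == "constant_PS" and hit in (DUP, DEL, TRA)
              and significance_test is not None)
    for attempt in range(redraw_cap if redraw else 1):
        target = None if hit == HOR else int(targets[rng.integers(0, len(targets))])
        mutant, ev = apply_event(genome, hit, target, rng, hor_basal)
        if not redraw or significance_test(mutant):
            return mutant, [ev]
    # redraw cap exceeded: drop the event, record the failure
    return genome, [MutationEvent(hit, no_op=True,
                                  new_value="constant_PS_redraw_cap")]
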