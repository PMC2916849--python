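"""The Wright-Fisher generation loop and whole-run orchestration.

Each generation: fitness is evaluated for every individual against the
optimum current at that generation; parents are sampled in proportion to
fitness; each offspring is a copy of its parent subjected to mutation; a
non-viable offspring (development fails to settle under either signal
condition) is discarded and sampling repeats until Z viable offspring
exist; the optimum then advances.

Development is deterministic, so development results and fitness inputs
are computed once per distinct genotype and cached; unmutated offspring
share their parent's cached genotype object.  This caching is what makes
desk-scale runs (small Z, thousands of generations) fast: per generation
the only developmental work is for the handful of mutated offspring.

Randomness flows from one master seed through named independent streams
(founder, mutation, selection, environment, assay), so a change in one
subsystem's draws does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .dynamics import DevelopmentResult, phenotype_pair
from .environment import OptimumProcess, init_optimum, step_optimum
from .genome import Genome, make_founder
from .mutation import (HOR, MutationEvent, MutationRates, apply_event,
                       draw_mutations, eligible_counts, events_from_counts,
                       MUTATION_TYPES, _eligible_targets)
from .selection import ExtinctionError, evaluate_fitness, reproduction_weights

__all__ = ["Genotype", "PopulationState", "RunSummary", "FitnessEffectEvent",
           "develop_genotype", "make_rngs", "run_generation",
           "run_simulation", "time_averaged_fitness"]


class Genotype:
    """A genome with its (deterministic) development results cached."""

    __slots__ = ("genome", "dev_on", "dev_off", "viable",
                 "phenotype_on", "phenotype_off", "total_on", "total_off")

    def __init__(self, genome: Genome, dev_on: DevelopmentResult,
                 dev_off: DevelopmentResult) -> None:
        self.genome = genome
        self.dev_on = dev_on
        self.dev_off = dev_off
        self.viable = not (dev_on.lethal or dev_off.lethal)
        self.phenotype_on = dev_on.phenotype
        self.phenotype_off = dev_off.phenotype
        self.total_on = dev_on.expression_total
        self.total_off = dev_off.expression_total


def develop_genotype(genome: Genome, cfg: SimulationConfig) -> Genotype:
    on, off = phenotype_pair(genome, cfg)
    return Genotype(genome, on, off)


@dataclass
class FitnessEffectEvent:
    """One mutation's fitness effect at its generation of incidence (c = 0)."""

    generation: int
    type: str
    F_parent: float
    F_mutant: float

    @property
    def delta(self) -> float:
        return self.F_mutant - self.F_parent


@dataclass
class PopulationState:
    genotypes: list[Genotype]
    generation: int
    mean_fitness: float = float("nan")
    mean_S: float = float("nan")
    mean_Q: float = float("nan")

    @property
    def Z(self) -> int:
        return len(self.genotypes)


@dataclass
class RunSummary:
    F_prime: float
    mean_fitness: np.ndarray          # per-generation population mean fitness
    mean_S: np.ndarray
    mean_Q: np.ndarray
    class_counts: list[tuple[int, float, float, float]]  # (gen, core, psdexp, silent)
    final_population: PopulationState
    optimum: OptimumProcess
    fitness_effects: list[FitnessEffectEvent] | None
    founder: Genome = None
    config: SimulationConfig = None
    seed: int | None = None


def make_rngs(seed: int | None) -> dict[str, np.random.Generator]:
    """Spawn the named independent RNG streams from one master seed."""
    root = np.random.SeedSequence(seed)
    names = ("founder", "mutation", "selection", "environment", "assay")
    children = root.spawn(len(names))
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(names, children)}


def time_averaged_fitness(mean_fitness_series) -> float:
    """F' — the arithmetic mean of the per-generation mean fitness."""
    series = np.asarray(mean_fitness_series, dtype=np.float64)
    if series.size == 0:
        raise ValueError("empty mean-fitness series")
    return float(series.mean())


def _population_fitness(pop: PopulationState, proc: OptimumProcess,
                        cfg: SimulationConfig
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectors of (F, S, Q), computed once per distinct genotype."""
    cache: dict[int, tuple[float, float, float]] = {}
    F = np.empty(pop.Z)
    S = np.empty(pop.Z)
    Q = np.empty(pop.Z)
    for i, gt in enumerate(pop.genotypes):
        key = id(gt)
        rec = cache.get(key)
        if rec is None:
            r = evaluate_fitness(gt.phenotype_on, gt.phenotype_off,
                                 gt.total_on, gt.total_off,
                                 proc.theta_on, proc.theta_off, cfg,
                                 viable=gt.viable)
            rec = (r.F, r.S, r.Q)
            cache[key] = rec
        F[i], S[i], Q[i] = rec
    return F, S, Q


def _significance_test_factory(parent: Genotype, cfg: SimulationConfig):
    """Build the Significant-phenotype predicate used by constant_PS mode."""
    from .assays import classify_phenotype_effect  # local import, cycle-free

    def is_significant(mutant_genome: Genome) -> bool:
        mutant = develop_genotype(mutant_genome, cfg)
        return classify_phenotype_effect(parent, mutant, cfg) == "significant"

    return is_significant


def run_generation(pop: PopulationState, proc: OptimumProcess,
                   cfg: SimulationConfig,
                   rng_mut: np.random.Generator,
                   rng_sel: np.random.Generator,
                   rng_env: np.random.Generator,
                   tracker: list[FitnessEffectEvent] | None = None
                   ) -> PopulationState:
    """Advance the population by one generation (returns a new state).

    Records the parent generation's mean fitness on the returned state.
    If ``tracker`` is given, every mutation's fitness effect (mutant vs
    parent, c = 0, against the optimum at this generation) is appended.
    """
    Z = pop.Z
    F, S, Q = _population_fitness(pop, proc, cfg)
    try:
        W = reproduction_weights(F)
    except ExtinctionError:
        raise ExtinctionError(
            f"population extinct at generation {pop.generation}: "
            f"all {Z} individuals have zero fitness")

    rates = MutationRates.from_config(cfg)
    per_gene = rates.mode == "per_gene"
    rate_vec = np.array([rates.rate(t) for t in MUTATION_TYPES])
    active = rate_vec.sum() > 0

    offspring: list[Genotype] = []
    attempts = 0
    cap = cfg.extinction_cap_factor * Z
    gen = pop.generation + 1

    while len(offspring) < Z:
        need = Z - len(offspring)
        attempts += need
        if attempts > cap:
            raise ExtinctionError(
                f"generation {gen}: {attempts} sampling attempts without "
                f"{Z} viable offspring")
        parent_idx = rng_sel.choice(Z, size=need, p=W)
        if not active:
            offspring.extend(pop.genotypes[i] for i in parent_idx)
            continue

        # Vectorized screening: which offspring carry >= 1 mutation event.
        if per_gene:
            elig = np.empty((len(MUTATION_TYPES), need), dtype=np.int64)
            count_cache: dict[int, list[int]] = {}
            for col, i in enumerate(parent_idx):
                gt = pop.genotypes[i]
                key = id(gt)
                counts = count_cache.get(key)
                if counts is None:
                    ec = eligible_counts(gt.genome)
                    counts = [ec[t] for t in MUTATION_TYPES]
                    count_cache[key] = counts
                elig[:, col] = counts
            hits = np.zeros(need, dtype=bool)
            counts_mat = np.zeros_like(elig)
            for t_i, rate in enumerate(rate_vec):
                if rate > 0:
                    counts_mat[t_i] = rng_mut.binomial(elig[t_i], rate)
            hits = counts_mat.sum(axis=0) > 0
        else:
            p_any = 1.0 - np.prod(1.0 - np.minimum(1.0, 10.0 * rate_vec))
            hits = rng_mut.random(need) < p_any

        for col in np.flatnonzero(~hits):
            offspring.append(pop.genotypes[parent_idx[col]])

        for col in np.flatnonzero(hits):
            parent = pop.genotypes[parent_idx[col]]
            if per_gene:
                counts = {t: int(counts_mat[t_i, col])
                          for t_i, t in enumerate(MUTATION_TYPES)}
                mutant_genome, events = events_from_counts(
                    parent.genome, counts, rng_mut, cfg.hor_basal)
            else:
                # conditional on >= 1 type firing: redraw until a hit
                sig = (_significance_test_factory(parent, cfg)
                       if rates.mode == "constant_PS" else None)
                while True:
                    mutant_genome, events = draw_mutations(
                        parent.genome, rates, rng_mut, cfg.hor_basal,
                        significance_test=sig,
                        redraw_cap=cfg.constant_ps_cap)
                    if events:
                        break
            real_events = [e for e in events if not e.no_op]
            if not real_events:
                offspring.append(parent)
                continue
            mutant = develop_genotype(mutant_genome, cfg)
            if tracker is not None:
                _track_events(tracker, parent, mutant, real_events, proc,
                              cfg, gen, rng_mut)
            if mutant.viable:
                offspring.append(mutant)
            # non-viable: slot stays open, resampled next round

    new_pop = PopulationState(offspring, gen,
                              mean_fitness=float(F.mean()),
                              mean_S=float(S.mean()),
                              mean_Q=float(Q.mean()))
    step_optimum(proc, gen, rng_env)
    return new_pop


def _track_events(tracker: list[FitnessEffectEvent], parent: Genotype,
                  mutant: Genotype, events: list[MutationEvent],
                  proc: OptimumProcess, cfg: SimulationConfig,
                  generation: int, rng: np.random.Generator) -> None:
    """Record each mutation's c = 0 fitness effect at its incidence time."""
    f_parent = evaluate_fitness(
        parent.phenotype_on, parent.phenotype_off, parent.total_on,
        parent.total_off, proc.theta_on, proc.theta_off, cfg,
        viable=parent.viable, c=0.0).F
    if len(events) == 1:
        mutants = [mutant]
    else:
        # rare multi-hit offspring: evaluate each mutation singly
        mutants = []
        for ev in events:
            if ev.type == HOR:
                g, _ = apply_event(parent.genome, HOR, None, rng, cfg.hor_basal)
            else:
                targets = _eligible_targets(parent.genome, ev.type)
                if ev.gene_index is not None and ev.gene_index in targets:
                    target = ev.gene_index
                else:
                    target = int(targets[rng.integers(0, len(targets))]) if targets else None
                if target is None:
                    continue
                g, _ = apply_event(parent.genome, ev.type, target, rng,
                                   cfg.hor_basal)
            mutants.append(develop_genotype(g, cfg))
    for ev, mt in zip(events, mutants):
        f_mut = evaluate_fitness(
            mt.phenotype_on, mt.phenotype_off, mt.total_on, mt.total_off,
            proc.theta_on, proc.theta_off, cfg, viable=mt.viable, c=0.0).F
        tracker.append(FitnessEffectEvent(generation, ev.type, f_parent, f_mut))


def run_simulation(cfg: SimulationConfig, founder: Genome | None = None
                   ) -> RunSummary:
    """Run a full simulation from founder construction to RunSummary.

    Fully reproducible from (config, seed).  The mean-fitness series
    includes generation 0, so F' averages from the founding generation
    onwards.
    """
    from .assays import classify_genes  # local import, cycle-free

    rngs = make_rngs(cfg.seed)
    if founder is None:
        founder = make_founder(cfg, rngs["founder"])
    founder_gt = develop_genotype(founder, cfg)
    if not founder_gt.viable:
        raise ValueError("provided founder genome is not viable")

    proc = init_optimum(founder_gt.phenotype_on, cfg.regime, cfg.d, cfg.f,
                        rngs["environment"], theta_min=cfg.theta_min,
                        e_max=cfg.E_max)
    pop = PopulationState([founder_gt] * cfg.Z, generation=0)
    tracker: list[FitnessEffectEvent] | None = (
        [] if cfg.track_fitness_effects else None)

    mean_F = np.empty(cfg.generations + 1)
    mean_S = np.empty(cfg.generations + 1)
    mean_Q = np.empty(cfg.generations + 1)
    class_counts: list[tuple[int, float, float, float]] = []

    def census(state: PopulationState) -> tuple[float, float, float]:
        cache: dict[int, tuple[int, int, int]] = {}
        totals = np.zeros(3)
        for gt in state.genotypes:
            key = id(gt)
            rec = cache.get(key)
            if rec is None:
                cls = classify_genes(gt.genome, cfg)
                rec = (cls.n_core, cls.n_psdexp, cls.n_silent)
                cache[key] = rec
            totals += rec
        return tuple(totals / state.Z)

    class_counts.append((0, *census(pop)))
    for g in range(1, cfg.generations + 1):
        pop = run_generation(pop, proc, cfg, rngs["mutation"],
                             rngs["selection"], rngs["environment"], tracker)
        mean_F[g - 1] = pop.mean_fitness   # fitness of generation g-1
        mean_S[g - 1] = pop.mean_S
        mean_Q[g - 1] = pop.mean_Q
        if g % cfg.class_cadence == 0:
            class_counts.append((g, *census(pop)))

    # final generation's own fitness against the current optimum
    F, S, Q = _population_fitness(pop, proc, cfg)
    mean_F[-1], mean_S[-1], mean_Q[-1] = F.mean(), S.mean(), Q.mean()
    pop.mean_fitness, pop.mean_S, pop.mean_Q = mean_F[-1], mean_S[-1], mean_Q[-1]
    if cfg.generations % cfg.class_cadence != 0:
        class_counts.append((cfg.generations, *census(pop)))

    return RunSummary(
        F_prime=time_averaged_fitness(mean_F),
        mean_fitness=mean_F, mean_S=mean_S, mean_Q=mean_Q,
        class_counts=class_counts,
        final_population=pop,
        optimum=proc,
        fitness_effects=tracker,
        founder=founder,
        config=cfg,
        seed=cfg.seed,
    )
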