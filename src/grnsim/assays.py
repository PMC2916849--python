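"""Analyses of evolved populations: gene classes, mutational spectra,
fitness effects, evolvability, and the adaptation-rate benchmark.

Regulatory genes partition into three classes by their behaviour in the
signal-on developmental run: *silent* genes are not expressed at steady
state (windowed mean <= eps_expr); *core* genes are expressed and reach at
least one phenotypic gene through a directed regulatory path whose
intermediate nodes are themselves expressed regulators; *pseudo-expression*
genes are expressed but have no such path.

Single mutations are classified by phenotypic effect: *Loss-of-phenotype*
(some phenotypic gene's signal-on steady level drops below 1e-2, or
development fails to settle), *Non-effect* (phenotype displacement within
eps_same), and *Significant* (the rest); P_L + P_N + P_S = 1, and D_S is
the mean Euclidean phenotype displacement of Significant mutations.  The
evolvability of a population is summarized as (mutational target size) x
P_S = n_core * P_S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .dynamics import develop
from .environment import init_optimum
from .genome import Genome, REGULATORY, interaction_graph
from .mutation import (BTL, CIS, DEL, DUP, TRA, MUTATION_TYPES,
                       apply_event, _eligible_targets)

__all__ = ["GeneClassification", "MutationEffectSummary",
           "FitnessEffectSummary", "AdaptationTrajectory",
           "classify_genes", "classify_phenotype_effect",
           "mutation_effect_assay", "classify_fitness_effect",
           "track_fitness_effects", "evolvability_index",
           "adaptation_benchmark"]


# ---------------------------------------------------------------------------
# Gene classification
# ---------------------------------------------------------------------------

@dataclass
class GeneClassification:
    core: set[str]
    pseudo_expression: set[str]
    silent: set[str]

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_psdexp(self) -> int:
        return len(self.pseudo_expression)

    @property
    def n_silent(self) -> int:
        return len(self.silent)


def classify_genes(genome: Genome, cfg: SimulationConfig) -> GeneClassification:
    """Partition the regulatory genes into core / pseudo-expression / silent."""
    result = develop(genome, signal_on=True, cfg=cfg)
    if result.lethal:
        raise ValueError("cannot classify genes of a non-viable genome")
    means = result.gene_means
    expressed: set[str] = set()
    silent: set[str] = set()
    for idx, gene in zip(range(genome.n_genes), genome.genes):
        if gene.role != REGULATORY:
            continue
        (expressed if means[idx] > cfg.eps_expr else silent).add(gene.label)

    graph = interaction_graph(genome)
    phen_labels = {genome.genes[i].label for i in genome.phenotypic_indices}
    # Backward reachability from the phenotypic genes through expressed
    # regulators: a core gene has a directed path to some phenotypic gene
    # whose intermediate nodes are all expressed regulators.
    reaches = set(phen_labels)
    frontier = set(phen_labels)
    while frontier:
        new = set()
        for node in frontier:
            for pred in graph.predecessors(node):
                if pred in expressed and pred not in reaches:
                    new.add(pred)
        reaches |= new
        frontier = new
    core = expressed & reaches
    return GeneClassification(core=core,
                              pseudo_expression=expressed - core,
                              silent=silent)


# ---------------------------------------------------------------------------
# Single-mutation phenotypic effects
# ---------------------------------------------------------------------------

def classify_phenotype_effect(parent, mutant, cfg: SimulationConfig,
                              return_displacement: bool = False):
    """Classify one mutation as 'loss', 'none', or 'significant'.

    ``parent`` and ``mutant`` are developed genotypes
    (:class:`~grnsim.evolution.Genotype`).  Loss-of-phenotype: the mutant
    fails to settle under either condition or some phenotypic gene's
    signal-on steady level falls below the loss threshold.  Non-effect:
    concatenated two-condition phenotype displacement <= eps_same.
    """
    if not mutant.viable:
        return ("loss", float("nan")) if return_displacement else "loss"
    if np.any(mutant.phenotype_on < cfg.loss_threshold):
        return ("loss", float("nan")) if return_displacement else "loss"
    delta = float(np.linalg.norm(np.concatenate([
        mutant.phenotype_on - parent.phenotype_on,
        mutant.phenotype_off - parent.phenotype_off])))
    kind = "none" if delta <= cfg.eps_same else "significant"
    return (kind, delta) if return_displacement else kind


@dataclass
class MutationEffectSummary:
    """Per-type mutational-effect spectrum over sampled individuals."""

    counts: dict[str, dict[str, int]]          # type -> {loss, none, significant}
    displacements: dict[str, list[float]]      # type -> Significant |dphi|
    skipped: int = 0                           # individuals without core genes

    def P_L(self, mtype: str) -> float:
        return self._prop(mtype, "loss")

    def P_N(self, mtype: str) -> float:
        return self._prop(mtype, "none")

    def P_S(self, mtype: str) -> float:
        return self._prop(mtype, "significant")

    def D_S(self, mtype: str, use_median: bool = False) -> float:
        d = self.displacements[mtype]
        if not d:
            return float("nan")
        return float(np.median(d) if use_median else np.mean(d))

    def sample_size(self, mtype: str) -> int:
        return sum(self.counts[mtype].values())

    def _prop(self, mtype: str, kind: str) -> float:
        n = self.sample_size(mtype)
        return self.counts[mtype][kind] / n if n else float("nan")


def mutation_effect_assay(population, cfg: SimulationConfig,
                          rng: np.random.Generator,
                          types: tuple[str, ...] = (BTL, CIS, TRA, DEL, DUP),
                          n_individuals: int = 1000,
                          restrict_to_core: bool = True
                          ) -> MutationEffectSummary:
    """Introduce single mutations into sampled individuals and classify them.

    For each type, ``n_individuals`` individuals are drawn uniformly (with
    replacement) from the population; each receives one mutation of that
    type at a uniformly random core-gene target (site uniform for CIS) and
    the mutant phenotype is compared with the original.  Individuals with
    no core gene are skipped and counted.
    """
    from .evolution import develop_genotype  # cycle-free

    genotypes = (population.genotypes
                 if hasattr(population, "genotypes") else list(population))
    unknown = set(types) - set(MUTATION_TYPES)
    if unknown:
        raise ValueError(f"unknown mutation types {sorted(unknown)}")

    class_cache: dict[int, set[str]] = {}
    counts = {t: {"loss": 0, "none": 0, "significant": 0} for t in types}
    displacements: dict[str, list[float]] = {t: [] for t in types}
    skipped = 0

    for mtype in types:
        picks = rng.integers(0, len(genotypes), size=n_individuals)
        for i in picks:
            parent = genotypes[int(i)]
            genome = parent.genome
            if restrict_to_core:
                key = id(parent)
                core = class_cache.get(key)
                if core is None:
                    core = classify_genes(genome, cfg).core
                    class_cache[key] = core
                targets = [j for j, g in enumerate(genome.genes)
                           if g.label in core]
                if mtype in (DUP, DEL):
                    targets = [j for j in targets
                               if not genome.genes[j].is_receptor]
            else:
                targets = _eligible_targets(genome, mtype)
            if not targets:
                skipped += 1
                continue
            target = int(targets[rng.integers(0, len(targets))])
            mutant_genome, _ = apply_event(genome, mtype, target, rng,
                                           cfg.hor_basal)
            mutant = develop_genotype(mutant_genome, cfg)
            kind, delta = classify_phenotype_effect(parent, mutant, cfg,
                                                    return_displacement=True)
            counts[mtype][kind] += 1
            if kind == "significant":
                displacements[mtype].append(delta)

    return MutationEffectSummary(counts, displacements, skipped)


# ---------------------------------------------------------------------------
# Fitness effects of mutations during evolution
# ---------------------------------------------------------------------------

def classify_fitness_effect(F_mutant: float, F_parent: float,
                            neutral_band: float = 1e-2) -> str:
    """Beneficial / neutral / deleterious by the fitness difference.

    Effects smaller in magnitude than the neutral band (default 1e-2) are
    regarded as neutral; the classification is qualitatively stable for
    bands between 1e-4 and 1e-1.
    """
    delta = F_mutant - F_parent
    if delta >= neutral_band:
        return "beneficial"
    if delta <= -neutral_band:
        return "deleterious"
    return "neutral"


@dataclass
class FitnessEffectSummary:
    """Counts of beneficial/neutral/deleterious mutations per type."""

    Nt: dict[str, int]
    Nb: dict[str, int]
    Nn: dict[str, int]
    Nd: dict[str, int]

    def Pb(self, mtype: str) -> float:
        return self.Nb[mtype] / self.Nt[mtype] if self.Nt[mtype] else float("nan")

    @property
    def dup_del_count_contrast(self) -> int:
        """Nb(DUP) - Nb(DEL): excess of beneficial duplications."""
        return self.Nb[DUP] - self.Nb[DEL]

    @property
    def dup_del_prop_contrast(self) -> float:
        return self.Pb(DUP) - self.Pb(DEL)


def track_fitness_effects(run_summary, neutral_band: float | None = None
                          ) -> FitnessEffectSummary:
    """Aggregate the fitness effects logged during a c = 0 tracking run."""
    if run_summary.fitness_effects is None:
        raise ValueError(
            "run was not executed in fitness-effect tracking mode "
            "(set track_fitness_effects = true)")
    band = (run_summary.config.neutral_band
            if neutral_band is None else neutral_band)
    Nt = {t: 0 for t in MUTATION_TYPES}
    Nb = {t: 0 for t in MUTATION_TYPES}
    Nn = {t: 0 for t in MUTATION_TYPES}
    Nd = {t: 0 for t in MUTATION_TYPES}
    for ev in run_summary.fitness_effects:
        Nt[ev.type] += 1
        kind = classify_fitness_effect(ev.F_mutant, ev.F_parent, band)
        {"beneficial": Nb, "neutral": Nn, "deleterious": Nd}[kind][ev.type] += 1
    return FitnessEffectSummary(Nt, Nb, Nn, Nd)


# ---------------------------------------------------------------------------
# Evolvability and the adaptation benchmark
# ---------------------------------------------------------------------------

def evolvability_index(n_core: int, P_S: float) -> float:
    """Evolvability = mutational target size (core genes) x P_S."""
    if n_core < 0 or not 0.0 <= P_S <= 1.0:
        raise ValueError("n_core must be >= 0 and P_S in [0, 1]")
    return n_core * P_S


@dataclass
class AdaptationTrajectory:
    """Distance of the population mean phenotype to a benchmark optimum."""

    D: np.ndarray            # D[i], i = 0..generations
    optimum: np.ndarray

    @property
    def D0(self) -> float:
        return float(self.D[0])

    @property
    def D_final(self) -> float:
        return float(self.D[-1])


def _mean_phenotype_on(pop) -> np.ndarray:
    return np.mean([gt.phenotype_on for gt in pop.genotypes], axis=0)


def adaptation_benchmark(pop, cfg: SimulationConfig,
                         rng: np.random.Generator,
                         generations: int = 1000,
                         d: float = 1.0) -> AdaptationTrajectory:
    """Measure the rate of phenotypic adaptation to a displaced optimum.

    A new static optimum is placed at distance ``d`` (default 1) from the
    population's mean signal-on phenotype, in a uniformly random direction
    kept inside the environment bounds; the population then evolves for
    ``generations`` generations and D_i, the distance between the optimum
    and the mean phenotype, is recorded each generation.
    """
    from .environment import _in_bounds, _random_direction
    from .evolution import PopulationState, run_generation

    mean_phi = _mean_phenotype_on(pop)
    m = mean_phi.size
    for _ in range(10_000):
        target = mean_phi + d * _random_direction(m, rng)
        if _in_bounds(target, cfg.theta_min, cfg.E_max):
            break
    else:
        raise RuntimeError("could not place the benchmark optimum in bounds")

    bench_cfg = cfg.replace(regime="static", d=0.0)
    proc = init_optimum(target, "static", 0.0, 0.0, rng,
                        theta_min=cfg.theta_min, e_max=cfg.E_max)
    state = PopulationState(list(pop.genotypes), generation=0)
    D = np.empty(generations + 1)
    D[0] = float(np.linalg.norm(_mean_phenotype_on(state) - target))
    for g in range(1, generations + 1):
        state = run_generation(state, proc, bench_cfg, rng, rng, rng)
        D[g] = float(np.linalg.norm(_mean_phenotype_on(state) - target))
    return AdaptationTrajectory(D=D, optimum=target)
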