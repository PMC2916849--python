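"""Genome data structures, motif-space arithmetic, and founder construction.

A genome is an ordered list of genes, each composed of a cis-regulatory
region (L cis-sites, each a motif identifier plus a fixed real interaction
coefficient) and a coding region (a single trans-number).  A regulatory
gene's product binds every cis-site whose cis-number equals the gene's
trans-number; the realized regulatory interactions form a directed graph
extracted by :func:`interaction_graph`.

The motif space has ``n = round((1/2) * 4**m)`` distinct words for a binding
motif of ``m`` base pairs (the factor 1/2 accounts for motif orientation
against the promoter).  The probability that a particular transcription
factor has at least one binding site in an L-site region is

    C_mut = 1 - (1 - 1/n)**L

which also sets the per-mutation rate of interaction gain, so the gain/loss
bias of regulatory interactions is alpha ~= (1 - C_mut) / C_mut.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "REGULATORY", "PHENOTYPIC", "FORMAT_VERSION",
    "CisSite", "Gene", "Genome", "InitializationError",
    "motif_space_size", "cmut_from_L", "L_for_cmut",
    "n_init_for_connectivity", "cmut_to_alpha",
    "make_founder", "interaction_graph",
    "edge_list_tsv", "write_graphml",
]

REGULATORY = "regulatory"
PHENOTYPIC = "phenotypic"
FORMAT_VERSION = 1

COEFF_MIN, COEFF_MAX = -5.0, 5.0


class InitializationError(RuntimeError):
    """No viable founder individual found within the attempt cap."""


class CisSite(NamedTuple):
    """One potential transcription-factor binding site."""

    cis_number: int
    coefficient: float


# ---------------------------------------------------------------------------
# Motif-space arithmetic
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def motif_space_size(m: float, sig_figs: int | None = None) -> int:
    """Number of distinct DNA motifs of length ``m`` base pairs.

    Computed as ``round((1/2) * 4**m)``; the 1/2 accounts for the two
    orientations of a motif relative to the promoter.  With
    ``sig_figs`` the result is additionally rounded to that many
    significant figures (e.g. m = 7.14 gives 9947, or 9950 at 3 figures).
    """
    if m <= 0:
        raise ValueError(f"motif length m must be positive, got {m}")
    n = 0.5 * 4.0 ** m
    if sig_figs is not None:
        n = _round_sig(n, sig_figs)
    return int(round(n))


def cmut_from_L(L: int, n: int) -> float:
    """Probability that a given TF has >= 1 binding site among L cis-sites."""
    if n < 1:
        raise ValueError(f"motif-space size n must be >= 1, got {n}")
    if L < 0:
        raise ValueError(f"site count L must be >= 0, got {L}")
    return 1.0 - (1.0 - 1.0 / n) ** L


def L_for_cmut(C_mut: float, n: int) -> int:
    """Invert :func:`cmut_from_L`: the L giving presence probability C_mut."""
    if not 0.0 < C_mut < 1.0:
        raise ValueError(f"C_mut must lie in (0, 1), got {C_mut}")
    if n < 2:
        raise ValueError(f"motif-space size n must be >= 2, got {n}")
    return int(round(math.log(1.0 - C_mut) / math.log(1.0 - 1.0 / n)))


def n_init_for_connectivity(C_init: float, L: int) -> int:
    """Motif-space size under which an L-site region realizes connectivity C_init.

    Founder genomes are drawn from a reduced motif space of this size so
    that each (regulator, gene) pair is connected with probability C_init.
    """
    if not 0.0 < C_init < 1.0:
        raise ValueError(f"C_init must lie in (0, 1), got {C_init}")
    if L < 1:
        raise ValueError(f"site count L must be >= 1, got {L}")
    return int(round(1.0 / (1.0 - (1.0 - C_init) ** (1.0 / L))))


def cmut_to_alpha(C_mut: float) -> float:
    """Interaction loss/gain rate ratio alpha ~= (1 - C_mut) / C_mut."""
    if not 0.0 < C_mut < 1.0:
        raise ValueError(f"C_mut must lie in (0, 1), got {C_mut}")
    return (1.0 - C_mut) / C_mut


# ---------------------------------------------------------------------------
# Gene / Genome
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """One gene: a coding region (trans-number) plus L cis-sites.

    ``cis_numbers`` and ``coefficients`` are parallel arrays of length L.
    Coefficients are fixed at gene creation and never mutated; only the
    cis-numbers (and the trans-number) change under regulatory mutation.
    Phenotypic genes carry a trans-number for structural uniformity but
    their products never act as transcription factors.
    """

    role: str
    trans_number: int
    basal: int
    cis_numbers: np.ndarray
    coefficients: np.ndarray
    is_receptor: bool = False
    label: str = ""

    @property
    def cis_sites(self) -> list[CisSite]:
        return [CisSite(int(c), float(w))
                for c, w in zip(self.cis_numbers, self.coefficients)]

    def copy(self) -> "Gene":
        return Gene(self.role, self.trans_number, self.basal,
                    self.cis_numbers.copy(), self.coefficients.copy(),
                    self.is_receptor, self.label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Gene):
            return NotImplemented
        return (self.role == other.role
                and self.trans_number == other.trans_number
                and self.basal == other.basal
                and self.is_receptor == other.is_receptor
                and self.label == other.label
                and np.array_equal(self.cis_numbers, other.cis_numbers)
                and np.array_equal(self.coefficients, other.coefficients))


@dataclass(eq=False)
class Genome:
    """Ordered gene list plus the shared structural parameters L and n."""

    genes: list[Gene]
    L: int
    n: int
    next_reg_label: int = 0   # counter for labelling new regulatory genes

    def __post_init__(self) -> None:
        if self.next_reg_label == 0:
            self.next_reg_label = 1 + sum(
                1 for g in self.genes if g.role == REGULATORY)

    # -- structure queries ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def regulatory_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.genes) if g.role == REGULATORY]

    @property
    def phenotypic_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.genes) if g.role == PHENOTYPIC]

    @property
    def n_regulatory(self) -> int:
        return len(self.regulatory_indices)

    @property
    def n_phenotypic(self) -> int:
        return len(self.phenotypic_indices)

    @property
    def receptor_index(self) -> int:
        for i, g in enumerate(self.genes):
            if g.is_receptor:
                return i
        raise ValueError("genome has no receptor gene")

    def copy(self) -> "Genome":
        return Genome([g.copy() for g in self.genes], self.L, self.n,
                      self.next_reg_label)

    def fresh_reg_label(self) -> str:
        label = f"R{self.next_reg_label}"
        self.next_reg_label += 1
        return label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (self.L == other.L and self.n == other.n
                and self.genes == other.genes)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "params": {"L": self.L, "n": self.n,
                       "next_reg_label": self.next_reg_label},
            "genes": [
                {
                    "role": g.role,
                    "label": g.label,
                    "trans_number": int(g.trans_number),
                    "basal": int(g.basal),
                    "is_receptor": bool(g.is_receptor),
                    "cis_sites": [[int(c), float(w)] for c, w in
                                  zip(g.cis_numbers, g.coefficients)],
                }
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Genome":
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported genome format_version {doc.get('format_version')}")
        genes = []
        for gd in doc["genes"]:
            sites = gd["cis_sites"]
            genes.append(Gene(
                role=gd["role"],
                trans_number=int(gd["trans_number"]),
                basal=int(gd["basal"]),
                cis_numbers=np.array([s[0] for s in sites], dtype=np.int64),
                coefficients=np.array([s[1] for s in sites], dtype=np.float64),
                is_receptor=bool(gd["is_receptor"]),
                label=gd.get("label", ""),
            ))
        params = doc["params"]
        return cls(genes, int(params["L"]), int(params["n"]),
                   int(params.get("next_reg_label", 0)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Founder construction
# ---------------------------------------------------------------------------

def _random_founder_candidate(cfg, rng: np.random.Generator) -> Genome:
    n_init = n_init_for_connectivity(cfg.C_init, cfg.L)
    n_total = cfg.N_ini + cfg.M_ini
    genes: list[Gene] = []
    for i in range(cfg.N_ini):
        genes.append(Gene(
            role=REGULATORY,
            trans_number=int(rng.integers(1, n_init + 1)),
            basal=0,
            cis_numbers=rng.integers(1, n_init + 1, size=cfg.L).astype(np.int64),
            coefficients=rng.uniform(COEFF_MIN, COEFF_MAX, size=cfg.L),
            is_receptor=(i == 0),
            label=f"R{i + 1}",
        ))
    for i in range(cfg.M_ini):
        genes.append(Gene(
            role=PHENOTYPIC,
            trans_number=int(rng.integers(1, n_init + 1)),
            basal=0,
            cis_numbers=rng.integers(1, n_init + 1, size=cfg.L).astype(np.int64),
            coefficients=rng.uniform(COEFF_MIN, COEFF_MAX, size=cfg.L),
            label=f"P{i + 1}",
        ))
    # half of the genes start with basal transcription b = 1
    half = n_total // 2
    if cfg.b_assignment == "random":
        chosen = rng.choice(n_total, size=half, replace=False)
    else:
        chosen = np.arange(half)
    for i in chosen:
        genes[int(i)].basal = 1

    genome = Genome(genes, cfg.L, cfg.n)

    # Re-randomize every cis-number not participating in a realized
    # interaction into the full motif space [1, n], excluding all current
    # trans-numbers; leaves realized connectivity (~C_init) intact while
    # diversifying the unused sites.
    reg_trans = {g.trans_number for g in genes if g.role == REGULATORY}
    all_trans = {g.trans_number for g in genes}
    for g in genes:
        unused = ~np.isin(g.cis_numbers, list(reg_trans))
        k = int(unused.sum())
        if k == 0:
            continue
        draws = rng.integers(1, cfg.n + 1, size=k)
        for j in range(k):
            while int(draws[j]) in all_trans:
                draws[j] = rng.integers(1, cfg.n + 1)
        g.cis_numbers[unused] = draws
    return genome


def make_founder(cfg, rng: np.random.Generator) -> Genome:
    """Generate a viable founder genome by rejection sampling.

    A candidate genome is drawn with connectivity C_init (cis- and
    trans-numbers uniform on [1, n_init]); it is accepted only if both
    developmental runs reach steady state and all phenotypic steady-state
    levels are < 0.01 with the signal absent and > 2.0 with it present.
    """
    from .dynamics import develop  # local import to avoid a cycle

    for _ in range(cfg.founder_max_attempts):
        genome = _random_founder_candidate(cfg, rng)
        on = develop(genome, signal_on=True, cfg=cfg)
        if on.lethal or not np.all(on.phenotype > 2.0):
            continue
        off = develop(genome, signal_on=False, cfg=cfg)
        if off.lethal or not np.all(off.phenotype < 0.01):
            continue
        return genome
    raise InitializationError(
        f"no viable founder in {cfg.founder_max_attempts} attempts")


# ---------------------------------------------------------------------------
# Interaction graph
# ---------------------------------------------------------------------------

def interaction_graph(genome: Genome) -> nx.DiGraph:
    """Extract the realized regulatory-interaction graph.

    Nodes are gene labels; a directed edge regulator -> target exists iff
    the target has >= 1 cis-site whose cis-number equals the regulator's
    trans-number.  Edge attributes: ``weight`` (algebraic sum of the
    matching sites' coefficients) and ``multiplicity`` (their count).
    Phenotypic genes are never edge sources.
    """
    graph = nx.DiGraph()
    for g in genome.genes:
        graph.add_node(g.label, role=g.role, is_receptor=g.is_receptor)
    for r_idx in genome.regulatory_indices:
        reg = genome.genes[r_idx]
        for target in genome.genes:
            match = target.cis_numbers == reg.trans_number
            mult = int(match.sum())
            if mult >= 1:
                graph.add_edge(
                    reg.label, target.label,
                    weight=float(target.coefficients[match].sum()),
                    multiplicity=mult,
                )
    return graph


def edge_list_tsv(graph: nx.DiGraph) -> str:
    """Render a graph as a 3-column TSV edge list (source, target, weight)."""
    lines = ["source\ttarget\tweight"]
    for u, v, data in graph.edges(data=True):
        lines.append(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}")
    return "\n".join(lines) + "\n"


def write_graphml(graph: nx.DiGraph, path: str) -> None:
    nx.write_graphml(graph, path)
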