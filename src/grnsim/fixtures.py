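"""Deterministic small fixtures used by the test suite and the CLI.

These are hand-built miniature genomes and synthetic histograms:

* ``fig1_like`` — a 5-regulator, 2-phenotypic-gene module exhibiting all
  three regulatory-gene classes: a receptor-driven activation cascade
  (core R1-R3), a self-sustaining regulator disconnected from the
  phenotypic genes (pseudo-expression R4), and an untranscribed gene
  (silent R5).
* ``oscillator`` — a self-repressing regulator driving the phenotypic
  genes into a persistent limit cycle, so development never settles
  (a constructed lethal genome).
* ``star_graph`` — one hub regulator targeting ten genes.
* ``degree_histograms`` — noiseless Poisson and power-law degree
  histograms for parameter-recovery checks.
* ``founder`` — a genome drawn by the model's own founder-initialization
  procedure at the standard parameter values.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .config import SimulationConfig
from .genome import Gene, Genome, PHENOTYPIC, REGULATORY, make_founder

__all__ = ["make_fig1_genome", "make_oscillator_genome", "make_star_graph",
           "make_poisson_hist", "make_powerlaw_hist", "write_fixture"]

_L, _N = 5, 1000   # miniature cis-region size and motif space


def _gene(role: str, label: str, trans: int, basal: int,
          sites: list[tuple[int, float]], receptor: bool = False) -> Gene:
    # pad unused sites with high motif numbers matched by no regulator
    padded = sites + [(900 + i, 0.1) for i in range(_L - len(sites))]
    return Gene(
        role=role, trans_number=trans, basal=basal,
        cis_numbers=np.array([s[0] for s in padded], dtype=np.int64),
        coefficients=np.array([s[1] for s in padded]),
        is_receptor=receptor, label=label,
    )


def make_fig1_genome() -> Genome:
    """Module with core R1-R3, pseudo-expression R4 and silent R5."""
    genes = [
        _gene(REGULATORY, "R1", 1, 1, [], receptor=True),
        _gene(REGULATORY, "R2", 2, 0, [(1, 5.0)]),          # activated by R1
        _gene(REGULATORY, "R3", 3, 0, [(1, 5.0)]),
        _gene(REGULATORY, "R4", 4, 1, [(4, 3.0)]),          # self-sustaining
        _gene(REGULATORY, "R5", 5, 0, [(4, -5.0)]),         # repressed, silent
        _gene(PHENOTYPIC, "P1", 6, 0, [(2, 5.0), (3, 5.0)]),
        _gene(PHENOTYPIC, "P2", 7, 0, [(2, 5.0)]),
    ]
    return Genome(genes, L=_L, n=_N)


def make_oscillator_genome() -> Genome:
    """Self-repressing regulator driving the phenotypic genes: never settles.

    R2 expresses strongly from its basal level and represses itself with
    five maximal-strength sites, producing a period-2 relaxation
    oscillation that the phenotypic genes inherit, so the windowed
    variance never falls below V.
    """
    genes = [
        _gene(REGULATORY, "R1", 1, 0, [], receptor=True),
        Gene(role=REGULATORY, trans_number=2, basal=20,
             cis_numbers=np.full(_L, 2, dtype=np.int64),
             coefficients=np.full(_L, -5.0), label="R2"),
        Gene(role=PHENOTYPIC, trans_number=6, basal=0,
             cis_numbers=np.full(_L, 2, dtype=np.int64),
             coefficients=np.full(_L, 5.0), label="P1"),
        Gene(role=PHENOTYPIC, trans_number=7, basal=0,
             cis_numbers=np.full(_L, 2, dtype=np.int64),
             coefficients=np.full(_L, 5.0), label="P2"),
    ]
    return Genome(genes, L=_L, n=_N)


def make_star_graph(n_targets: int = 10) -> nx.DiGraph:
    graph = nx.DiGraph()
    for i in range(n_targets):
        graph.add_edge("hub", f"t{i}", weight=1.0)
    return graph


def make_poisson_hist(lam: float = 3.0, scale: float = 200.0,
                      k_max: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless histogram count(k) = round(scale * lam^k e^-lam / k!)."""
    k = np.arange(1, k_max + 1)
    counts = np.round(scale * np.exp(k * np.log(lam) - lam - gammaln(k + 1)))
    return k, counts.astype(np.int64)


def make_powerlaw_hist(gamma: float = 2.0, scale: float = 500.0,
                       k_max: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless histogram count(k) = round(scale * k^-gamma)."""
    k = np.arange(1, k_max + 1)
    counts = np.round(scale * np.power(k, -float(gamma)))
    return k, counts.astype(np.int64)


def write_fixture(kind: str, seed: int, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    if kind == "founder":
        cfg = SimulationConfig(seed=seed)
        rng = np.random.default_rng(seed)
        genome = make_founder(cfg, rng)
        (out_dir / "founder.json").write_text(genome.to_json())
    elif kind == "fig1_like":
        (out_dir / "fig1_like.json").write_text(make_fig1_genome().to_json())
    elif kind == "oscillator":
        (out_dir / "oscillator.json").write_text(
            make_oscillator_genome().to_json())
    elif kind == "star_graph":
        graph = make_star_graph()
        lines = ["source\ttarget\tweight"]
        lines += [f"{u}\t{v}\t1" for u, v in graph.edges()]
        (out_dir / "star_graph.tsv").write_text("\n".join(lines) + "\n")
    elif kind == "degree_histograms":
        for name, (k, c) in (("poisson", make_poisson_hist()),
                             ("powerlaw", make_powerlaw_hist())):
            lines = ["k\tcount"] + [f"{ki}\t{ci}" for ki, ci in zip(k, c)]
            (out_dir / f"{name}_hist.tsv").write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
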