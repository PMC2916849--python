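"""Discrete-time gene-expression dynamics and steady-state phenotypes.

Development starts from the all-zero expression state and iterates the
synchronous update ``G_i(t+1) = Phi(x_i(t))``, where the regulatory input

    x_i(t) = b_i + sum_j B_ji * E_ji(t)

sums, over the L cis-sites of gene i, the site coefficient times the total
expression of all regulatory genes whose trans-number matches the site's
cis-number.  The receptor gene R1 is special: its protein is active (binds
its sites) only while the external signal is present; without the signal it
contributes nothing to any input, although the gene itself is expressed
normally.

The saturating activation function Phi(x) = E_max * x / (K + x) for x > 0
(0 otherwise) bounds every level to [0, E_max); K = 15 is the
half-saturation input and E_max = 10 the expression ceiling.

Steady state is declared at the first time t >= window at which the
population variance of every phenotypic gene's levels over the window
(t-window .. t) falls to <= V; the phenotype is the vector of windowed
means at that time.  An individual whose development does not settle
within t_max = 500 steps is lethal.

The inner time loop is compiled with numba when available (it is the
simulator's hot spot); a pure-Python fallback keeps the package importable
without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome

__all__ = ["DevelopmentResult", "activation", "regulatory_input",
           "develop", "phenotype_pair", "compile_network"]

_FORM_CODES = {"michaelis": 0, "hill2": 1}


@dataclass
class DevelopmentResult:
    """Outcome of one developmental run under one signal condition."""

    phenotype: np.ndarray | None      # windowed means of phenotypic genes
    lethal: bool
    steady_time: int | None
    expression_total: float           # sum of all levels over recorded steps
    signal_on: bool
    gene_means: np.ndarray | None = None   # windowed means, all genes
    trajectory: np.ndarray | None = None   # (t+1, n_genes) levels, optional


class _Compiled:
    """Genome flattened to arrays for fast iteration.

    ``W_on``/``W_off`` are (n_reg, n_genes) coupling matrices: entry
    [r, g] is the summed coefficient of gene g's cis-sites matching
    regulator r's trans-number.  ``W_off`` has the receptor row zeroed,
    implementing the inactive receptor protein when the signal is absent.
    """

    __slots__ = ("b", "W_on", "W_off", "reg_idx", "phen_idx",
                 "receptor_pos", "n_genes")

    def __init__(self, genome: Genome) -> None:
        genes = genome.genes
        self.n_genes = len(genes)
        self.b = np.array([g.basal for g in genes], dtype=np.float64)
        self.reg_idx = np.array(genome.regulatory_indices, dtype=np.int64)
        self.phen_idx = np.array(genome.phenotypic_indices, dtype=np.int64)
        n_reg = len(self.reg_idx)
        W = np.zeros((n_reg, self.n_genes))
        receptor_pos = -1
        for r_pos, r_idx in enumerate(self.reg_idx):
            reg = genes[r_idx]
            if reg.is_receptor:
                receptor_pos = r_pos
            for g_pos, target in enumerate(genes):
                match = target.cis_numbers == reg.trans_number
                if match.any():
                    W[r_pos, g_pos] = target.coefficients[match].sum()
        self.receptor_pos = receptor_pos
        self.W_on = W
        self.W_off = W.copy()
        if receptor_pos >= 0:
            self.W_off[receptor_pos, :] = 0.0


def compile_network(genome: Genome) -> _Compiled:
    """Return (and cache on the genome) the array form of its network."""
    compiled = getattr(genome, "_compiled", None)
    if compiled is None:
        compiled = _Compiled(genome)
        genome._compiled = compiled  # type: ignore[attr-defined]
    return compiled


def activation(x, K: float = 15.0, E_max: float = 10.0, form: str = "michaelis"):
    """Saturating activation Phi: regulatory input -> expression level.

    The default Michaelis form is E_max*x/(K+x) for x > 0 and 0 otherwise
    (monotone, bounded in [0, E_max)); ``form="hill2"`` substitutes the
    sigmoid Hill form E_max*x^2/(K^2+x^2) for sensitivity analysis.
    """
    x = np.asarray(x, dtype=np.float64)
    pos = np.maximum(x, 0.0)
    if form == "michaelis":
        out = E_max * pos / (K + pos)
    elif form == "hill2":
        out = E_max * pos * pos / (K * K + pos * pos)
    else:
        raise ValueError(f"unknown activation form {form!r}")
    return out if out.ndim else float(out)


def regulatory_input(genome: Genome, levels: np.ndarray, gene_index: int,
                     signal_on: bool) -> float:
    """Regulatory input x_i to one gene given the current expression state."""
    comp = compile_network(genome)
    W = comp.W_on if signal_on else comp.W_off
    g_reg = np.asarray(levels, dtype=np.float64)[comp.reg_idx]
    return float(comp.b[gene_index] + g_reg @ W[:, gene_index])


def _develop_loop(W, b, reg_idx, phen_idx, V, t_max, window,
                  K, E_max, lam, form_code, stop_at_steady, hist):
    """Inner developmental time loop; fills ``hist`` and returns steady time.

    Returns -1 if the steady-state criterion is never met by t_max.
    Windowed variances are maintained by running sums over the last
    window+1 points of each phenotypic gene.
    """
    n_genes = b.shape[0]
    n_reg = reg_idx.shape[0]
    n_phen = phen_idx.shape[0]
    s = np.zeros(n_phen)
    s2 = np.zeros(n_phen)
    steady = -1
    count = float(window + 1)
    for t in range(1, t_max + 1):
        prev = hist[t - 1]
        for g in range(n_genes):
            x = b[g]
            for r in range(n_reg):
                x += prev[reg_idx[r]] * W[r, g]
            if x > 0.0:
                if form_code == 0:
                    val = E_max * x / (K + x)
                else:
                    val = E_max * x * x / (K * K + x * x)
            else:
                val = 0.0
            if lam == 1.0:
                hist[t, g] = val
            else:
                hist[t, g] = (1.0 - lam) * prev[g] + lam * val
        for p in range(n_phen):
            v = hist[t, phen_idx[p]]
            s[p] += v
            s2[p] += v * v
            if t > window:
                old = hist[t - window - 1, phen_idx[p]]
                s[p] -= old
                s2[p] -= old * old
        if t >= window and steady < 0:
            ok = True
            for p in range(n_phen):
                mean = s[p] / count
                var = s2[p] / count - mean * mean
                if var > V:
                    ok = False
                    break
            if ok:
                steady = t
                if stop_at_steady:
                    return steady
    return steady


try:  # numba compilation of the hot loop; plain Python otherwise
    from numba import njit

    _develop_loop = njit(cache=True)(_develop_loop)
except ImportError:  # pragma: no cover - numba is normally present
    pass


def develop(genome: Genome, signal_on: bool, cfg=None, *,
            V: float | None = None, t_max: int | None = None,
            window: int | None = None, keep_trajectory: bool = False) -> DevelopmentResult:
    """Run development under one signal condition.

    Parameters may come from a :class:`~grnsim.config.SimulationConfig`
    (``cfg``) or be given explicitly; explicit values win.  Returns a
    :class:`DevelopmentResult`; lethality (no steady state within t_max)
    is an outcome, not an error.
    """
    if cfg is not None:
        V = cfg.V if V is None else V
        t_max = cfg.t_max if t_max is None else t_max
        window = cfg.window if window is None else window
        K, E_max = cfg.K, cfg.E_max
        form, lam = cfg.activation_form, cfg.relaxation
        accumulate_full = cfg.accumulate_full
    else:
        V = 1e-4 if V is None else V
        t_max = 500 if t_max is None else t_max
        window = 50 if window is None else window
        K, E_max, form, lam = 15.0, 10.0, "michaelis", 1.0
        accumulate_full = False

    comp = compile_network(genome)
    W = comp.W_on if signal_on else comp.W_off
    hist = np.zeros((t_max + 1, comp.n_genes))
    steady = int(_develop_loop(
        W, comp.b, comp.reg_idx, comp.phen_idx, V, t_max, window,
        K, E_max, lam, _FORM_CODES[form], not accumulate_full, hist))

    lethal = steady < 0
    if lethal:
        seg = hist[t_max - window:t_max + 1]
        phenotype = None
        gene_means = seg.mean(axis=0)
        steady_time = None
        end = t_max
    else:
        seg = hist[steady - window:steady + 1]
        phenotype = seg[:, comp.phen_idx].mean(axis=0)
        gene_means = seg.mean(axis=0)
        steady_time = steady
        end = t_max if accumulate_full else steady

    return DevelopmentResult(
        phenotype=phenotype,
        lethal=lethal,
        steady_time=steady_time,
        expression_total=float(hist[1:end + 1].sum()),
        signal_on=signal_on,
        gene_means=gene_means,
        trajectory=hist[:end + 1].copy() if keep_trajectory else None,
    )


def phenotype_pair(genome: Genome, cfg, keep_trajectory: bool = False
                   ) -> tuple[DevelopmentResult, DevelopmentResult]:
    """Develop under both signal conditions; viable iff both settle."""
    on = develop(genome, True, cfg, keep_trajectory=keep_trajectory)
    off = develop(genome, False, cfg, keep_trajectory=keep_trajectory)
    return on, off


def trajectory_tsv(result: DevelopmentResult, gene_labels=None) -> str:
    """Render a kept trajectory as long-format TSV (t, gene_id, level)."""
    if result.trajectory is None:
        raise ValueError("development was run without keep_trajectory")
    n_genes = result.trajectory.shape[1]
    labels = list(gene_labels) if gene_labels is not None else \
        [str(i) for i in range(n_genes)]
    lines = ["t\tgene_id\tlevel"]
    for t, row in enumerate(result.trajectory):
        for label, level in zip(labels, row):
            lines.append(f"{t}\t{label}\t{level:.6g}")
    return "\n".join(lines) + "\n"
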