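"""Fitness: phenotypic suitability, expression cost, and reproduction weights.

Suitability is Gaussian stabilizing selection on the two-condition
phenotype: with D_on and D_off the Euclidean distances of the signal-on and
signal-off phenotypes from their optima (the signal-off optimum is the zero
vector throughout — expressing phenotypic genes without the signal is
wasteful),

    S = exp(-(D_on^2 + D_off^2) / (2 sigma^2)),   sigma = 1.

The cost of expressing the phenotype is linear in the total expression
accumulated over both developmental runs, Q = c * (T_on + T_off), and
fitness combines the two as F = S * max(0, 1 - Q).  Lethal individuals
(development never settles) have F = 0 regardless of S and Q.  Offspring
are sampled in proportion to fitness, W_i = F_i / sum_j F_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitnessRecord", "ExtinctionError", "suitability",
           "expression_cost", "fitness", "reproduction_weights",
           "evaluate_fitness"]


class ExtinctionError(RuntimeError):
    """Every individual has zero fitness; the population cannot reproduce."""


@dataclass
class FitnessRecord:
    S: float
    Q: float
    F: float
    D_on: float
    D_off: float


def suitability(phi_on: np.ndarray, phi_off: np.ndarray,
                theta_on: np.ndarray, theta_off: np.ndarray,
                sigma: float = 1.0) -> tuple[float, float, float]:
    """Return (S, D_on, D_off) for one individual's two-condition phenotype."""
    phi_on = np.asarray(phi_on, dtype=np.float64)
    phi_off = np.asarray(phi_off, dtype=np.float64)
    theta_on = np.asarray(theta_on, dtype=np.float64)
    theta_off = np.asarray(theta_off, dtype=np.float64)
    if not (phi_on.shape == phi_off.shape == theta_on.shape == theta_off.shape):
        raise ValueError("phenotype and optimum vectors must share one shape")
    d_on = float(np.linalg.norm(phi_on - theta_on))
    d_off = float(np.linalg.norm(phi_off - theta_off))
    s = float(np.exp(-(d_on ** 2 + d_off ** 2) / (2.0 * sigma ** 2)))
    return s, d_on, d_off


def expression_cost(expression_total_on: float, expression_total_off: float,
                    c: float) -> float:
    """Q = c * (total expression over both developmental runs)."""
    if c < 0 or expression_total_on < 0 or expression_total_off < 0:
        raise ValueError("cost inputs must be non-negative")
    return c * (expression_total_on + expression_total_off)


def fitness(S: float, Q: float, viable: bool = True,
            form: str = "multiplicative") -> float:
    """Combine suitability and cost; lethal individuals get F = 0."""
    if not viable:
        return 0.0
    if form == "multiplicative":
        return S * max(0.0, 1.0 - Q)
    if form == "subtractive":
        return max(0.0, S - Q)
    raise ValueError(f"unknown fitness form {form!r}")


def reproduction_weights(F_vec: np.ndarray) -> np.ndarray:
    """Fitness-proportional reproduction probabilities W_i = F_i / sum F."""
    F_vec = np.asarray(F_vec, dtype=np.float64)
    if np.any(F_vec < 0):
        raise ValueError("fitness values must be non-negative")
    total = F_vec.sum()
    if total <= 0:
        raise ExtinctionError("all individuals have zero fitness")
    return F_vec / total


def evaluate_fitness(phi_on, phi_off, total_on: float, total_off: float,
                     theta_on, theta_off, cfg, viable: bool = True,
                     c: float | None = None) -> FitnessRecord:
    """Full fitness evaluation of one individual against the current optima.

    ``c`` overrides the configured expression-cost load (the mutation
    fitness-effect analysis uses c = 0).
    """
    if not viable:
        return FitnessRecord(0.0, 0.0, 0.0, float("nan"), float("nan"))
    s, d_on, d_off = suitability(phi_on, phi_off, theta_on, theta_off, cfg.sigma)
    q = expression_cost(total_on, total_off, cfg.c if c is None else c)
    f = fitness(s, q, True, cfg.fitness_form)
    return FitnessRecord(s, q, f, d_on, d_off)
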