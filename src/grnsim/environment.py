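"""The fluctuating-optimum process driving phenotypic selection.

The signal-on optimum Theta+ starts at the founder's signal-on phenotype
and thereafter shifts a constant Euclidean distance d once every 1/f
generations, either in a uniformly random direction (random-walk regime)
or by toggling between two fixed points at distance d (cyclic regime).
The signal-off optimum Theta- is the zero vector throughout.

The walk avoids the vicinity of zero expression: every coordinate of
Theta+ is kept inside [theta_min, E_max] (default floor 0.5) by rejection
sampling of shift directions, so that losing a phenotypic gene's
expression always remains deleterious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OptimumProcess", "init_optimum", "step_optimum"]

_RETRY_CAP = 10_000


@dataclass
class OptimumProcess:
    regime: str                       # random_walk | cyclic | static
    d: float
    f: float
    theta_on: np.ndarray
    theta_off: np.ndarray
    theta_min: float = 0.5
    e_max: float = 10.0
    cyclic_pair: tuple[np.ndarray, np.ndarray] | None = None
    cyclic_state: int = 0             # which of the pair is current
    period: int = 0                   # generations between shifts (0 = never)
    shift_log: list[tuple[int, np.ndarray]] = field(default_factory=list)


def _random_direction(m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the (m-1)-sphere via normalized Gaussians."""
    while True:
        v = rng.standard_normal(m)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def _in_bounds(theta: np.ndarray, lo: float, hi: float) -> bool:
    return bool(np.all(theta >= lo) and np.all(theta <= hi))


def init_optimum(founder_phenotype_on: np.ndarray, regime: str, d: float,
                 f: float, rng: np.random.Generator, *,
                 theta_min: float = 0.5, e_max: float = 10.0) -> OptimumProcess:
    """Place the initial optimum at the founder's signal-on phenotype."""
    theta = np.asarray(founder_phenotype_on, dtype=np.float64).copy()
    m = theta.size
    period = 0 if (regime == "static" or d == 0 or f <= 0) else int(round(1.0 / f))
    proc = OptimumProcess(
        regime=regime, d=d, f=f,
        theta_on=theta, theta_off=np.zeros(m),
        theta_min=theta_min, e_max=e_max, period=period,
    )
    if regime == "cyclic" and period > 0:
        for _ in range(_RETRY_CAP):
            other = theta + d * _random_direction(m, rng)
            if _in_bounds(other, theta_min, e_max):
                proc.cyclic_pair = (theta.copy(), other)
                break
        else:
            raise RuntimeError(
                f"could not place the second cyclic optimum at distance {d} "
                f"inside [{theta_min}, {e_max}] after {_RETRY_CAP} tries")
    return proc


def step_optimum(proc: OptimumProcess, generation: int,
                 rng: np.random.Generator) -> OptimumProcess:
    """Advance the optimum at generation boundaries; returns ``proc``.

    No-op unless the regime shifts and ``generation`` is a multiple of the
    shift period round(1/f).  Random-walk shifts are re-drawn until every
    coordinate stays inside [theta_min, E_max].
    """
    if proc.period <= 0 or generation < 1 or generation % proc.period != 0:
        return proc
    if proc.regime == "random_walk":
        m = proc.theta_on.size
        for _ in range(_RETRY_CAP):
            proposal = proc.theta_on + proc.d * _random_direction(m, rng)
            if _in_bounds(proposal, proc.theta_min, proc.e_max):
                proc.theta_on = proposal
                break
        else:
            raise RuntimeError(
                f"random-walk shift of size {proc.d} cannot stay inside "
                f"[{proc.theta_min}, {proc.e_max}] after {_RETRY_CAP} tries")
    elif proc.regime == "cyclic":
        assert proc.cyclic_pair is not None
        proc.cyclic_state = 1 - proc.cyclic_state
        proc.theta_on = proc.cyclic_pair[proc.cyclic_state].copy()
    proc.shift_log.append((generation, proc.theta_on.copy()))
    return proc
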