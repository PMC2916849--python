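"""Simulation configuration: parameter glossary, defaults, and TOML loading.

The default values are the model's standard parameter set: a population of
Z = 1e5 haploid asexual individuals, each carrying a regulatory module of
N = 10 regulatory genes and M = 2 phenotypic genes, cis-regulatory regions
of L = 100 sites drawn from a motif space of n = 9950 distinct DNA words,
per-gene per-generation mutation rates of 1e-6 for five mutation types and
0 for horizontal transfer, an expression cost of c = 1e-5 per unit of
expression, and a steady-state constraint V = 1e-4.

Desk-scale runs override ``Z`` and ``generations`` (and typically scale the
mutation rates so the population mutational supply Z*mu is preserved); the
defaults here remain the cluster-scale standard set.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from typing import Any

__all__ = ["SimulationConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range parameter values."""


@dataclass
class SimulationConfig:
    """All tunable model parameters with their standard defaults."""

    # --- population / genome architecture ---
    Z: int = 100_000               # population size
    M_ini: int = 2                 # phenotypic genes in the founder
    N_ini: int = 10                # regulatory genes in the founder
    L: int = 100                   # cis-sites per cis-regulatory region
    n: int = 9950                  # motif-space size (distinct DNA words)
    C_init: float = 0.5            # founder GRN connectivity
    founder_max_attempts: int = 100_000

    # --- expression dynamics ---
    K: float = 15.0                # activation half-saturation constant
    E_max: float = 10.0            # maximum expression level
    V: float = 1e-4                # steady-state variance threshold
    t_max: int = 500               # developmental time limit
    window: int = 50               # steady-state detection window
    activation_form: str = "michaelis"   # or "hill2"
    relaxation: float = 1.0        # update inertia; 1.0 = full replacement
    accumulate_full: bool = False  # cost accrued over full t_max vs to steady state

    # --- fitness ---
    sigma: float = 1.0             # strength of phenotypic selection
    c: float = 1e-5                # fitness load per unit of expression
    suitability_form: str = "gaussian"
    fitness_form: str = "multiplicative"  # F = S*max(0, 1-Q); or "subtractive"

    # --- mutation ---
    mu_BTL: float = 1e-6
    mu_CIS: float = 1e-6
    mu_TRA: float = 1e-6
    mu_DUP: float = 1e-6
    mu_DEL: float = 1e-6
    mu_HOR: float = 0.0
    mutation_mode: str = "per_gene"   # per_gene | per_individual | constant_PS
    hor_basal: int = 0             # basal level of horizontally acquired genes
    constant_ps_cap: int = 1000    # redraw cap in constant_PS mode
    b_assignment: str = "deterministic"   # founder b=1 assignment rule; or "random"

    # --- environment (optimum process) ---
    regime: str = "random_walk"    # random_walk | cyclic | static
    d: float = 0.1                 # optimum shift amplitude
    f: float = 0.1                 # shift frequency (shifts per generation)
    theta_min: float = 0.5         # per-coordinate floor of the moving optimum

    # --- run control ---
    generations: int = 50_000
    seed: int | None = None
    record_cadence: int = 1        # mean-fitness record cadence
    class_cadence: int = 100       # gene-class census cadence
    track_fitness_effects: bool = False   # c = 0 mutation-tracking mode
    extinction_cap_factor: int = 100      # sampling attempts cap, multiples of Z

    # --- assay thresholds ---
    eps_expr: float = 1e-2         # "expressed" threshold on steady levels
    eps_same: float = 1e-6         # Non-effect phenotype-displacement tolerance
    loss_threshold: float = 1e-2   # Loss-of-phenotype threshold on P_i (signal on)
    neutral_band: float = 1e-2     # |dF| band for neutral fitness effects

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive_ints = ("Z", "M_ini", "N_ini", "L", "n", "t_max", "window",
                         "generations", "founder_max_attempts")
        for key in positive_ints:
            if int(getattr(self, key)) <= 0:
                raise ConfigError(f"{key} must be a positive integer, got {getattr(self, key)}")
        for key in ("mu_BTL", "mu_CIS", "mu_TRA", "mu_DUP", "mu_DEL", "mu_HOR"):
            rate = getattr(self, key)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{key} must lie in [0, 1], got {rate}")
        if not 0.0 < self.C_init < 1.0:
            raise ConfigError(f"C_init must lie in (0, 1), got {self.C_init}")
        if self.c < 0 or self.V <= 0 or self.sigma <= 0:
            raise ConfigError("c must be >= 0 and V, sigma must be > 0")
        if self.d < 0 or not 0.0 <= self.f <= 1.0:
            raise ConfigError("d must be >= 0 and f must lie in [0, 1]")
        if self.mutation_mode not in ("per_gene", "per_individual", "constant_PS"):
            raise ConfigError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.regime not in ("random_walk", "cyclic", "static"):
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.activation_form not in ("michaelis", "hill2"):
            raise ConfigError(f"unknown activation_form {self.activation_form!r}")
        if self.fitness_form not in ("multiplicative", "subtractive"):
            raise ConfigError(f"unknown fitness_form {self.fitness_form!r}")
        if self.b_assignment not in ("deterministic", "random"):
            raise ConfigError(f"unknown b_assignment {self.b_assignment!r}")
        if self.window >= self.t_max:
            raise ConfigError("window must be smaller than t_max")

    def replace(self, **overrides: Any) -> "SimulationConfig":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str) -> SimulationConfig:
    """Load a flat TOML key-value file; missing keys take the standard defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return SimulationConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
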