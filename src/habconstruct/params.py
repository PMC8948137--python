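"""Model parameters.

Every knob of the simulation lives in :class:`ModelParams`, whose defaults
reproduce the baseline regime of the habitat-construction model: an
unstructured 64-deme metapopulation of demes of 8, island dispersal at 44%,
environmental decay of 50% per generation, Gaussian stabilizing selection of
width 4 on an additive 5-locus trait, a 50% fitness decrease at the baseline
environment, and a construction cost of 0.002 per unit constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any

NOISE_TARGETS = ("none", "selection_env", "optimum")
DISPERSAL_PATTERNS = ("island", "stepping_stone")
LIFE_HISTORIES = ("move_first", "select_first")
ENVIRONMENT_MODES = ("uniform", "gradient_parallel", "gradient_single")


class ConfigurationError(ValueError):
    """Raised when a parameter value or combination is invalid."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one simulation run.

    Rates are fractions in [0, 1]; environmental quantities are in the
    model's arbitrary environment units (the baseline-to-optimum distance
    at the gradient center is ``optimum_offset`` = 10 units and normalizes
    both the construction benefit and the reported construction means).
    """

    n_demes: int = 64
    deme_capacity: int = 8
    delta: float = 0.5            # per-generation decay rate toward baseline
    omega: float = 4.0            # Gaussian selection width (lower = stronger)
    gamma: float = 0.002          # fitness cost per unit individual construction
    phi: float = 0.5              # fitness decrease at the baseline environment
    tau: float = 0.0              # temporal-variation SD as fraction of offset
    noise_target: str = "none"    # none | selection_env | optimum
    noise_correlated: bool = False
    noise_persists: bool = False  # z on S carries into end-of-generation E
    dispersal_pattern: str = "island"
    dispersal_rate: float = 0.44
    life_history: str = "select_first"
    environment_mode: str = "uniform"
    gradient_spacing: float = 0.4
    optimum_offset: float = 10.0
    mutation_rate: float = 0.1    # per-allele per-generation
    mutation_sd: float = 0.1      # SD of the Gaussian mutation increment
    generations: int = 1000
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _frac(name: str) -> None:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in [0, 1]")

        for name in ("delta", "phi", "dispersal_rate", "mutation_rate"):
            _frac(name)
        if self.omega <= 0:
            raise ConfigurationError(f"omega={self.omega!r} must be positive")
        if self.tau < 0:
            raise ConfigurationError(f"tau={self.tau!r} must be non-negative")
        if self.mutation_sd < 0:
            raise ConfigurationError(f"mutation_sd={self.mutation_sd!r} must be non-negative")
        if self.n_demes < 1 or self.deme_capacity < 1:
            raise ConfigurationError(
                f"metapopulation must be non-empty (n_demes={self.n_demes}, "
                f"deme_capacity={self.deme_capacity})"
            )
        if self.generations < 0 or self.replicates < 1:
            raise ConfigurationError("generations must be >= 0 and replicates >= 1")
        if self.noise_target not in NOISE_TARGETS:
            raise ConfigurationError(
                f"noise_target={self.noise_target!r} not in {NOISE_TARGETS}"
            )
        if self.dispersal_pattern not in DISPERSAL_PATTERNS:
            raise ConfigurationError(
                f"dispersal_pattern={self.dispersal_pattern!r} not in {DISPERSAL_PATTERNS}"
            )
        if self.life_history not in LIFE_HISTORIES:
            raise ConfigurationError(
                f"life_history={self.life_history!r} not in {LIFE_HISTORIES}"
            )
        if self.environment_mode not in ENVIRONMENT_MODES:
            raise ConfigurationError(
                f"environment_mode={self.environment_mode!r} not in {ENVIRONMENT_MODES}"
            )
        if self.dispersal_pattern == "stepping_stone" and self.dispersal_rate >= 1.0:
            raise ConfigurationError(
                "stepping-stone dispersal rate must be < 1 (truncated-Gaussian "
                "movement probability cannot reach 1)"
            )
        if self.n_demes == 1 and self.dispersal_rate > 0:
            raise ConfigurationError("dispersal requires at least 2 demes")

    @property
    def total_size(self) -> int:
        return self.n_demes * self.deme_capacity

    @property
    def noise_sd_units(self) -> float:
        """Temporal-variation SD in environment units (τ × offset)."""
        return self.tau * self.optimum_offset

    def with_(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)
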