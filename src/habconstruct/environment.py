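"""Deme environment dynamics.

Each deme has a baseline state θ_i and an optimum θ_i*. Construction pushes
the environment up from the baseline; decay relaxes it back at rate δ per
generation. The environment at the time of selection is

    S_it = E_i(t−1) + ΔE_it + ΔH_it (+ z_it when noise targets S),

with ΔE the decay increment and ΔH the saturating deme-level construction.
Optional zero-mean Gaussian temporal deviates perturb either S or the
optimum, independently per deme or identically across demes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError, ModelParams

DEME_SATURATION = 0.2   # ΔH = ΣB / (1 + 0.2 ΣB): asymptote 1/0.2 = 5 units


@dataclass(frozen=True)
class EnvironmentProfile:
    """Baselines θ_i and optima θ_i* for every deme.

    ``normalization`` is the baseline-to-optimum distance at the gradient
    center (10 units in all standard configurations); it scales both the
    construction benefit and the reported normalized construction.
    """

    baselines: np.ndarray
    optima: np.ndarray
    normalization: float = 10.0

    @property
    def n_demes(self) -> int:
        return self.baselines.shape[0]


@dataclass(frozen=True)
class TemporalNoise:
    """Temporal-variation settings: what z perturbs and its SD in env units."""

    target: str = "none"          # none | selection_env | optimum
    correlated: bool = False
    sd: float = 0.0

    @classmethod
    def from_params(cls, params: ModelParams) -> "TemporalNoise":
        return cls(target=params.noise_target, correlated=params.noise_correlated,
                   sd=params.noise_sd_units if params.noise_target != "none" else 0.0)


def make_profile(mode: str, n_demes: int, spacing: float = 0.4,
                 offset: float = 10.0) -> EnvironmentProfile:
    """Build the deme baseline/optimum profile.

    uniform:            θ_i = 0 and θ_i* = offset everywhere.
    gradient_parallel:  θ_i = spacing·(i − (n+1)/2) (1-based), θ_i* = θ_i + offset,
                        so the required construction is constant along the array.
    gradient_single:    same baseline gradient but a single flat optimum
                        θ_i* = offset, so the required construction shrinks
                        from one end of the gradient to the other.
    """
    if n_demes < 1:
        raise ConfigurationError("n_demes must be >= 1")
    if mode == "uniform":
        baselines = np.zeros(n_demes)
        optima = np.full(n_demes, offset)
    elif mode in ("gradient_parallel", "gradient_single"):
        i = np.arange(1, n_demes + 1, dtype=float)
        baselines = spacing * (i - (n_demes + 1) / 2.0)
        optima = baselines + offset if mode == "gradient_parallel" else np.full(n_demes, offset)
    else:
        raise ConfigurationError(f"unknown environment mode {mode!r}")
    return EnvironmentProfile(baselines=baselines, optima=optima, normalization=offset)


def decay_step(E_prev, baseline, delta: float):
    """Decay increment ΔE = −δ(E_prev − θ); vectorized over demes."""
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"delta={delta!r} must lie in [0, 1]")
    return -delta * (np.asarray(E_prev, dtype=float) - np.asarray(baseline, dtype=float))


def deme_construction(B_values) -> float:
    """Deme-level construction ΔH = ΣB / (1 + 0.2 ΣB) from individual amounts."""
    total = float(np.sum(B_values)) if np.ndim(B_values) else float(B_values)
    return deme_construction_from_total(total)


def deme_construction_from_total(total_B):
    """ΔH from the per-deme sum of individual constructions (vectorized)."""
    total = np.asarray(total_B, dtype=float)
    out = total / (1.0 + DEME_SATURATION * total)
    return float(out) if out.ndim == 0 else out


def temporal_deviates(noise: TemporalNoise, n_demes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-deme Gaussian deviates z for one generation.

    Correlated noise means a single draw z_t shared by every deme;
    uncorrelated noise draws independently per deme. With no noise target
    (or zero SD) the deviates are exactly zero.
    """
    if noise.target == "none" or noise.sd == 0.0:
        return np.zeros(n_demes)
    if noise.correlated:
        return np.full(n_demes, rng.normal(0.0, noise.sd))
    return rng.normal(0.0, noise.sd, size=n_demes)


def selection_environment(E_prev, dE, dH, z=0.0):
    """Environment at the time of selection: S = E_prev + ΔE + ΔH + z."""
    return np.asarray(E_prev, dtype=float) + dE + dH + z


def effective_optimum(optimum, z=0.0):
    """Optimum at the time of selection, θ*_t = θ* + z (never stored)."""
    return np.asarray(optimum, dtype=float) + z
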