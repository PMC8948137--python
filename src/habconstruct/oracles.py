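"""Closed-form oracle quantities of the model.

Each oracle recomputes, from the package's own primitives, a quantity the
model fixes analytically — saturation limits, equilibrium ceilings, cost
magnitudes, and the structural constants of the two environment layouts.
They back the ``check`` CLI subcommand and the fast analytic tests.
"""

from __future__ import annotations

import numpy as np

from .environment import deme_construction, deme_construction_from_total, make_profile
from .lifecycle import survival_probability
from .model_core import B_MAX, individual_construction
from .params import ModelParams


def deme_construction_asymptote() -> float:
    """Limit of ΔH = ΣB/(1 + 0.2 ΣB) as ΣB grows without bound (→ 5)."""
    return float(deme_construction_from_total(1e9))


def construction_at_zero_propensity() -> float:
    """Individual construction B at propensity A = 0 (→ 2.5)."""
    return float(individual_construction(0.0))


def equilibrium_ceiling_coefficient(n: int | None = None) -> float:
    """Coefficient c of 1/δ in the maximum steady-state normalized construction.

    At steady state, decay balances construction: δ(E − θ) = ΔH, so the
    normalized construction (E − θ)/10 equals ΔH/(10δ). With every one of
    the deme's N occupants constructing the individual maximum B = 5,
    ΔH = 5N/(1 + N); c = ΔH/10. n=None takes the large-N asymptote (c = 0.5).
    """
    dH = deme_construction_asymptote() if n is None else deme_construction([B_MAX] * n)
    return dH / 10.0


def equilibrium_ceiling(n: int, delta: float) -> float:
    """Maximum achievable normalized equilibrium construction for deme size n."""
    return equilibrium_ceiling_coefficient(n) / delta


def max_construction_cost(params: ModelParams | None = None) -> float:
    """Fitness decrease for an optimal-phenotype individual at maximal B.

    W = 1·exp(0) − γ·B_max, so the decrease is γ·B_max (= 0.01, i.e. 1%).
    """
    params = params or ModelParams()
    w = survival_probability(T=0.0, S=0.0, optimum_t=0.0, B=B_MAX,
                             params=params.with_(phi=0.0))
    return 1.0 - w


def gradient_span_over_selection_width(params: ModelParams | None = None) -> float:
    """Length of the baseline gradient relative to the selection width 2ω (≈ 2.5)."""
    params = params or ModelParams(environment_mode="gradient_parallel",
                                   n_demes=50, deme_capacity=8)
    profile = make_profile("gradient_parallel", 50, params.gradient_spacing,
                           params.optimum_offset)
    span = float(profile.baselines.max() - profile.baselines.min())
    return span / (2.0 * params.omega)


def adjacent_deme_spacing() -> float:
    """Baseline difference between adjacent demes on the 50-deme gradient."""
    profile = make_profile("gradient_parallel", 50)
    return float(np.diff(profile.baselines).mean())


def metapopulation_size(mode: str) -> int:
    """Total metapopulation size: 512 unstructured, 400 on the gradient."""
    if mode == "uniform":
        p = ModelParams(environment_mode="uniform", n_demes=64, deme_capacity=8)
    else:
        p = ModelParams(environment_mode=mode, n_demes=50, deme_capacity=8,
                        dispersal_pattern="stepping_stone", dispersal_rate=0.41)
    return p.total_size


def analytic_oracles() -> dict[str, tuple[float, float, float]]:
    """All analytic checks as name -> (computed, expected, tolerance)."""
    return {
        "deme construction asymptote": (deme_construction_asymptote(), 5.0, 1e-6),
        "individual construction at A=0": (construction_at_zero_propensity(), 2.5, 1e-12),
        "large-N ceiling coefficient (of 1/delta)": (
            equilibrium_ceiling_coefficient(), 0.5, 1e-6),
        "N=2 ceiling coefficient (of 1/delta)": (
            round(equilibrium_ceiling_coefficient(2), 2), 0.33, 1e-12),
        "N=32, delta=20% ceiling": (round(equilibrium_ceiling(32, 0.2), 1), 2.4, 1e-12),
        "maximal-construction fitness cost": (max_construction_cost(), 0.01, 1e-12),
        "gradient span / selection width": (
            round(gradient_span_over_selection_width(), 1), 2.5, 0.05),
        "adjacent-deme baseline spacing": (adjacent_deme_spacing(), 0.4, 1e-12),
        "unstructured metapopulation size": (metapopulation_size("uniform"), 512, 0),
        "gradient metapopulation size": (metapopulation_size("gradient_parallel"), 400, 0),
    }
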