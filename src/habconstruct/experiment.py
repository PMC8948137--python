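"""Replicated runs, response variables, presets and sweeps.

The response variables mirror how the simulation study is summarized:
after the final generation one extra round of mating and reproduction
(without environmental decay) returns the demes to full size, and on that
cohort we report the normalized construction mean (mean deme environment
divided by 10), the mean construction propensity (averaged within demes,
then across demes), and the mean survival probability of the cohort in its
current environment. For gradient runs, the least-squares slopes of the
deme means of E and A against deme position, normalized by the 0.4-unit
baseline spacing, measure how well construction tracks the gradient and
how genetically differentiated the construction propensity is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .environment import EnvironmentProfile, TemporalNoise, make_profile
from .lifecycle import DispersalSpec, reproduce_all, run_generation, survival_probability
from .model_core import MetapopState, individual_construction, init_metapopulation
from .params import ConfigurationError, ModelParams

STAT_NAMES = ("mean_construction", "mean_propensity", "mean_fitness",
              "construction_slope", "propensity_slope")


@dataclass(frozen=True)
class SummaryStats:
    """Per-replicate response variables; slopes are NaN for uniform runs."""

    mean_construction: float = math.nan   # mean deme E / 10
    mean_propensity: float = math.nan     # mean A, within- then across-deme
    mean_fitness: float = math.nan        # mean W of the final cohort
    construction_slope: float = math.nan  # OLS slope of deme-mean E, / spacing
    propensity_slope: float = math.nan    # OLS slope of deme-mean A, / spacing
    extinct: bool = False

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in STAT_NAMES} | {"extinct": self.extinct}


@dataclass
class ExperimentResult:
    """Replicated runs of one parameter combination."""

    params: ModelParams
    replicates: list[SummaryStats]
    seeds: list[int]
    base_seed: int

    @property
    def n_extinct(self) -> int:
        return sum(s.extinct for s in self.replicates)

    @property
    def n_surviving(self) -> int:
        return len(self.replicates) - self.n_extinct

    def replicate_frame(self) -> pd.DataFrame:
        rows = []
        for rep, (s, seed) in enumerate(zip(self.replicates, self.seeds)):
            rows.append({"replicate": rep, "seed": seed, **s.as_dict()})
        return pd.DataFrame(rows)

    def aggregate(self) -> dict:
        """Across-replicate mean and SE per statistic, surviving replicates only."""
        out: dict = {"n_replicates": len(self.replicates),
                     "n_extinct": self.n_extinct}
        alive = [s for s in self.replicates if not s.extinct]
        for name in STAT_NAMES:
            vals = np.array([getattr(s, name) for s in alive], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                mean = se = math.nan
            else:
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
            out[f"{name}_mean"] = mean
            out[f"{name}_se"] = se
        return out


def gradient_slopes(deme_means: Sequence[float], spacing: float,
                    indices: Sequence[int] | None = None) -> float:
    """Normalized least-squares slope of deme means along the array.

    The slope against deme index is divided by the baseline spacing
    (0.4 units/deme), so deme means that reproduce the baseline gradient
    give exactly 1.0 and a flat profile gives 0.0. ``indices`` identifies
    which (occupied) demes the means belong to; requires at least two.
    """
    y = np.asarray(deme_means, dtype=float)
    if y.size < 2:
        return math.nan
    x = np.arange(y.size, dtype=float) if indices is None else np.asarray(indices, dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope / spacing)


def summarize(state: MetapopState, profile: EnvironmentProfile,
              params: ModelParams) -> SummaryStats:
    """Response variables on the current (refilled) cohort.

    Averages run within demes first, then across occupied demes; empty
    demes are excluded everywhere. mean_construction is the mean deme
    environment divided by 10, which equals mean (E − θ)/10 because the
    baselines average to zero in every standard profile. Fitness is each
    newborn's survival probability evaluated in its deme's current
    environment (no fresh decay or noise).
    """
    if state.extinct:
        return SummaryStats(extinct=True)
    occ = state.occupancy()
    occupied = np.flatnonzero(occ)

    n = state.n_individuals
    A = state.constr.reshape(n, -1).sum(axis=1)
    T = state.trait.reshape(n, -1).sum(axis=1)
    B = individual_construction(A)
    S = state.env[state.deme]
    W = survival_probability(T, S, profile.optima[state.deme], B, params)

    def deme_mean(values: np.ndarray) -> np.ndarray:
        tot = np.bincount(state.deme, weights=values, minlength=state.n_demes)
        return tot[occupied] / occ[occupied]

    a_means = deme_mean(A)
    w_means = deme_mean(W)
    e_means = state.env[occupied]

    gradient = params.environment_mode != "uniform"
    return SummaryStats(
        mean_construction=float(e_means.mean()) / profile.normalization,
        mean_propensity=float(a_means.mean()),
        mean_fitness=float(w_means.mean()),
        construction_slope=(gradient_slopes(e_means, params.gradient_spacing, occupied)
                            if gradient else math.nan),
        propensity_slope=(gradient_slopes(a_means, params.gradient_spacing, occupied)
                          if gradient else math.nan),
    )


def run_simulation(params: ModelParams, seed: int | Sequence[int] | None = None
                   ) -> tuple[MetapopState, SummaryStats]:
    """One replicate: init, `generations` generations, final refill, summary.

    After the last generation there is one extra round of mating and
    reproduction with no environmental decay (and no construction, noise,
    selection or dispersal) so that every occupied deme is at capacity when
    the response variables are computed. A metapopulation that loses all
    individuals at any point is recorded as extinct, with no statistics.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    profile = make_profile(params.environment_mode, params.n_demes,
                           params.gradient_spacing, params.optimum_offset)
    spec = DispersalSpec.from_params(params)
    noise = TemporalNoise.from_params(params)
    state = init_metapopulation(params, rng, profile)
    for _ in range(params.generations):
        state = run_generation(state, profile, params, rng, spec, noise)
        if state.extinct:
            return state, SummaryStats(extinct=True)
    state = reproduce_all(state, params, rng)  # final refill, no decay
    return state, summarize(state, profile, params)


def run_replicates(params: ModelParams, n_reps: int | None = None,
                   base_seed: int | None = None) -> ExperimentResult:
    """Independent replicates with per-replicate seed streams.

    Replicate r uses the seed sequence (base_seed, r), giving reproducible,
    order-independent streams.
    """
    n_reps = params.replicates if n_reps is None else n_reps
    base_seed = params.seed if base_seed is None else base_seed
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    stats, seeds = [], []
    for r in range(n_reps):
        _, s = run_simulation(params, seed=(base_seed, r))
        stats.append(s)
        seeds.append(r)
    return ExperimentResult(params=params, replicates=stats, seeds=seeds,
                            base_seed=base_seed)


# ---------------------------------------------------------------------------
# Preset catalog: the standard experiment grids.

_UNIFORM_SIZES = ((256, 2), (128, 4), (64, 8), (32, 16), (16, 32))  # 512 total
_DECAY_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))         # 10%..100%
_DISPERSAL_GRID = tuple(round(0.04 + 0.08 * k, 2) for k in range(13))  # 4%..100%
_TAU_GRID = tuple(round(0.025 * k, 3) for k in range(12))            # 0%..27.5%
_PHI_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))           # 10%..90%

PRESET_NAMES = (
    "decay_sweep_move_first",
    "decay_sweep_select_first",
    "dispersal_sweep_move_first",
    "dispersal_sweep_select_first",
    "temporal_variation",
    "gradient_dispersal_sweep",
    "gradient_phi_sweep",
    "gradient_island_mismatch",
)


def _uniform_base(**kw) -> ModelParams:
    return ModelParams(environment_mode="uniform", dispersal_pattern="island", **kw)


def _gradient_base(**kw) -> ModelParams:
    return ModelParams(n_demes=50, deme_capacity=8, delta=0.5, phi=0.5, **kw)


def preset(name: str) -> list[ModelParams]:
    """The parameter grid of one named standard experiment.

    Unstructured grids hold the metapopulation at 512 individuals across
    deme sizes N ∈ {2,4,8,16,32}; gradient grids use 50 demes of 8 (400).
    """
    if name == "decay_sweep_move_first" or name == "decay_sweep_select_first":
        lh = "move_first" if name.endswith("move_first") else "select_first"
        return [
            _uniform_base(n_demes=nd, deme_capacity=n, delta=d,
                          dispersal_rate=0.44, life_history=lh)
            for nd, n in _UNIFORM_SIZES for d in _DECAY_GRID
        ]
    if name in ("dispersal_sweep_move_first", "dispersal_sweep_select_first"):
        lh = "move_first" if name.endswith("move_first") else "select_first"
        return [
            _uniform_base(n_demes=nd, deme_capacity=n, delta=0.5,
                          dispersal_rate=m, life_history=lh)
            for nd, n in _UNIFORM_SIZES for m in _DISPERSAL_GRID
        ]
    if name == "temporal_variation":
        grid = []
        for target in ("selection_env", "optimum"):
            for corr in (False, True):
                for tau in _TAU_GRID:
                    grid.append(_uniform_base(
                        n_demes=64, deme_capacity=8, delta=0.5,
                        dispersal_rate=0.04, life_history="select_first",
                        tau=tau, noise_target=target if tau > 0 else "none",
                        noise_correlated=corr))
        return grid
    if name == "gradient_dispersal_sweep":
        return [
            _gradient_base(environment_mode=mode, dispersal_pattern="stepping_stone",
                           dispersal_rate=m, life_history=lh)
            for mode in ("gradient_parallel", "gradient_single")
            for lh in ("move_first", "select_first")
            for m in _DISPERSAL_GRID if m < 1.0
        ]
    if name == "gradient_phi_sweep":
        return [
            _gradient_base(environment_mode=mode, dispersal_pattern="stepping_stone",
                           dispersal_rate=0.41, life_history=lh).with_(phi=p)
            for mode in ("gradient_parallel", "gradient_single")
            for lh in ("move_first", "select_first")
            for p in _PHI_GRID
        ]
    if name == "gradient_island_mismatch":
        return [
            _gradient_base(environment_mode=mode, dispersal_pattern="island",
                           dispersal_rate=m, life_history=lh)
            for mode in ("gradient_parallel", "gradient_single")
            for lh in ("move_first", "select_first")
            for m in _DISPERSAL_GRID
        ]
    raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


@dataclass
class SweepResult:
    """Results for a parameter grid: one ExperimentResult per combination."""

    results: list[ExperimentResult]

    def aggregate_frame(self) -> pd.DataFrame:
        """One row per parameter combination with mean ± SE per statistic."""
        rows = []
        for combo, res in enumerate(self.results):
            rows.append({"combo": combo, **res.params.to_dict(), **res.aggregate()})
        return pd.DataFrame(rows)

    def replicate_frame(self) -> pd.DataFrame:
        """One row per (combination, replicate)."""
        frames = []
        for combo, res in enumerate(self.results):
            f = res.replicate_frame()
            f.insert(0, "combo", combo)
            frames.append(f)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def sweep(grid: Iterable[ModelParams], n_reps: int | None = None,
          base_seed: int = 0) -> SweepResult:
    """Run every combination of a grid with reproducible per-combo seeds.

    Combination c, replicate r draws from the stream seeded by
    (base_seed, c, r), so results are independent of grid order and can be
    recomputed combination-by-combination.
    """
    results = []
    for c, params in enumerate(grid):
        n = params.replicates if n_reps is None else n_reps
        stats, seeds = [], []
        for r in range(n):
            _, s = run_simulation(params, seed=(base_seed, c, r))
            stats.append(s)
            seeds.append(r)
        results.append(ExperimentResult(params=params, replicates=stats,
                                        seeds=seeds, base_seed=base_seed))
    return SweepResult(results)
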