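"""Selection, dispersal, reproduction, and the generation loop.

Two life-history orderings are supported (both start each generation with
birth and construction):

* move_first:   construction → dispersal → selection → reproduction
* select_first: construction → selection → dispersal → reproduction

Survival from juvenile to adult is an independent Bernoulli trial per
individual with probability W = f · exp(−½((T − S)/ω)²) − γB, clamped to
[0, 1]; f is the construction benefit, a linear penalty on the distance
between the selection environment S and the deme optimum. Reproduction is
soft selection: every deme with at least one survivor is refilled to
carrying capacity by offspring of parent pairs drawn at random with
replacement (selfing allowed), each parent contributing a freely
recombining haploid gamete whose alleles then mutate independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .environment import (
    EnvironmentProfile,
    TemporalNoise,
    decay_step,
    deme_construction_from_total,
    effective_optimum,
    selection_environment,
    temporal_deviates,
)
from .model_core import (
    N_LOCI,
    PLOIDY,
    Genome,
    MetapopState,
    construction_propensity,
    individual_construction,
)
from .params import ConfigurationError, ModelParams


@dataclass(frozen=True)
class DispersalSpec:
    """Dispersal pattern and rate; kernel_sd is the stepping-stone Gaussian σ."""

    pattern: str
    rate: float
    kernel_sd: float = 0.0

    @classmethod
    def from_params(cls, params: ModelParams) -> "DispersalSpec":
        sd = (sigma_for_rate(params.dispersal_rate)
              if params.dispersal_pattern == "stepping_stone" else 0.0)
        return cls(params.dispersal_pattern, params.dispersal_rate, sd)


def construction_benefit(S, optimum, phi: float, normalization: float):
    """Benefit term f = 1 − φ·|θ* − S| / normalization.

    Equals 1 when the selection environment sits at the optimum, falls
    linearly (and symmetrically: overshooting the optimum is as bad as
    undershooting it) with the deviation, and is deliberately not floored
    at 1 − φ: demes further than one normalization unit from their optimum
    get a lower benefit still.
    """
    if normalization <= 0:
        raise ConfigurationError("normalization must be positive")
    S = np.asarray(S, dtype=float)
    out = 1.0 - phi * np.abs(np.asarray(optimum, dtype=float) - S) / normalization
    return float(out) if out.ndim == 0 else out


def survival_probability(T, S, optimum_t, B, params: ModelParams):
    """Survival probability W, clamped to [0, 1].

    W = f(θ*_t, S) · exp(−½((T − T_opt)/ω)²) − γB, with the optimum
    phenotype T_opt equal to the selection environment S (trait and
    environment share units). Negative values mean certain death and are
    clamped to 0; the clamp at 1 can only bind when φ = 0 and γ = 0.
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    f = construction_benefit(S, optimum_t, params.phi, params.optimum_offset)
    gauss = np.exp(-0.5 * ((T - S) / params.omega) ** 2)
    W = f * gauss - params.gamma * np.asarray(B, dtype=float)
    out = np.clip(W, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def apply_selection(state: MetapopState, S_by_deme: np.ndarray,
                    optima_t: np.ndarray, params: ModelParams,
                    rng: np.random.Generator) -> MetapopState:
    """Viability selection: keep each individual with probability W.

    Each individual is evaluated in its current deme's selection
    environment; a deme may lose all of its occupants.
    """
    if state.extinct:
        return state
    T = state.trait.reshape(state.n_individuals, -1).sum(axis=1)
    A = state.constr.reshape(state.n_individuals, -1).sum(axis=1)
    B = individual_construction(A)
    S = S_by_deme[state.deme]
    opt = optima_t[state.deme]
    W = survival_probability(T, S, opt, B, params)
    keep = rng.random(state.n_individuals) < W
    state.trait = state.trait[keep]
    state.constr = state.constr[keep]
    state.deme = state.deme[keep]
    return state


def island_disperse(state: MetapopState, rate: float,
                    rng: np.random.Generator) -> MetapopState:
    """Island dispersal: movers land uniformly on one of the other demes.

    Each individual moves with probability ``rate``; dispersal is cost-free
    and conserves the individual count.
    """
    if rate == 0.0 or state.extinct:
        return state
    if state.n_demes < 2:
        raise ConfigurationError("island dispersal requires at least 2 demes")
    move = rng.random(state.n_individuals) < rate
    n_move = int(move.sum())
    if n_move:
        dest = rng.integers(0, state.n_demes - 1, size=n_move)
        cur = state.deme[move]
        dest = dest + (dest >= cur)  # skip the source deme
        state.deme[move] = dest
    return state


def displacement(z) -> int | np.ndarray:
    """Stepping-stone displacement: the integer part of the Gaussian draw.

    Truncation is toward zero, so |z| < 1 means no movement; the sign of z
    gives the direction.
    """
    out = np.trunc(z).astype(int)
    return int(out) if np.ndim(out) == 0 else out


def sigma_for_rate(rate: float) -> float:
    """Kernel SD σ such that P(|trunc(z)| ≥ 1) = rate for z ~ N(0, σ²).

    Solves 2(1 − Φ(1/σ)) = rate in closed form: σ = 1/Φ⁻¹(1 − rate/2).
    rate = 0 returns σ = 0 (nobody moves); rates ≥ 1 are unattainable for a
    finite σ.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError(f"stepping-stone rate {rate!r} must lie in [0, 1)")
    if rate == 0.0:
        return 0.0
    return 1.0 / float(ndtri(1.0 - rate / 2.0))


def stepping_stone_disperse(state: MetapopState, spec: DispersalSpec,
                            rng: np.random.Generator) -> MetapopState:
    """Stepping-stone dispersal along the linear deme array.

    Every individual draws one Gaussian deviate with SD ``spec.kernel_sd``;
    its integer part is the signed number of demes moved. Moves past either
    end stop at the end deme. Count-conserving and cost-free.
    """
    if spec.kernel_sd == 0.0 or state.extinct:
        return state
    z = rng.normal(0.0, spec.kernel_sd, size=state.n_individuals)
    new = state.deme + displacement(z)
    np.clip(new, 0, state.n_demes - 1, out=new)
    state.deme = new
    return state


def disperse(state: MetapopState, spec: DispersalSpec,
             rng: np.random.Generator) -> MetapopState:
    if spec.pattern == "island":
        return island_disperse(state, spec.rate, rng)
    return stepping_stone_disperse(state, spec, rng)


def make_gamete(genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete: per locus, one of the two homologs, independently.

    Returns a (2, 5) array: row 0 the trait alleles, row 1 the construction
    alleles. Loci are unlinked within and between classes (free
    recombination), so each of the 10 choices is an independent coin flip.
    """
    pick_t = rng.integers(0, PLOIDY, size=N_LOCI)
    pick_c = rng.integers(0, PLOIDY, size=N_LOCI)
    loci = np.arange(N_LOCI)
    return np.stack([genome.trait_alleles[loci, pick_t],
                     genome.construction_alleles[loci, pick_c]])


def mutate(alleles: np.ndarray, rate: float, sd: float,
           rng: np.random.Generator) -> np.ndarray:
    """Continuum-of-alleles mutation.

    Each allele independently mutates with probability ``rate`` by adding a
    zero-mean Gaussian deviate of SD ``sd``; values stay unbounded.
    Returns a new array; the input is not modified.
    """
    if not 0.0 <= rate <= 1.0 or sd < 0:
        raise ConfigurationError("mutation rate must lie in [0,1] and sd be >= 0")
    out = np.array(alleles, dtype=float, copy=True)
    if rate == 0.0 or sd == 0.0 or out.size == 0:
        return out
    hit = rng.random(out.shape) < rate
    out[hit] += rng.normal(0.0, sd, size=int(hit.sum()))
    return out


def _gametes(parent_trait: np.ndarray, parent_constr: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gametes for a batch of parents: (n,5,2) diploid → (n,5) haploid."""
    n = parent_trait.shape[0]
    rows = np.arange(n)[:, None]
    loci = np.arange(N_LOCI)[None, :]
    pick_t = rng.integers(0, PLOIDY, size=(n, N_LOCI))
    pick_c = rng.integers(0, PLOIDY, size=(n, N_LOCI))
    return parent_trait[rows, loci, pick_t], parent_constr[rows, loci, pick_c]


def reproduce_deme(surv_trait: np.ndarray, surv_constr: np.ndarray,
                   capacity: int, params: ModelParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Soft-selection reproduction within one deme.

    Given the survivors' allele arrays ((m, 5, 2) each), produce exactly
    ``capacity`` offspring (zero if there are no survivors): for each
    offspring two parents are drawn independently with replacement (a pair
    lasts for one offspring; selfing is possible), each contributes a
    mutated gamete, and the two gametes form the diploid newborn. Offspring
    number is independent of how many adults survived.
    """
    m = surv_trait.shape[0]
    if m == 0 or capacity == 0:
        empty = np.empty((0, N_LOCI, PLOIDY))
        return empty, empty.copy()
    pidx = rng.integers(0, m, size=(capacity, 2))
    off_t = np.empty((capacity, N_LOCI, PLOIDY))
    off_c = np.empty((capacity, N_LOCI, PLOIDY))
    for h in range(2):
        gt, gc = _gametes(surv_trait[pidx[:, h]], surv_constr[pidx[:, h]], rng)
        off_t[:, :, h] = mutate(gt, params.mutation_rate, params.mutation_sd, rng)
        off_c[:, :, h] = mutate(gc, params.mutation_rate, params.mutation_sd, rng)
    return off_t, off_c


def reproduce_all(state: MetapopState, params: ModelParams,
                  rng: np.random.Generator, mutation: bool = True) -> MetapopState:
    """Refill every occupied deme to capacity; empty demes stay empty.

    Vectorized across demes: parent indices are drawn per occupied deme in
    one batch, then gametes and mutation are applied to the whole offspring
    cohort at once.
    """
    n_demes, cap = state.n_demes, state.capacity
    if state.extinct:
        return state
    order = np.argsort(state.deme, kind="stable")
    deme_sorted = state.deme[order]
    counts = np.bincount(deme_sorted, minlength=n_demes)
    occupied = np.flatnonzero(counts)
    starts = np.concatenate(([0], np.cumsum(counts)))[occupied]
    # two parents per offspring, capacity offspring per occupied deme
    u = rng.random((occupied.size, cap, 2))
    local = (u * counts[occupied][:, None, None]).astype(np.int64)
    parents = order[(local + starts[:, None, None]).reshape(-1, 2)]

    rate = params.mutation_rate if mutation else 0.0
    n_off = parents.shape[0]
    off_t = np.empty((n_off, N_LOCI, PLOIDY))
    off_c = np.empty((n_off, N_LOCI, PLOIDY))
    for h in range(2):
        gt, gc = _gametes(state.trait[parents[:, h]], state.constr[parents[:, h]], rng)
        off_t[:, :, h] = mutate(gt, rate, params.mutation_sd, rng)
        off_c[:, :, h] = mutate(gc, rate, params.mutation_sd, rng)

    state.trait = off_t
    state.constr = off_c
    state.deme = np.repeat(occupied, cap)
    return state


def run_generation(state: MetapopState, profile: EnvironmentProfile,
                   params: ModelParams, rng: np.random.Generator,
                   spec: DispersalSpec | None = None,
                   noise: TemporalNoise | None = None) -> MetapopState:
    """Advance the metapopulation by one full generation.

    Order: environmental decay; deme-level construction by the current
    (newborn) occupants; temporal noise; then dispersal/selection in the
    order set by the life history; finally soft-selection reproduction.
    The end-of-generation environment is the selection environment S
    (including the z deviate when noise targets S and persistence is on).
    """
    if state.extinct:
        warnings.warn("run_generation called on an extinct metapopulation; no-op")
        return state
    if spec is None:
        spec = DispersalSpec.from_params(params)
    if noise is None:
        noise = TemporalNoise.from_params(params)

    n = state.n_individuals
    A = state.constr.reshape(n, -1).sum(axis=1)
    B = individual_construction(A)
    sum_B = np.bincount(state.deme, weights=B, minlength=state.n_demes)
    dE = decay_step(state.env, profile.baselines, params.delta)
    dH = deme_construction_from_total(sum_B)
    z = temporal_deviates(noise, state.n_demes, rng)

    if noise.target == "selection_env":
        S = selection_environment(state.env, dE, dH, z)
        state.env = S if params.noise_persists else S - z
        optima_t = profile.optima
    elif noise.target == "optimum":
        S = selection_environment(state.env, dE, dH)
        state.env = S
        optima_t = effective_optimum(profile.optima, z)  # not stored past selection
    else:
        S = selection_environment(state.env, dE, dH)
        state.env = S
        optima_t = profile.optima

    if params.life_history == "move_first":
        state = disperse(state, spec, rng)
        state = apply_selection(state, S, optima_t, params, rng)
    else:
        state = apply_selection(state, S, optima_t, params, rng)
        state = disperse(state, spec, rng)
    state = reproduce_all(state, params, rng)
    state.generation += 1
    return state
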