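"""Domain types and genotype maps.

Individuals carry two classes of five unlinked diploid loci: trait loci,
whose allelic values sum to the phenotype, and construction loci, whose
allelic values sum to the construction propensity A. The propensity maps
through a logistic to the amount of construction B an individual performs,
bounded in (0, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .params import ConfigurationError, ModelParams

N_LOCI = 5          # per allele class (trait, construction)
PLOIDY = 2
INIT_ALLELE_VALUES = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
B_MAX = 5.0         # asymptote of individual construction
B_SLOPE = 5.0       # steepness of the logistic in the propensity


def _as_loci(alleles) -> np.ndarray:
    """Coerce 10 allelic values (flat or (5, 2)) to a float (5, 2) array."""
    a = np.asarray(alleles, dtype=float)
    if a.size != N_LOCI * PLOIDY:
        raise ValueError(f"expected {N_LOCI * PLOIDY} allelic values, got {a.size}")
    return a.reshape(N_LOCI, PLOIDY)


@dataclass
class Genome:
    """Ten trait and ten construction allelic values, stored by (locus, homolog)."""

    trait_alleles: np.ndarray
    construction_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.trait_alleles = _as_loci(self.trait_alleles)
        self.construction_alleles = _as_loci(self.construction_alleles)


@dataclass
class Individual:
    genome: Genome
    deme_index: int
    survived: bool = True


@dataclass
class Deme:
    """A habitat patch: baseline θ, optimum θ*, current environment E, capacity N."""

    index: int
    baseline: float
    optimum: float
    environment: float
    capacity: int


@dataclass
class MetapopState:
    """Vectorized metapopulation state.

    ``trait`` and ``constr`` have shape (n_individuals, 5, 2); ``deme`` is the
    integer deme index of each individual. ``env`` holds the current
    environment of every deme (tracked even for empty demes, which keep
    decaying toward baseline).
    """

    trait: np.ndarray
    constr: np.ndarray
    deme: np.ndarray
    env: np.ndarray
    capacity: int
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return self.deme.shape[0]

    @property
    def n_demes(self) -> int:
        return self.env.shape[0]

    @property
    def extinct(self) -> bool:
        return self.n_individuals == 0

    def occupancy(self) -> np.ndarray:
        """Number of individuals currently in each deme."""
        return np.bincount(self.deme, minlength=self.n_demes)

    def individuals(self) -> list[Individual]:
        """Materialize object views of the population (for inspection/tests)."""
        return [
            Individual(Genome(self.trait[j].copy(), self.constr[j].copy()), int(self.deme[j]))
            for j in range(self.n_individuals)
        ]

    def demes(self, profile) -> list[Deme]:
        return [
            Deme(i, float(profile.baselines[i]), float(profile.optima[i]),
                 float(self.env[i]), self.capacity)
            for i in range(self.n_demes)
        ]


def phenotype(genome) -> float | np.ndarray:
    """Additive phenotype: the sum of the ten trait allelic values.

    Accepts a :class:`Genome` or an array of allelic values whose last axes
    hold the 10 values (e.g. the population's (n, 5, 2) trait array, giving a
    vector of n phenotypes). There is no environmental/random component.
    """
    if isinstance(genome, Genome):
        return float(genome.trait_alleles.sum())
    a = np.asarray(genome, dtype=float)
    if a.ndim <= 2:
        return float(a.sum())
    return a.reshape(a.shape[0], -1).sum(axis=1)


def construction_propensity(genome) -> float | np.ndarray:
    """Construction propensity A: the sum of the ten construction allelic values."""
    if isinstance(genome, Genome):
        return float(genome.construction_alleles.sum())
    a = np.asarray(genome, dtype=float)
    if a.ndim <= 2:
        return float(a.sum())
    return a.reshape(a.shape[0], -1).sum(axis=1)


def individual_construction(A) -> float | np.ndarray:
    """Amount of construction B = 5 / (1 + exp(−5A)).

    Computed via the logistic sigmoid, which is numerically stable for any
    finite propensity (alleles are unbounded reals). B(0) = 2.5 and
    0 < B < 5 for all finite A.
    """
    A = np.asarray(A, dtype=float)
    out = B_MAX * expit(B_SLOPE * A)
    return float(out) if out.ndim == 0 else out


def init_metapopulation(params: ModelParams, rng: np.random.Generator,
                        profile=None) -> MetapopState:
    """Found the metapopulation: every deme filled to capacity with newborns.

    Each of the 20 allelic values is drawn uniformly from {−2, −1, 0, 1, 2},
    so the expected propensity is 0 and the expected individual construction
    is 2.5. Every deme's environment starts at its baseline.
    """
    from .environment import make_profile  # local import to avoid a cycle

    if profile is None:
        profile = make_profile(params.environment_mode, params.n_demes,
                               params.gradient_spacing, params.optimum_offset)
    if profile.baselines.shape[0] != params.n_demes:
        raise ConfigurationError(
            f"profile has {profile.baselines.shape[0]} demes, params expect {params.n_demes}"
        )
    n = params.total_size
    trait = rng.choice(INIT_ALLELE_VALUES, size=(n, N_LOCI, PLOIDY))
    constr = rng.choice(INIT_ALLELE_VALUES, size=(n, N_LOCI, PLOIDY))
    deme = np.repeat(np.arange(params.n_demes), params.deme_capacity)
    env = profile.baselines.astype(float).copy()
    return MetapopState(trait=trait, constr=constr, deme=deme, env=env,
                        capacity=params.deme_capacity, generation=0)
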