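# Methods

## Model and assumptions

The simulator is a discrete-time, individual-based metapopulation model with
non-overlapping generations and fixed deme carrying capacities. Its purpose
is to ask under which ecological and life-history conditions a heritable
propensity to construct habitat — to push the local environment from its
baseline toward the fitness optimum — is maintained by selection despite an
individual survival cost, when the benefits are shared by every occupant of
the deme.

Assumptions worth keeping in mind:

* **Unresponsive construction.** The amount an individual constructs is a
  fixed function of its genotype; individuals do not sense the environment
  and construct only the deficit. Restraint comes solely from the two
  saturating functions (individual B < 5, deme ΔH < 5 per generation).
* **Within-deme feedback only.** Construction in one deme never spills into
  another; demes interact through dispersal alone.
* **Soft selection.** Each deme with at least one surviving adult is
  refilled exactly to capacity, so deme-level productivity differences do
  not propagate except through whole-deme (local) extinction and
  recolonization.
* **No linkage, dominance, epistasis, plasticity, age structure, sexes, or
  evolving dispersal.** Five unlinked diploid loci per trait class, strictly
  additive; gametes recombine freely; mating is random with replacement and
  selfing is allowed.

## Per-generation order of events

1. decay ΔE = −δ(E − θ) (all demes, occupied or not);
2. deme construction ΔH from the current newborn occupants;
3. temporal deviate z (if configured);
4. dispersal → selection (move first) or selection → dispersal (select
   first);
5. soft-selection reproduction with mutation, generation counter increment.

Selection evaluates each individual in the deme where it sits at selection
time, with optimum phenotype T_opt = S (trait and environment share units).
After the configured number of generations there is one extra round of
mating and reproduction with no decay, construction, noise, selection or
dispersal, so statistics are computed on full demes; the final cohort's
fitness is each newborn's survival probability in its deme's current
environment with the deme's unperturbed optimum.

## Parameters, units and defaults

Environmental quantities are in arbitrary "environment units"; the
baseline-to-optimum distance at the gradient center (10 units) normalizes
both the construction benefit and the reported construction means.

| parameter | meaning | default |
|---|---|---|
| δ (`delta`) | per-generation fractional decay toward baseline | 0.5 |
| ω (`omega`) | Gaussian selection width on the trait (env units; lower = stronger) | 4 |
| γ (`gamma`) | survival cost per unit constructed (max cost γ·5 = 1%) | 0.002 |
| φ (`phi`) | fitness decrease at the baseline environment | 0.5 |
| τ (`tau`) | temporal-deviate SD, fraction of the 10-unit offset | 0 |
| dispersal | island 44% (unstructured) / stepping-stone 41% (gradient) | island 0.44 |
| demes × N | 64 × 8 unstructured (512 total); 50 × 8 gradient (400) | 64 × 8 |
| mutation | per-allele rate 0.1, Gaussian increment SD 0.1 | — |
| generations / replicates | equilibrium horizon / replication | 1000 / 20 |

Founding populations draw every allelic value uniformly from
{−2, −1, 0, 1, 2}: expected propensity 0, expected individual construction
2.5, so early generations construct substantially (this cushions high-φ
regimes against immediate extinction and biases the system toward the
constructing basin — see limitations).

The stepping-stone kernel SD is derived from the requested dispersal rate in
closed form, σ = 1/Φ⁻¹(1 − rate/2), so that P(|trunc(z)| ≥ 1) equals the
rate; rates ≥ 1 are unattainable for this kernel and are rejected.

## Numerical choices

* The logistic for B uses `scipy.special.expit`, stable for arbitrarily
  large |A| (alleles are unbounded).
* Survival W is clamped to [0, 1]; negative values mean certain death.
* The population is stored as flat numpy arrays ((n, 5, 2) alleles per
  class plus a deme index), and every lifecycle step — including
  reproduction across all demes — is vectorized; a 512-individual,
  1000-generation replicate runs in ~0.5 s on one core.
* Replicate r of combination c draws from `numpy` streams seeded by the
  sequence (base_seed, c, r): runs are bit-reproducible and independent of
  grid order.
* Deme-level averages (and gradient regressions, via least squares on deme
  index divided by the 0.4 spacing) use occupied demes only; extinct
  replicates are excluded from across-replicate means and standard errors
  and counted separately. Slopes need ≥ 2 occupied demes, otherwise NaN.

## Design choices where the design was open

* **Temporal deviates on S are transient** (`noise_persists=False`): the
  deviate enters the selection environment but not the end-of-generation E.
  With persistence, correlated deviates at the top of the τ range (SD 2.75
  units, identical in every deme) accumulate as a metapopulation-wide AR(1)
  excursion and frequently extinguish the whole system, which contradicts
  the regime this noise model is meant to represent (background variation
  with near-zero equilibrium effect). The switch is exposed for users who
  want the persistent reading. Optimum deviates are never stored; θ\*
  reverts each generation.
* **Parent pairs are redrawn per offspring** (with replacement, selfing
  allowed); a pair produces exactly one offspring.
* **Mutation acts on gametes** at offspring formation.
* **Locally extinct demes persist** and can be recolonized; the
  metapopulation is extinct only when no individuals remain anywhere.
* **In select-first, reproduction fills the destination deme** (dispersal
  happens between selection and reproduction).

## What the generator/tests do and do not show

The simulation *is* the study system — there is no external data. The test
suite checks the primitives against closed forms (decay balance c/δ, the
ΔH < 5 and B < 5 saturations, the equilibrium ceilings 5N/((1+N)·10δ)),
checks the stochastic operators against their stated distributions
(Mendelian ½, mutation rate/variance, dispersal fractions and uniformity)
at 3-standard-error tolerances, and reproduces the qualitative equilibrium
findings at reduced replication (4–12 replicates instead of 20): the
δ = 40% construction peak for move-first small demes, the monotone rise of
propensity with δ under select-first, insensitivity to island dispersal
rate under select-first, near-ideal gradient slopes (1.0, 0.0) for the
parallel optimum at high φ, and the near-null effect of temporal variation.
Reduced replication means the trend checks have modest power; they are
direction-of-effect tests, not estimates of the full-replication curves.

Two regime notes uncovered while testing:

* With φ = 0 and the default ω, mean propensity does **not** decline despite
  the γ cost — it drifts upward, because saturated construction stabilizes S
  and the indirect feedback through trait selection outweighs the ≤ 1%
  direct cost. The "cost-only" and "neutral-drift" invariants are therefore
  tested with the trait term neutralized (ω → ∞, so W = 1 − γB and W = 1
  respectively), which isolates the stated mechanism.
* Uncorrelated selection-environment noise at the very top of the τ range
  (27.5%) depresses equilibrium construction by ~1.5% of the optimum
  distance — a real but tiny effect, below the resolution of a
  few-replicate band test but visible at high replication.

## Known limitations

* The bimodal construction outcome reported for N = 32 at δ = 20% (some
  populations trapped near maximal construction) is initialization-
  dependent; the preset exposes it but no test asserts it.
* The ideal single-optimum propensity slope of −0.5 is treated as an
  observed benchmark, not an enforced invariant: A maps nonlinearly to B,
  so the linear-slope argument is only approximate.
* Stepping-stone rates arbitrarily close to 1 produce very heavy-tailed
  kernels; presets cap the stepping-stone grid at 92%.
* Dispersal-rate and τ grids use evenly spaced values across their standard
  ranges; only the ranges themselves, the fixed rates (44%, 41%, 4%) and
  the δ/φ grids are pinned by the experimental design the presets encode.
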