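# habconstruct

An individual-based, forward-time simulator for studying when **adaptive
habitat construction** — heritable modification of the local environment that
raises the modifier's (inclusive) fitness — can evolve in a metapopulation,
and when environmental alterations remain mere conditioning that selection
cannot maintain.

It is aimed at evolutionary ecologists and theoreticians exploring
eco-evolutionary feedbacks, kin/group selection in deme-structured
populations, and the interaction of construction with environmental decay,
dispersal pattern, life-history ordering, and spatial/temporal heterogeneity.

## The model

A metapopulation of demes, each with a baseline environment θᵢ, an optimum
θᵢ\*, a current environment Eᵢ, and carrying capacity N. Generations are
discrete and non-overlapping. Each individual carries ten unlinked diploid
loci: five **trait** loci (phenotype T = Σ Gₖ, environment units) and five
**construction** loci (propensity A = Σ Cₖ). An individual constructs

&nbsp;&nbsp;&nbsp;&nbsp;B = 5 / (1 + e^(−5A))  ∈ (0, 5),

and a deme's occupants jointly add

&nbsp;&nbsp;&nbsp;&nbsp;ΔH = ΣB / (1 + 0.2 ΣB)  < 5

to its environment, while decay pulls it back toward baseline at rate δ:
ΔE = −δ(E − θ). The environment at selection is S = E + ΔE + ΔH (plus an
optional zero-mean Gaussian temporal deviate z with SD τ·10, on S or on θ\*,
independent or correlated across demes). Survival from juvenile to adult is

&nbsp;&nbsp;&nbsp;&nbsp;W = f · exp(−½((T − S)/ω)²) − γB,  clamped to [0, 1],

with construction benefit f = 1 − φ|θ\* − S|/10: fitness is maximal when
construction has moved the environment to the optimum (10 units above the
mean baseline) and drops by φ at the baseline. γ = 0.002 makes maximal
construction cost 1% of survival. Dispersal is island (uniform over other
demes) or stepping-stone (signed truncated-Gaussian steps along a linear
gradient with absorbing ends), placed either before selection ("move
first") or after it ("select first"). Reproduction is soft selection:
random mating with replacement (selfing allowed) refills each surviving
deme to capacity; gametes recombine freely and each allele mutates with
probability 0.1 by a Gaussian deviate of SD 0.1 (continuum of alleles).

The headline response variables are the normalized construction mean
(mean E/10; 1.0 = environment held at the optimum), the mean propensity A,
mean fitness W, and — on gradients — the slopes of deme-mean E and A
against position, normalized by the 0.4-unit baseline spacing.

## Worked example

```python
from habconstruct import ModelParams, run_replicates

result = run_replicates(ModelParams(), n_reps=5, base_seed=1)
agg = result.aggregate()
print(f"mean E/10: {agg['mean_construction_mean']:.3f} ± {agg['mean_construction_se']:.3f}")
print(f"mean A:    {agg['mean_propensity_mean']:.2f}")
print(f"mean W:    {agg['mean_fitness_mean']:.3f}")
```

prints, for the default regime (64 demes × 8, δ = 50%, island dispersal 44%,
select-first, φ = 50%, 1000 generations):

```
mean E/10: 0.882 ± 0.006
mean A:    6.80
mean W:    0.894
```

Construction evolved: the average deme environment is held ~88% of the way
to the optimum against 50% decay per generation, the mean construction
propensity rose from its founding value of 0 to strongly positive (B
saturated near its maximum of 5), and mean survival sits near 0.9. The
scripts in `examples/` walk through the other capabilities — the decay
sweep that locates the construction peak at δ = 40% for small demes, the
gradient runs whose normalized slopes diagnose parallel vs single-optimum
adaptation, and the temporal-noise experiment.

A thin CLI mirrors the library: `habconstruct run` (one combination),
`habconstruct sweep <preset>` (a predefined parameter grid; see
`habconstruct presets`), and `habconstruct check` (closed-form sanity
checks). Results are written as tidy replicate/aggregate CSVs with a JSON
metadata sidecar.

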