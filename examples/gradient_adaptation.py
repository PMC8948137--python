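"""Construction along an environmental gradient: parallel vs single optimum.

On a 50-deme linear gradient (baselines −9.8 … +9.8, stepping-stone
dispersal at 41%), the optimum either tracks the baseline (parallel: the
same amount of construction is ideal everywhere) or is flat (single: demes
need genetically differentiated construction, from a lot at one end to none
at the other). Normalized slopes of the deme means diagnose the outcome:
perfect parallel adaptation gives a construction slope of 1.0 and a
propensity slope of 0.0; for the single optimum the ideals are 0.0 and −0.5.
"""

from habconstruct import ModelParams, run_replicates

for mode in ("gradient_parallel", "gradient_single"):
    p = ModelParams(n_demes=50, deme_capacity=8, environment_mode=mode,
                    dispersal_pattern="stepping_stone", dispersal_rate=0.41,
                    life_history="select_first", phi=0.9)
    agg = run_replicates(p, n_reps=4, base_seed=3).aggregate()
    print(f"{mode:18s}  E-slope {agg['construction_slope_mean']:+.2f}"
          f"  A-slope {agg['propensity_slope_mean']:+.2f}"
          f"  mean E/10 {agg['mean_construction_mean']:.2f}"
          f"  mean W {agg['mean_fitness_mean']:.3f}")

print()
print("With a strong benefit (phi=90%) and selection before dispersal, the")
print("parallel optimum is tracked almost perfectly (slopes ~1 and ~0); under a")
print("single optimum the propensity must differentiate along the gradient,")
print("which indirect selection achieves only partially.")
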