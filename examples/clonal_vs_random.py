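"""Clonal versus random-mating guilds: replicate-run comparison.

A scaled-down version of the headline experiment: several independent
epochs per reproduction mode, total biomass produced per generation,
phase totals over the burn-in (generations 1-125) and
approach-to-equilibrium (126-250) phases, and a Welch t-test between
modes.  (The full design uses 50 runs per mode; this demo uses 4 to
finish in a couple of minutes.)
"""

from guildsim import (
    EpochConfig, ExperimentConfig, ReproductionMode, compare_modes,
    run_experiment,
)

cfg = ExperimentConfig(
    base=EpochConfig(n_agents=100, n_generations=250),
    modes=(ReproductionMode.CLONAL, ReproductionMode.DIPLOID_RANDOM),
    n_runs=4,
    base_seed=0,
)
result = run_experiment(cfg)
print(result.summary().round(1).to_string(index=False))

for phase in cfg.phases:
    rep = compare_modes(result, phase)
    print(f"\nphase {rep.phase}: clonal {rep.mean_a:.0f} vs "
          f"random mating {rep.mean_b:.0f}")
    print(f"  Welch t = {rep.t_stat:.2f} (df {rep.t_df:.1f}), p = {rep.t_p:.2g}; "
          f"variance ratio F = {rep.f_stat:.2f}, p = {rep.f_p:.2g}")

print("\nEarly in the epoch a monomorphic clonal guild over-exploits the",
      "shared landscape; its advantage over random mating emerges only in",
      "the later, polymorphic phase (more replicate runs sharpen the",
      "second-phase contrast into significance).", sep="\n")
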