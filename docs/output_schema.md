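# Output file schemas

## `evolve --out DIR`

* `records.csv` — one row per generation:
  `generation, total_biomass, fitness_mean, fitness_sd,
  alpha_mean, alpha_sd, delta_mean, delta_sd, rho_mean, rho_sd`.
* `final_population.csv` — one row per agent of the final generation:
  `agent_id, alpha, delta, rho, fitness`.
* `epoch.json` — config echo (`n_agents, mode, n_ticks, n_generations,
  grid, schedule`), the seed, and the per-generation rows of
  `records.csv` as JSON records.

## `experiment --out DIR`

* `per_generation.csv` — `mode, run, seed, generation, total_biomass`.
* `phase_totals.csv` — `mode, run, seed, phase, total` where `phase` is
  an inclusive generation range label like `1-125` and `total` is the
  sum of `total_biomass` over that range for that run.
* `summary.json` — per-(mode, phase) `count, mean, var, std` of phase
  totals, plus (when two or more modes and runs are present) one test
  record per phase: Welch two-sided t (`t_stat, t_df, t_p`) and the
  variance-ratio F test (`f_stat, f_p`) with per-mode means/variances.

## `analyze --out FILE`

Morph table, one row per movement-type morph sorted by mean alpha:
`morph, count, alpha_mean, alpha_sd, delta_mean, delta_sd, rho_mean,
rho_sd[, fitness_mean, fitness_sd]`.

## `scripts/acceptance.py --out FILE`

JSON object keyed by target id; each entry holds `value` (the
recomputed quantity), `n` (number of replicate epochs) and `per_seed`
values.
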