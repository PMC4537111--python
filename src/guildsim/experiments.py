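"""Multi-run experiment driver: replicate epochs and mode comparisons.

The central study design compares clonal against random-mating guilds:
run many independent epochs per reproduction mode, total the biomass
produced per generation, sum it over two phases of the epoch (a burn-in
phase and an approach-to-equilibrium phase, by default generations
1-125 and 126-250), and compare modes with a Welch two-sided t-test on
the phase totals plus an F-ratio test for unequal variances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .foraging import Agent
from .evolution import EpochConfig, EpochResult, ReproductionMode, run_epoch

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "PhaseComparison",
    "total_biomass_per_generation",
    "run_experiment",
    "compare_modes",
]

logger = logging.getLogger("guildsim.experiments")


def total_biomass_per_generation(agents: list[Agent]) -> float:
    """Total biomass accumulated by a generation: sum of B_a(n) over agents."""
    return float(sum(a.biomass for a in agents))


@dataclass(frozen=True)
class ExperimentConfig:
    """A replicate-run comparison design.

    ``base`` supplies everything but the reproduction mode; each mode in
    ``modes`` is run ``n_runs`` times with seeds base_seed + run index,
    so any single run can be reproduced in isolation.  Phases are
    inclusive generation ranges and must be disjoint, ordered and within
    the epoch.
    """

    base: EpochConfig = field(default_factory=lambda: EpochConfig(n_generations=250))
    modes: tuple[ReproductionMode, ...] = (
        ReproductionMode.CLONAL,
        ReproductionMode.DIPLOID_RANDOM,
    )
    n_runs: int = 50
    base_seed: int = 0
    phases: tuple[tuple[int, int], ...] = ((1, 125), (126, 250))

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        prev_end = 0
        for lo, hi in self.phases:
            if not (prev_end < lo <= hi <= self.base.n_generations):
                raise ValueError(
                    f"phases must be disjoint, ordered and within "
                    f"1..{self.base.n_generations}, got {self.phases}"
                )
            prev_end = hi

    def phase_label(self, phase: tuple[int, int]) -> str:
        return f"{phase[0]}-{phase[1]}"


@dataclass
class PhaseComparison:
    """Two-mode comparison of phase totals across replicate runs."""

    phase: str
    mode_a: str
    mode_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    t_stat: float
    t_df: float
    t_p: float
    f_stat: float
    f_p: float


@dataclass
class ExperimentResult:
    """Raw and aggregated output of a replicate-run experiment."""

    config: ExperimentConfig
    per_generation: pd.DataFrame  # mode, run, seed, generation, total_biomass
    phase_totals: pd.DataFrame    # mode, run, seed, phase, total

    def summary(self) -> pd.DataFrame:
        """Across-run mean and variance of phase totals per mode."""
        g = self.phase_totals.groupby(["mode", "phase"])["total"]
        out = g.agg(["count", "mean", "var", "std"]).reset_index()
        return out

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_generation.to_csv(outdir / "per_generation.csv", index=False)
        self.phase_totals.to_csv(outdir / "phase_totals.csv", index=False)
        payload = {"summary": self.summary().to_dict(orient="records")}
        if len(self.config.modes) >= 2 and self.n_runs_per_mode() >= 2:
            payload["tests"] = [
                vars(compare_modes(self, phase)) for phase in self.config.phases
            ]
        (outdir / "summary.json").write_text(json.dumps(payload, indent=2))

    def n_runs_per_mode(self) -> int:
        return self.config.n_runs


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run every (mode, replicate) epoch and tabulate phase totals.

    Seeds are ``base_seed + run_index`` (shared across modes, so the
    mode comparison is a paired-seed design on independent streams).
    """
    gen_rows = []
    phase_rows = []
    for mode in config.modes:
        epoch_cfg = replace(config.base, mode=mode)
        for run in range(config.n_runs):
            seed = config.base_seed + run
            result = run_epoch(epoch_cfg, seed=seed)
            totals = result.total_biomass_trajectory()
            for rec in result.records:
                logger.info(
                    "mode=%s run=%d T=%d total_biomass=%.3f mean_fitness=%.3f",
                    mode.value, run, rec.generation, rec.total_biomass,
                    rec.fitness_mean,
                )
            gens = np.arange(1, len(totals) + 1)
            gen_rows.append(
                pd.DataFrame(
                    {
                        "mode": mode.value,
                        "run": run,
                        "seed": seed,
                        "generation": gens,
                        "total_biomass": totals,
                    }
                )
            )
            for phase in config.phases:
                lo, hi = phase
                phase_rows.append(
                    {
                        "mode": mode.value,
                        "run": run,
                        "seed": seed,
                        "phase": config.phase_label(phase),
                        "total": float(totals[lo - 1 : hi].sum()),
                    }
                )
            if progress:
                print(f"  finished mode={mode.value} run={run} seed={seed}")
    return ExperimentResult(
        config=config,
        per_generation=pd.concat(gen_rows, ignore_index=True),
        phase_totals=pd.DataFrame(phase_rows),
    )


def compare_modes(
    result: ExperimentResult,
    phase: tuple[int, int] | str,
    mode_a: ReproductionMode | str | None = None,
    mode_b: ReproductionMode | str | None = None,
) -> PhaseComparison:
    """Welch two-sided t-test and F variance-ratio test on one phase.

    Defaults to the experiment's first two modes.  Requires at least two
    runs per mode (otherwise variances are undefined).
    """
    cfg = result.config
    label = phase if isinstance(phase, str) else cfg.phase_label(phase)
    mode_a = mode_a or cfg.modes[0]
    mode_b = mode_b or cfg.modes[1]
    name_a = mode_a.value if isinstance(mode_a, ReproductionMode) else str(mode_a)
    name_b = mode_b.value if isinstance(mode_b, ReproductionMode) else str(mode_b)

    pt = result.phase_totals
    a = pt.loc[(pt["mode"] == name_a) & (pt["phase"] == label), "total"].to_numpy()
    b = pt.loc[(pt["mode"] == name_b) & (pt["phase"] == label), "total"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("mode comparison needs at least two runs per mode")

    t_res = stats.ttest_ind(a, b, equal_var=False)
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_b == 0:
        f_stat, f_p = float("inf"), 0.0
    else:
        f_stat = var_a / var_b
        dfn, dfd = len(a) - 1, len(b) - 1
        tail = stats.f.sf(f_stat, dfn, dfd)
        f_p = float(min(1.0, 2.0 * min(tail, 1.0 - tail)))

    return PhaseComparison(
        phase=label,
        mode_a=name_a,
        mode_b=name_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=var_a,
        var_b=var_b,
        t_stat=float(t_res.statistic),
        t_df=float(t_res.df),
        t_p=float(t_res.pvalue),
        f_stat=float(f_stat),
        f_p=f_p,
    )
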