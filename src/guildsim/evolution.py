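"""Genetic algorithm layer: selection, mutation schedule, reproduction, epochs.

Selection is hard truncation: agents are ranked by their end-of-generation
biomass B_a(n) and the fittest half reproduce.  The maximum mutation
perturbation shrinks over generations (simulated annealing),

    mu(T) = (mu0 - mu_inf) / (1 + (T / psi)^3) + mu_inf,

so early epochs explore trait space coarsely and late epochs refine.
Perturbations are uniform on [-mu, mu] and are never clamped: slightly
negative evolved trait values are legitimate outcomes.

Three reproduction modes:

CLONAL            fittest half survive unchanged, each adds one mutated clone.
AVERAGING_SEXUAL  fittest half pair at random; each pair leaves 4 progeny
                  whose traits are the parental means, then mutated
                  (a deliberately naive haploid stand-in for sex).
DIPLOID_RANDOM    hermaphroditic random mating with diploid codominant
                  genetics: two alleles per trait, one inherited from each
                  parent by random segregation, no linkage, each inherited
                  allele mutated, phenotype = mean of the two alleles.

An epoch is G generations.  Each generation the agents are re-placed at
random and their biomass reset, while the resource landscape persists
across generations within the epoch (initialised once, at T = 1):
genotypes and the standing crop of resources are the only state carried
between generations.  This shared landscape is what couples guild
density to per-capita productivity — dense guilds keep the landscape
cropped down and earn less per head.  A per-generation resource
re-initialisation is available via ``fresh_landscape_each_generation``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foraging import Agent, ForagingParams, GenerationRecord, run_generation
from .landscape import GridSpec, ResourceParams, init_resources
from .movement import MovementParams

__all__ = [
    "MutationSchedule",
    "Ploidy",
    "Genotype",
    "ReproductionMode",
    "EpochConfig",
    "EpochResult",
    "mutation_scale",
    "select_fittest",
    "mutate_value",
    "reproduce_clonal",
    "reproduce_averaging",
    "reproduce_diploid",
    "run_epoch",
]

_TRAITS = ("alpha", "delta", "rho")


@dataclass(frozen=True)
class MutationSchedule:
    """Annealing schedule (mu0, mu_inf, psi) for the mutation size mu(T).

    mu0 is the initial maximum perturbation, mu_inf the asymptotic one,
    psi the time constant in generations: mu(psi) sits halfway between
    mu0 and mu_inf.
    """

    mu0: float = 0.1
    mu_inf: float = 0.001
    psi: float = 50.0

    def __post_init__(self) -> None:
        if not self.mu0 > self.mu_inf > 0:
            raise ValueError(
                f"need mu0 > mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")


class Ploidy(enum.Enum):
    HAPLOID = "haploid"
    DIPLOID = "diploid"


@dataclass
class Genotype:
    """Genetic state of one agent.

    Haploid: one value per trait (the genome *is* the phenotype).
    Diploid: two alleles per trait, expressed codominantly (phenotype =
    arithmetic mean of the two allele values, exactly).  ``tags`` carry
    integer lineage labels per allele so allele identity in analyses is
    by descent, never by rounding numeric values.
    """

    ploidy: Ploidy
    values: np.ndarray | None = None   # (3,) for haploid
    alleles: np.ndarray | None = None  # (3, 2) for diploid
    tags: np.ndarray | None = None     # (3, 2) int lineage labels

    def phenotype(self) -> MovementParams:
        if self.ploidy is Ploidy.HAPLOID:
            v = self.values
        else:
            v = self.alleles.mean(axis=1)
        return MovementParams(alpha=float(v[0]), delta=float(v[1]), rho=float(v[2]))


class ReproductionMode(enum.Enum):
    CLONAL = "clonal"
    AVERAGING_SEXUAL = "averaging"
    DIPLOID_RANDOM = "diploid"


def mutation_scale(T: float, schedule: MutationSchedule) -> float:
    """Maximum mutation size mu(T) at generation T (monotone decreasing)."""
    if T < 0:
        raise ValueError(f"generation must be >= 0, got {T}")
    return (schedule.mu0 - schedule.mu_inf) / (1.0 + (T / schedule.psi) ** 3) + schedule.mu_inf


def select_fittest(agents: list[Agent]) -> list[Agent]:
    """Hard selection: the fittest half by biomass, ties broken by id."""
    if not agents:
        raise ValueError("cannot select from an empty population")
    if any(math.isnan(a.biomass) for a in agents):
        raise ValueError("NaN fitness encountered; engine bug upstream")
    ranked = sorted(agents, key=lambda a: (-a.biomass, a.id))
    return ranked[: len(agents) // 2]


def mutate_value(x: float, mu: float, rng: np.random.Generator) -> float:
    """Perturb a value by U[-mu, mu].  No clamping."""
    if mu < 0:
        raise ValueError(f"mutation scale must be >= 0, got {mu}")
    return float(x + rng.uniform(-mu, mu))


def _traits_array(parents: list[Agent]) -> np.ndarray:
    return np.array([[a.phenotype.alpha, a.phenotype.delta, a.phenotype.rho]
                     for a in parents])


def _haploid_agent(i: int, traits: np.ndarray) -> Agent:
    pheno = MovementParams(*map(float, traits))
    return Agent(id=i, location=-1, biomass=0.0, phenotype=pheno,
                 genotype=Genotype(Ploidy.HAPLOID, values=np.asarray(traits, dtype=float)))


def reproduce_clonal(
    parents: list[Agent], T: int, schedule: MutationSchedule,
    rng: np.random.Generator,
) -> list[Agent]:
    """Parents survive unchanged; each contributes one mutated clone.

    Output size is 2 * len(parents); ids are renumbered with parents
    first (in rank order) followed by their clones.
    """
    traits = _traits_array(parents)
    mu = mutation_scale(T, schedule)
    noise = rng.uniform(-mu, mu, size=traits.shape)
    clones = traits + noise
    out = [_haploid_agent(i, traits[i]) for i in range(len(parents))]
    out += [_haploid_agent(len(parents) + i, clones[i]) for i in range(len(parents))]
    return out


def _random_pairs(n_parents: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if n_parents % 2:
        raise ValueError("sexual reproduction needs an even number of parents")
    perm = rng.permutation(n_parents)
    return perm[0::2], perm[1::2]


def reproduce_averaging(
    parents: list[Agent], T: int, schedule: MutationSchedule,
    rng: np.random.Generator,
) -> list[Agent]:
    """Random pairing; 4 progeny per pair, traits = parental mean + mutation.

    Full replacement: the next generation consists of progeny only.
    """
    traits = _traits_array(parents)
    p1, p2 = _random_pairs(len(parents), rng)
    mid = 0.5 * (traits[p1] + traits[p2])       # (n_pairs, 3)
    child_mid = np.repeat(mid, 4, axis=0)       # 4 progeny per pair
    mu = mutation_scale(T, schedule)
    children = child_mid + rng.uniform(-mu, mu, size=child_mid.shape)
    return [_haploid_agent(i, children[i]) for i in range(len(children))]


def reproduce_diploid(
    parents: list[Agent], T: int, schedule: MutationSchedule,
    rng: np.random.Generator,
) -> list[Agent]:
    """Hermaphroditic random mating with diploid codominant genetics.

    For each progeny and each trait independently, one allele is drawn
    uniformly from each parent's two alleles (random segregation, no
    linkage between traits); every inherited allele is then mutated with
    mu(T); lineage tags pass through mutation unchanged.
    """
    for p in parents:
        if p.genotype is None or p.genotype.ploidy is not Ploidy.DIPLOID:
            raise TypeError("diploid reproduction requires diploid parents")
    A = np.stack([p.genotype.alleles for p in parents])  # (m, 3, 2)
    tags = np.stack([p.genotype.tags for p in parents])
    p1, p2 = _random_pairs(len(parents), rng)
    par1 = np.repeat(p1, 4)
    par2 = np.repeat(p2, 4)
    n_prog = par1.shape[0]

    pick1 = rng.integers(0, 2, size=(n_prog, 3))
    pick2 = rng.integers(0, 2, size=(n_prog, 3))
    tr = np.arange(3)
    a1 = A[par1[:, None], tr, pick1]
    a2 = A[par2[:, None], tr, pick2]
    t1 = tags[par1[:, None], tr, pick1]
    t2 = tags[par2[:, None], tr, pick2]

    mu = mutation_scale(T, schedule)
    child_alleles = np.stack([a1, a2], axis=2)  # (n_prog, 3, 2)
    child_alleles = child_alleles + rng.uniform(-mu, mu, size=child_alleles.shape)
    child_tags = np.stack([t1, t2], axis=2)

    out = []
    for i in range(n_prog):
        geno = Genotype(Ploidy.DIPLOID, alleles=child_alleles[i], tags=child_tags[i])
        out.append(Agent(id=i, location=-1, biomass=0.0,
                         phenotype=geno.phenotype(), genotype=geno))
    return out


_REPRODUCERS = {
    ReproductionMode.CLONAL: reproduce_clonal,
    ReproductionMode.AVERAGING_SEXUAL: reproduce_averaging,
    ReproductionMode.DIPLOID_RANDOM: reproduce_diploid,
}


@dataclass(frozen=True)
class EpochConfig:
    """Full configuration of one evolutionary run.

    Defaults are the baseline study conditions: a 20x20 toroidal grid,
    100-tick generations, 200-generation epochs, and the annealed
    mutation schedule (0.1 -> 0.001, psi = 50).  Initial trait values
    (and in diploid mode each allele independently) are uniform on
    [init_low, init_high] = [0, 1].
    """

    n_agents: int = 100
    mode: ReproductionMode = ReproductionMode.CLONAL
    n_ticks: int = 100
    n_generations: int = 200
    grid: GridSpec = field(default_factory=GridSpec)
    resources: ResourceParams = field(default_factory=ResourceParams)
    foraging: ForagingParams = field(default_factory=ForagingParams)
    schedule: MutationSchedule = field(default_factory=MutationSchedule)
    initial_biomass: float = 0.0
    init_low: float = 0.0
    init_high: float = 1.0
    self_excluded: bool = True
    fresh_landscape_each_generation: bool = False
    snapshot_generations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.mode is ReproductionMode.CLONAL and self.n_agents % 2:
            raise ValueError("clonal reproduction needs an even population size")
        if self.mode is not ReproductionMode.CLONAL and self.n_agents % 4:
            raise ValueError(
                "sexual modes need a population divisible by 4 "
                "(each parent pair produces 4 progeny)"
            )
        if self.n_generations < 1:
            raise ValueError("an epoch needs at least one generation")
        if self.n_ticks < 0:
            raise ValueError("n_ticks must be >= 0")

    @property
    def density(self) -> float:
        """Agents per patch."""
        return self.n_agents / self.grid.n_cells


@dataclass
class EpochResult:
    """Outcome of one epoch: per-generation records plus final population."""

    config: EpochConfig
    seed: int | None
    records: list[GenerationRecord]
    snapshots: dict[int, pd.DataFrame]
    final_agents: list[Agent]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "generation": r.generation,
                "total_biomass": r.total_biomass,
                "fitness_mean": r.fitness_mean,
                "fitness_sd": r.fitness_sd,
            }
            for t in _TRAITS:
                row[f"{t}_mean"] = r.trait_mean[t]
                row[f"{t}_sd"] = r.trait_sd[t]
            rows.append(row)
        return pd.DataFrame(rows)

    def final_frame(self) -> pd.DataFrame:
        """Final generation: one row per agent (id, traits, fitness)."""
        return _population_frame(self.final_agents,
                                 self.records[-1].fitness if self.records else None)

    def total_biomass_trajectory(self) -> np.ndarray:
        return np.array([r.total_biomass for r in self.records])

    def to_json(self) -> dict:
        """JSON-serialisable summary (config echo, seed, per-generation rows)."""
        cfg = self.config
        return {
            "config": {
                "n_agents": cfg.n_agents,
                "mode": cfg.mode.value,
                "n_ticks": cfg.n_ticks,
                "n_generations": cfg.n_generations,
                "grid": [cfg.grid.n_rows, cfg.grid.n_cols, cfg.grid.toroidal],
                "schedule": [cfg.schedule.mu0, cfg.schedule.mu_inf, cfg.schedule.psi],
            },
            "seed": self.seed,
            "generations": self.records_frame().to_dict(orient="records"),
        }


def _population_frame(agents: list[Agent], fitness=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "agent_id": [a.id for a in agents],
            "alpha": [a.phenotype.alpha for a in agents],
            "delta": [a.phenotype.delta for a in agents],
            "rho": [a.phenotype.rho for a in agents],
        }
    )
    df["fitness"] = np.asarray(fitness) if fitness is not None else np.nan
    return df


def _init_population(config: EpochConfig, rng: np.random.Generator) -> list[Agent]:
    n = config.n_agents
    lo, hi = config.init_low, config.init_high
    if config.mode is ReproductionMode.DIPLOID_RANDOM:
        alleles = rng.uniform(lo, hi, size=(n, 3, 2))
        tags = np.arange(n * 6, dtype=np.int64).reshape(n, 3, 2)
        out = []
        for i in range(n):
            geno = Genotype(Ploidy.DIPLOID, alleles=alleles[i], tags=tags[i])
            out.append(Agent(id=i, location=-1, biomass=0.0,
                             phenotype=geno.phenotype(), genotype=geno))
        return out
    traits = rng.uniform(lo, hi, size=(n, 3))
    return [_haploid_agent(i, traits[i]) for i in range(n)]


def run_epoch(config: EpochConfig, seed: int | np.random.Generator | None = None) -> EpochResult:
    """Run one full evolutionary epoch.

    Per generation, in RNG draw order: agent placement, landscape
    resource initialisation (first generation only, unless a fresh
    landscape is requested every generation), per-tick decision
    tie-break keys, then the reproduction draws.  A fixed integer seed
    therefore reproduces the whole trajectory bit-exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_echo = seed if isinstance(seed, (int, np.integer)) else None

    agents = _init_population(config, rng)
    records: list[GenerationRecord] = []
    snapshots: dict[int, pd.DataFrame] = {}
    snapset = set(config.snapshot_generations)

    landscape = None
    for T in range(1, config.n_generations + 1):
        loc = rng.integers(0, config.grid.n_cells, size=config.n_agents)
        for a, l in zip(agents, loc):
            a.location = int(l)
            a.biomass = config.initial_biomass
        if landscape is None or config.fresh_landscape_each_generation:
            landscape = init_resources(config.grid, config.resources, rng)
        landscape.J = np.bincount(loc, minlength=config.grid.n_cells)

        rec = run_generation(
            agents, landscape, config.foraging, config.resources,
            config.n_ticks, rng, generation=T, self_excluded=config.self_excluded,
        )
        records.append(rec)
        if T in snapset:
            snapshots[T] = _population_frame(agents, rec.fitness)

        if T < config.n_generations:
            parents = select_fittest(agents)
            agents = _REPRODUCERS[config.mode](parents, T, config.schedule, rng)

    return EpochResult(config=config, seed=seed_echo, records=records,
                       snapshots=snapshots, final_agents=agents)
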