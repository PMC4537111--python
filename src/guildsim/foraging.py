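"""Intragenerational clock: synchronous movement, extraction, growth.

One generation is ``n`` ticks.  Every tick proceeds in a fixed order:

1. all agents sense the pre-movement landscape and decide stay/move
   synchronously (perception is of the time-t state);
2. relocating agents change cell (an argmax at slot 0 keeps the cell but
   still counts as a move);
3. stayers in each cell form the extractor set of size N_k; each gains
   biomass kappa * F_k where the per-capita extraction is

       F_k = min{ R_k / N_k,  u R_k / (h + R_k + q N_k) }

   (stock sharing capped by a Beddington-DeAngelis-style saturating
   functional response with intraspecific interference q);
4. every mover, including movers-in-place, extracts nothing this tick
   (the forfeited extraction is the cost of moving); with
   ``deduct_move_cost`` set, movers are additionally charged the
   multiplicative deduction B <- (1 - c) B;
5. each cell regrows from its post-extraction stock;
6. occupancy counts are recomputed from the new locations.

RNG draw-order contract (per tick, from one shared generator): a single
uniform block of shape (n_agents, 9) of tie-break keys is drawn before
decisions.  This fixed order is what makes whole runs bit-reproducible
from a seed and lets an independent per-agent reference implementation
replay the same trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import (
    GridSpec,
    Landscape,
    ResourceParams,
    _neighbor_table,
    neighborhood_means,
    regrow,
)
from .movement import MovementParams

__all__ = [
    "ForagingParams",
    "Agent",
    "TickStats",
    "GenerationRecord",
    "extraction_rate",
    "step_tick",
    "run_generation",
]


@dataclass(frozen=True)
class ForagingParams:
    """Consumer-side parameters of the within-patch interaction.

    u : maximum per-capita extraction rate (resource units / tick).
    h : half-saturation efficiency (resource units).
    q : intraspecific competition (interference) coefficient.
    kappa : conversion of extracted resource into biomass.
    c : cost of moving, as a fraction of current biomass per move; only
        charged when ``deduct_move_cost`` is set.
    deduct_move_cost : when True, every mover is charged B <- (1 - c) B.
        Off by default: under the baseline conditions the cost of moving
        is the forfeited extraction (a mover gains nothing that tick),
        and a recurring multiplicative stock deduction caps attainable
        lifetime biomass far below the productivity an evolved guild
        actually sustains (see docs/methods.md).
    """

    u: float = 10.0
    h: float = 20.0
    q: float = 0.5
    kappa: float = 0.1
    c: float = 0.1
    deduct_move_cost: bool = False

    def __post_init__(self) -> None:
        if self.u < 0 or self.h < 0 or self.q < 0:
            raise ValueError("u, h, q must be >= 0")
        if not 0 <= self.kappa <= 1:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not 0 <= self.c < 1:
            raise ValueError(f"c must be in [0, 1), got {self.c}")


@dataclass
class Agent:
    """A forager: identity, current cell, accumulated biomass, phenotype.

    ``genotype`` is None for plain phenotype-carrying (clonal /
    trait-averaging) agents and a :class:`guildsim.evolution.Genotype`
    in diploid runs.
    """

    id: int
    location: int
    biomass: float
    phenotype: MovementParams
    genotype: object | None = None


@dataclass
class TickStats:
    """Per-tick bookkeeping: extractor counts and extraction per cell."""

    N: np.ndarray       # extractors (stayers) per cell
    F: np.ndarray       # per-capita extraction per cell (0 where N = 0)
    R_star: np.ndarray  # post-extraction, pre-regrowth resource
    stayed: np.ndarray  # per-agent: True if the agent stayed and extracted


@dataclass
class GenerationRecord:
    """Summary of one generation: fitness and phenotype statistics."""

    generation: int
    fitness: np.ndarray          # final biomass B_a(n), the fitness measure
    total_biomass: float
    fitness_mean: float
    fitness_sd: float
    trait_mean: dict = field(default_factory=dict)  # alpha/delta/rho -> mean
    trait_sd: dict = field(default_factory=dict)


def extraction_rate(R: float, N: int, params: ForagingParams) -> float:
    """Per-capita extraction F for N agents sharing a stock R.

    F = min{R/N, uR/(h + R + qN)}; the stock-sharing cap guarantees
    N * F <= R, so extraction can never drive a patch negative.
    """
    if N < 1:
        raise ValueError("extraction_rate requires at least one extractor")
    if R < 0:
        raise ValueError("negative resource stock")
    return min(R / N, params.u * R / (params.h + R + params.q * N))


def _tick_arrays(
    loc: np.ndarray,
    B: np.ndarray,
    alpha: np.ndarray,
    delta: np.ndarray,
    rho: np.ndarray,
    R: np.ndarray,
    J: np.ndarray,
    grid: GridSpec,
    fp: ForagingParams,
    rp: ResourceParams,
    rng: np.random.Generator,
    self_excluded: bool = True,
):
    """Advance one tick on the array representation (in-place loc/B).

    Returns (R_next, J_next, stats).  This is the production path; the
    per-agent semantics it must match are those of
    :func:`guildsim.movement.decide_move` applied synchronously.
    """
    n = loc.shape[0]
    table, _ = _neighbor_table(grid)

    R_M = neighborhood_means(R, grid)
    J_M = neighborhood_means(J, grid)

    cells9 = np.concatenate([loc[:, None], table[loc]], axis=1)  # (n, 9)
    valid = cells9 >= 0
    safe = np.where(valid, cells9, 0)

    R9 = R[safe]
    J9 = J[safe].astype(float)
    RM9 = R_M[safe]
    JM9 = J_M[safe]
    if self_excluded:
        J9[:, 0] -= 1.0

    d = delta[:, None]
    V = R9 - d * J9 + alpha[:, None] * (RM9 - d * JM9)
    V[~valid] = np.nan  # bounded-grid edge slots take no part in the rule

    keys = rng.random((n, 9))  # tie-break keys: the tick's only draw
    keys[~valid] = -1.0

    v0 = V[:, 0]
    # stay iff V_0 > 0 and rho * V_l < V_0 for every neighbour slot
    with np.errstate(invalid="ignore"):
        worst = np.nanmax(rho[:, None] * V[:, 1:], axis=1)
    stay = (v0 > 0) & (worst < v0)

    vmax = np.nanmax(V, axis=1)
    with np.errstate(invalid="ignore"):
        candidates = np.where(V == vmax[:, None], keys, -1.0)
    target = np.argmax(candidates, axis=1)

    move = ~stay
    loc[move] = cells9[move, target[move]]

    Nk = np.bincount(loc[stay], minlength=grid.n_cells)
    Fk = np.zeros(grid.n_cells)
    occ = Nk > 0
    if occ.any():
        Ro, No = R[occ], Nk[occ]
        Fk[occ] = np.minimum(Ro / No, fp.u * Ro / (fp.h + Ro + fp.q * No))

    B[stay] += fp.kappa * Fk[loc[stay]]
    if fp.deduct_move_cost:
        B[move] *= 1.0 - fp.c

    R_star = R - Nk * Fk
    # clip pure float round-off; genuine negatives still raise in regrow
    R_star[(R_star < 0.0) & (R_star > -1e-12)] = 0.0
    R_next = regrow(R_star, rp)
    J_next = np.bincount(loc, minlength=grid.n_cells)

    return R_next, J_next, TickStats(N=Nk, F=Fk, R_star=R_star, stayed=stay)


def step_tick(
    agents: list[Agent],
    landscape: Landscape,
    foraging: ForagingParams,
    resources: ResourceParams,
    rng: np.random.Generator,
    self_excluded: bool = True,
) -> TickStats:
    """Advance the world by one tick, mutating agents and landscape."""
    loc = np.array([a.location for a in agents], dtype=np.int64)
    B = np.array([a.biomass for a in agents], dtype=float)
    alpha = np.array([a.phenotype.alpha for a in agents])
    delta = np.array([a.phenotype.delta for a in agents])
    rho = np.array([a.phenotype.rho for a in agents])

    R_next, J_next, stats = _tick_arrays(
        loc, B, alpha, delta, rho, landscape.R, landscape.J,
        landscape.grid, foraging, resources, rng, self_excluded,
    )
    landscape.R = R_next
    landscape.J = J_next
    for a, l, b in zip(agents, loc, B):
        a.location = int(l)
        a.biomass = float(b)
    return stats


def run_generation(
    agents: list[Agent],
    landscape: Landscape,
    foraging: ForagingParams,
    resources: ResourceParams,
    n_ticks: int,
    rng: np.random.Generator,
    generation: int = 0,
    self_excluded: bool = True,
) -> GenerationRecord:
    """Run one generation's n ticks and return its summary record.

    Agents must already be placed with their initial biomass, and the
    landscape freshly initialised.  The final biomass B_a(n) is the
    fitness measure.  ``n_ticks = 0`` is allowed and leaves the initial
    biomass as the fitness.
    """
    if n_ticks < 0:
        raise ValueError(f"n_ticks must be >= 0, got {n_ticks}")

    loc = np.array([a.location for a in agents], dtype=np.int64)
    B = np.array([a.biomass for a in agents], dtype=float)
    alpha = np.array([a.phenotype.alpha for a in agents])
    delta = np.array([a.phenotype.delta for a in agents])
    rho = np.array([a.phenotype.rho for a in agents])
    R, J = landscape.R, landscape.J

    for _ in range(n_ticks):
        R, J, _ = _tick_arrays(
            loc, B, alpha, delta, rho, R, J,
            landscape.grid, foraging, resources, rng, self_excluded,
        )

    landscape.R, landscape.J = R, J
    for a, l, b in zip(agents, loc, B):
        a.location = int(l)
        a.biomass = float(b)

    return GenerationRecord(
        generation=generation,
        fitness=B.copy(),
        total_biomass=float(B.sum()),
        fitness_mean=float(B.mean()),
        fitness_sd=float(B.std()),
        trait_mean={"alpha": float(alpha.mean()), "delta": float(delta.mean()),
                    "rho": float(rho.mean())},
        trait_sd={"alpha": float(alpha.std()), "delta": float(delta.std()),
                  "rho": float(rho.std())},
    )
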