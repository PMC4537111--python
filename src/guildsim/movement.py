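"""Patch-selection rule: environmental perception and the stay/move decision.

Each forager carries three heritable movement parameters:

alpha -- neighbor-discount: weight on second-tier information (the
    neighbourhood means of a candidate cell) relative to the cell's own
    resource and competitor counts.
delta -- competition-tradeoff: per-competitor penalty converting
    occupancy counts into resource-equivalent units.
rho -- movement threshold: the agent stays on its patch only while
    every neighbouring cell's value stays below ``1/rho`` times the
    (positive) value of its current cell.  Small rho means the agent
    resists moving; rho near 1 means it moves whenever any neighbour
    looks even marginally better.

At each tick an agent senses a 36-entry environmental vector: for slot 0
(its own cell) and slots 1..8 (the Moore neighbours in fixed row-major
offset order) it records the resource R_l, the neighbourhood-mean
resource R_l^M, the occupancy J_l and the neighbourhood-mean occupancy
J_l^M.  Each slot is scored

    V_l = R_l - delta * J_l + alpha * (R_l^M - delta * J_l^M)

and the decision rule is: stay iff V_0 > 0 and rho * V_l < V_0 for all
l = 1..8; otherwise relocate to the argmax slot over 0..8 (ties broken
uniformly at random).  A relocation whose argmax is slot 0 is a "move
in place": the agent keeps its cell but is charged the movement cost
and extracts nothing that tick.

On a near-homogeneous landscape (all V_l approximately equal) an agent
with rho < 1 stays and extracts, and leaves once its own patch has been
depleted to the point that the best neighbour exceeds V_0 / rho; this
is what lets evolved populations forage at all on the baseline
landscape, whose initial resource spread is only 0.01.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape, moore_neighbors, neighborhood_mean

__all__ = [
    "MovementParams",
    "EnvironmentVector",
    "DecisionKind",
    "MoveDecision",
    "sense_environment",
    "cell_value",
    "decide_move",
]


@dataclass(frozen=True)
class MovementParams:
    """Heritable movement phenotype (alpha, delta, rho).

    Values are unconstrained reals: mutation applies no clamping, and
    evolved populations do exhibit (slightly) negative parameter values.
    """

    alpha: float
    delta: float
    rho: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.delta, self.rho], dtype=float)


@dataclass(frozen=True)
class EnvironmentVector:
    """What one agent perceives from its cell at one tick.

    Arrays have length 9: slot 0 is the agent's own cell, slots 1..8 the
    Moore neighbours in deterministic order.  ``J[0]`` excludes the
    focal agent itself when sensed with ``self_excluded=True`` (the
    competition penalty is about *other* foragers); the neighbourhood
    means are raw occupancy averages.
    """

    R: np.ndarray
    R_M: np.ndarray
    J: np.ndarray
    J_M: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.R, self.R_M, self.J, self.J_M):
            if len(arr) != 9:
                raise ValueError("environment vector needs 9 slots per field")


class DecisionKind(enum.Enum):
    STAY = "stay"
    RELOCATE = "relocate"


@dataclass(frozen=True)
class MoveDecision:
    """Outcome of the movement rule for one agent at one tick."""

    kind: DecisionKind
    target: int | None = None  # slot 0..8; only for RELOCATE (0 = in place)

    def __post_init__(self) -> None:
        if self.kind is DecisionKind.STAY and self.target is not None:
            raise ValueError("STAY carries no target")
        if self.kind is DecisionKind.RELOCATE:
            if self.target is None or not 0 <= self.target <= 8:
                raise ValueError(f"RELOCATE target must be a slot 0..8, got {self.target}")


def sense_environment(
    agent_location: int, landscape: Landscape, self_excluded: bool = True
) -> EnvironmentVector:
    """Build the 36-entry environmental vector for an agent.

    Perception is synchronous: occupancy counts are the pre-movement
    counts of the current tick.  With ``self_excluded`` the focal
    agent's own presence is removed from J_0.

    Bounded grids have fewer than 8 neighbours at edges; missing slots
    are filled with NaN and are ignored by :func:`decide_move`.
    """
    grid = landscape.grid
    nbrs = moore_neighbors(agent_location, landscape.grid)
    cells = [agent_location] + nbrs + [-1] * (8 - len(nbrs))

    R = np.full(9, np.nan)
    R_M = np.full(9, np.nan)
    J = np.full(9, np.nan)
    J_M = np.full(9, np.nan)
    for slot, k in enumerate(cells):
        if k < 0:
            continue
        R[slot] = landscape.R[k]
        R_M[slot] = neighborhood_mean(landscape.R, k, grid)
        J[slot] = landscape.J[k]
        J_M[slot] = neighborhood_mean(landscape.J, k, grid)
    if self_excluded:
        J[0] -= 1
    return EnvironmentVector(R=R, R_M=R_M, J=J, J_M=J_M)


def cell_value(R, J, R_M, J_M, params: MovementParams):
    """Score a candidate cell: V = R - delta*J + alpha*(R_M - delta*J_M).

    Linear in each input; may be negative.  Works on scalars or arrays.
    """
    return R - params.delta * J + params.alpha * (R_M - params.delta * J_M)


def decide_move(
    env: EnvironmentVector, params: MovementParams, rng: np.random.Generator
) -> MoveDecision:
    """Apply the three-parameter movement rule to one sensed environment.

    Stay iff V_0 > 0 and rho * V_l < V_0 for every neighbour slot
    (strict inequality: equality triggers a move, so in an exactly
    uniform positive world rho = 1 produces a move-in-place).
    Otherwise relocate to the argmax slot over 0..8, ties broken
    uniformly at random from ``rng``.
    """
    V = cell_value(env.R, env.J, env.R_M, env.J_M, params)
    valid = ~np.isnan(V)
    neighbor_vals = V[1:][valid[1:]]
    v0 = V[0]
    if v0 > 0 and (neighbor_vals.size == 0 or np.all(params.rho * neighbor_vals < v0)):
        return MoveDecision(DecisionKind.STAY)
    vmax = np.nanmax(V)
    ties = np.flatnonzero(valid & (V == vmax))
    target = int(ties[0]) if len(ties) == 1 else int(rng.choice(ties))
    return MoveDecision(DecisionKind.RELOCATE, target=target)
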