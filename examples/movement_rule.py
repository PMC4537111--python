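"""The three-parameter movement rule on a toy landscape.

Builds a 3x3 toroidal world with one rich cell, senses it from the
centre, scores the nine candidate cells and prints the decision for a
reluctant (small rho) and an eager (large rho) forager.
"""

import numpy as np

from guildsim import (
    GridSpec, Landscape, MovementParams, cell_value, decide_move,
    sense_environment,
)

grid = GridSpec(3, 3)
R = np.full(9, 5.0)
R[2] = 12.0  # one rich patch
world = Landscape(grid, R, np.zeros(9, dtype=np.int64))
world.J[4] = 1  # the focal agent stands at the centre

env = sense_environment(4, world)
rng = np.random.default_rng(0)

for rho in (0.3, 0.9):
    p = MovementParams(alpha=0.5, delta=0.5, rho=rho)
    V = cell_value(env.R, env.J, env.R_M, env.J_M, p)
    decision = decide_move(env, p, rng)
    print(f"rho = {rho}: V_0 = {V[0]:.2f}, best neighbour V = {V[1:].max():.2f}"
          f" -> {decision.kind.value}"
          + (f" to slot {decision.target}" if decision.target is not None else ""))

print()
print("A small rho stays put until a neighbour is worth V_0/rho; a large",
      "rho leaves for any marginally better patch.", sep="\n")
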