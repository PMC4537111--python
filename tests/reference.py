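"""Independent brute-force reference implementation of one engine tick.

Pure-Python, per-agent, with its own Moore-neighbourhood enumeration and
no imports from the production engine internals.  It shares only the
engine's documented RNG draw-order contract: one uniform block of shape
(n_agents, 9) of tie-break keys drawn at the start of each tick.
"""

from __future__ import annotations

import numpy as np

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def ref_neighbors(k, n_rows, n_cols, toroidal):
    r, c = divmod(k, n_cols)
    out = []
    for dr, dc in OFFSETS:
        rr, cc = r + dr, c + dc
        if toroidal:
            out.append((rr % n_rows) * n_cols + (cc % n_cols))
        elif 0 <= rr < n_rows and 0 <= cc < n_cols:
            out.append(rr * n_cols + cc)
    return out


def ref_nbr_mean(values, k, n_rows, n_cols, toroidal):
    # out-of-bounds offsets contribute 0 to the sum and are excluded
    # from the divisor (slot-ordered, to keep float summation exact
    # against vectorised evaluation)
    r, c = divmod(k, n_cols)
    terms = []
    count = 0
    for dr, dc in OFFSETS:
        rr, cc = r + dr, c + dc
        if toroidal:
            terms.append(values[(rr % n_rows) * n_cols + (cc % n_cols)])
            count += 1
        elif 0 <= rr < n_rows and 0 <= cc < n_cols:
            terms.append(values[rr * n_cols + cc])
            count += 1
        else:
            terms.append(0.0)
    return float(np.sum(terms)) / count


def ref_tick(loc, B, alpha, delta, rho, R, J, n_rows, n_cols, toroidal,
             u, h, q, kappa, c, deduct_move_cost, r, s, g, rng,
             self_excluded=True):
    """One synchronous tick; returns (loc, B, R, J) as new lists."""
    n_cells = n_rows * n_cols
    n = len(loc)
    keys = rng.random((n, 9))

    RM = [ref_nbr_mean(R, k, n_rows, n_cols, toroidal) for k in range(n_cells)]
    JM = [ref_nbr_mean(J, k, n_rows, n_cols, toroidal) for k in range(n_cells)]

    new_loc = list(loc)
    stayed = [False] * n
    for a in range(n):
        k0 = loc[a]
        cells = [k0] + ref_neighbors(k0, n_rows, n_cols, toroidal)
        V = []
        for slot, k in enumerate(cells):
            Jk = J[k] - 1 if (slot == 0 and self_excluded) else J[k]
            V.append(R[k] - delta[a] * Jk + alpha[a] * (RM[k] - delta[a] * JM[k]))
        stay = V[0] > 0 and all(rho[a] * v < V[0] for v in V[1:])
        if stay:
            stayed[a] = True
            continue
        vmax = max(V)
        tied = [i for i, v in enumerate(V) if v == vmax]
        best = max(tied, key=lambda i: keys[a, i])
        new_loc[a] = cells[best]  # slot 0 = move in place

    Nk = [0] * n_cells
    for a in range(n):
        if stayed[a]:
            Nk[new_loc[a]] += 1
    Fk = [0.0] * n_cells
    for k in range(n_cells):
        if Nk[k] > 0:
            Fk[k] = min(R[k] / Nk[k], u * R[k] / (h + R[k] + q * Nk[k]))

    new_B = list(B)
    for a in range(n):
        if stayed[a]:
            new_B[a] = B[a] + kappa * Fk[new_loc[a]]
        elif deduct_move_cost:
            new_B[a] = (1.0 - c) * B[a]

    new_R = []
    for k in range(n_cells):
        r_star = R[k] - Nk[k] * Fk[k]
        if abs(r_star) < 1e-12:
            r_star = max(r_star, 0.0)
        new_R.append(r_star + r * (1.0 - r_star / s) * (r_star + g))
    new_J = [0] * n_cells
    for a in range(n):
        new_J[new_loc[a]] += 1
    return new_loc, new_B, new_R, new_J
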