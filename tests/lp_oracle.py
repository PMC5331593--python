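"""Brute-force oracle for small diet LPs, independent of the HiGHS solver.

The optimization problem in food space minimizes the convex piecewise-linear
departure

    F(q) = sum_rep (w+ max(q-o, 0) + w- max(o-q, 0)) / o
         + pi * sum_nonrep q / m

over the polytope {A q <= b, E q = f, lo <= q <= ub}.  The minimum of a
convex piecewise-linear function over a bounded polytope is attained at an
intersection of n active hyperplanes drawn from the polytope's faces plus
the objective's kink planes q_i = o_i.  This oracle enumerates all such
intersections, keeps the feasible ones and returns the minimal objective —
no simplex, no duality, just linear algebra.
"""

from itertools import combinations

import numpy as np

FEAS_TOL = 1e-7


def departure_objective(q, o, rep, m, w_plus, w_minus, pi):
    dev = q - o
    obj = 0.0
    obj += np.sum(
        np.where(dev[rep] > 0, w_plus * dev[rep], -w_minus * dev[rep]) / o[rep]
    )
    obj += pi * np.sum(q[~rep] / m[~rep])
    return float(obj)


def solve_by_enumeration(model):
    """Return (status, objective) by exhaustive vertex/kink enumeration of an
    LPModel's food-space polytope."""
    n = model.n_foods
    o = model.observed.to_numpy()
    rep = model.repertoire
    params = model.params
    # non-repertoire scale m_f is recoverable from the objective coefficients
    c_q = model.c[:n]
    m = np.where(~rep & (c_q > 0), params.nonrepertoire_penalty / np.where(c_q > 0, c_q, 1.0), 1.0)

    A = model.A_ub[:, :n] if len(model.b_ub) else np.zeros((0, n))
    b = model.b_ub
    eq_mask = [i for i, cid in enumerate(model.eq_ids) if not cid.startswith("link:")]
    E = model.A_eq[eq_mask][:, :n]
    f = model.b_eq[eq_mask]

    lo = np.array([bd[0] for bd in model.bounds[:n]])
    ub = np.array(
        [bd[1] if bd[1] is not None else np.inf for bd in model.bounds[:n]]
    )

    # candidate hyperplanes: inequality rows, both bounds, kink planes
    planes = []
    for i in range(len(b)):
        planes.append((A[i], b[i]))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        planes.append((e.copy(), lo[i]))
        if np.isfinite(ub[i]):
            planes.append((e.copy(), ub[i]))
        if rep[i]:
            planes.append((e.copy(), o[i]))  # kink of the deviation objective

    n_eq = E.shape[0]
    k = n - n_eq
    best = None
    for combo in combinations(range(len(planes)), k):
        M = np.vstack([E] + [planes[i][0][None, :] for i in combo])
        rhs = np.concatenate([f, [planes[i][1] for i in combo]])
        try:
            q = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            continue
        if np.any(q < lo - FEAS_TOL) or np.any(q > ub + FEAS_TOL):
            continue
        if len(b) and np.any(A @ q > b + FEAS_TOL * np.maximum(1.0, np.abs(b))):
            continue
        if np.any(np.abs(E @ q - f) > FEAS_TOL * np.maximum(1.0, np.abs(f))):
            continue
        val = departure_objective(
            q, o, rep, m,
            params.repertoire_increase_weight,
            params.repertoire_decrease_weight,
            params.nonrepertoire_penalty,
        )
        if best is None or val < best:
            best = val
    if best is None:
        return "infeasible", None
    return "optimal", best
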