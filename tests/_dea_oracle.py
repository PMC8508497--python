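"""Brute-force oracle for the output-oriented BCC program.

Enumerates all basic solutions of the LP in the joint variables
(phi, lambda): the convexity equality is always active, and every choice
of n further active constraints among the m input rows, s output rows and
n sign constraints yields a candidate vertex.  The LP optimum is the best
feasible candidate.  Independent of any LP solver.
"""

import itertools

import numpy as np


def brute_force_phi(X: np.ndarray, Y: np.ndarray, unit: int, feas_tol: float = 1e-7) -> float:
    n, m = X.shape
    s = Y.shape[1]
    A_in = np.hstack([np.zeros((m, 1)), X.T])
    A_out = np.hstack([Y[unit][:, None], -Y.T])
    A_sign = np.hstack([np.zeros((n, 1)), -np.eye(n)])
    A_ub = np.vstack([A_in, A_out, A_sign])
    b_ub = np.concatenate([X[unit], np.zeros(s), np.zeros(n)])
    eq = np.concatenate([[0.0], np.ones(n)])

    best = -np.inf
    scale = max(1.0, np.abs(b_ub).max())
    for rows in itertools.combinations(range(len(A_ub)), n):
        M = np.vstack([eq[None, :], A_ub[list(rows)]])
        b = np.concatenate([[1.0], b_ub[list(rows)]])
        try:
            z = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(z)):
            continue
        if np.all(A_ub @ z <= b_ub + feas_tol * scale):
            best = max(best, z[0])
    return best
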