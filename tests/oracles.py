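"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def slsqp_joint_lasso(problem):
    """Generic convex-solver reference for the joint neighborhood objective.

    Split-variable formulation: beta = b+ - b- and one pair of nonnegative
    slack vectors per fusion pair, solved with SLSQP.  Completely independent
    of the package's ADMM path.
    """
    states = problem.states
    T, q = len(states), problem.q
    pairs = problem.fusion_pairs
    m = len(pairs)
    idx = {s: t for t, s in enumerate(states)}
    nvar = 2 * T * q + 2 * m * q

    def unpack(x):
        bp = x[: T * q].reshape(T, q)
        bm = x[T * q: 2 * T * q].reshape(T, q)
        return bp - bm

    def f(x):
        B = unpack(x)
        val = 0.0
        for t, s in enumerate(states):
            r = problem.y[s] - problem.X[s] @ B[t]
            val += 0.5 * float(r @ r)
        val += problem.lambda1 * float(x[: 2 * T * q].sum())
        val += problem.lambda2 * float(x[2 * T * q:].sum())
        return val

    cons = []
    if m:
        A = np.zeros((m * q, nvar))
        for r, (a, b) in enumerate(pairs):
            ta, tb = idx[a], idx[b]
            for c in range(q):
                row = r * q + c
                A[row, ta * q + c] = 1.0
                A[row, T * q + ta * q + c] = -1.0
                A[row, tb * q + c] = -1.0
                A[row, T * q + tb * q + c] = 1.0
                A[row, 2 * T * q + r * q + c] = -1.0
                A[row, 2 * T * q + m * q + r * q + c] = 1.0
        cons = [{"type": "eq", "fun": lambda x: A @ x, "jac": lambda x: A}]

    res = minimize(
        f,
        np.zeros(nvar),
        method="SLSQP",
        bounds=[(0, None)] * nvar,
        constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    B = unpack(res.x)
    return {s: B[t] for t, s in enumerate(states)}


def valid_parent_map(nodes, parent):
    """Brute-force tree check: one root, and every walk up ends at the root."""
    roots = [n for n in nodes if parent[n] is None]
    if len(roots) != 1:
        return False
    for n in nodes:
        seen = set()
        cur = n
        while cur is not None:
            if cur in seen:
                return False
            seen.add(cur)
            cur = parent[cur]
    return True
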