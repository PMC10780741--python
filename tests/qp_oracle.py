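"""Independent brute-force oracle for the epsilon-SVR dual.

Solves the box-and-equality-constrained QP in the raw (alpha, alpha*)
coordinates with SLSQP, sharing no code with the package's own solver.
"""

import numpy as np
from scipy.optimize import minimize


def dual_objective(k, y, beta, eps):
    """The epsilon-SVR dual value at beta (independent arithmetic)."""
    return float(-0.5 * beta @ k @ beta - eps * np.abs(beta).sum() + y @ beta)


def solve_dual_slsqp(k, y, c, eps):
    """Brute-force dense QP solution; returns beta = alpha* - alpha."""
    n = len(y)

    def neg_obj(z):
        beta = z[n:] - z[:n]
        return -dual_objective(k, y, beta, eps)

    def neg_grad(z):
        beta = z[n:] - z[:n]
        kb = k @ beta
        # of -W: d/d alpha = -kb + y + eps ; d/d alpha* = kb - y + eps
        return np.concatenate([-kb + y + eps, kb - y + eps])

    cons = {
        "type": "eq",
        "fun": lambda z: z[n:].sum() - z[:n].sum(),
        "jac": lambda z: np.concatenate([-np.ones(n), np.ones(n)]),
    }
    res = minimize(
        neg_obj,
        np.zeros(2 * n),
        jac=neg_grad,
        bounds=[(0.0, c)] * (2 * n),
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 10000, "ftol": 1e-10},
    )
    # status 8 is a line-search stall, which for a convex QP occurs at the
    # optimum once no ascent direction remains
    assert res.success or res.status == 8, res.message
    return res.x[n:] - res.x[:n]
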