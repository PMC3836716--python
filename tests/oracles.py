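"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms from the package code paths:
ADMM with exact proximal maps for the sparse group lasso objective,
bisection for group entry values, and brute-force set/interval logic.
"""

import numpy as np
from scipy.optimize import brentq


def admm_sgl(Xe, y, slices, weights, lam, alpha, rho=1.0, iters=5000):
    """ADMM solve of 1/2||y-Xe b||^2 + lam(1-a) sum w||b_l|| + lam a ||b||_1."""
    P = Xe.shape[1]
    XtX = Xe.T @ Xe
    Xty = Xe.T @ y
    M = np.linalg.inv(XtX + rho * np.eye(P))
    z = np.zeros(P)
    u = np.zeros(P)
    for _ in range(iters):
        b = M @ (Xty + rho * (z - u))
        v = b + u
        t1 = lam * alpha / rho
        zz = np.sign(v) * np.maximum(np.abs(v) - t1, 0.0)
        for l, sl in enumerate(slices):
            nrm = np.linalg.norm(zz[sl])
            t2 = lam * (1 - alpha) * weights[l] / rho
            zz[sl] = np.zeros_like(zz[sl]) if nrm <= t2 else (1 - t2 / nrm) * zz[sl]
        u = u + b - zz
        z = zz
    return z


def sgl_objective_expanded(Xe, y, slices, weights, lam, alpha, b):
    pen = 0.0
    for l, sl in enumerate(slices):
        pen += lam * (1 - alpha) * weights[l] * np.linalg.norm(b[sl])
        pen += lam * alpha * np.sum(np.abs(b[sl]))
    return 0.5 * np.sum((y - Xe @ b) ** 2) + pen


def entry_lambda_bisect(Xl, v, alpha, w):
    """Bisection oracle for the group entry value."""
    a = np.abs(Xl.T @ v)
    amax = a.max()
    if amax == 0:
        return 0.0
    if alpha == 1.0:
        return float(amax)

    def f(lam):
        return np.sum(np.maximum(a - alpha * lam, 0.0) ** 2) - (
            (1 - alpha) * w * lam
        ) ** 2

    hi = amax / alpha if alpha > 0 else np.linalg.norm(a) / ((1 - alpha) * w) * 2
    return float(brentq(f, 0.0, hi, xtol=1e-12))


def expanded_design(problem):
    return np.concatenate(
        [problem.X[:, g] for g in problem.pathways.groups], axis=1
    )


def canberra_capped(tau1, tau2, k):
    """Direct evaluation of the capped-rank Canberra sum."""
    total = 0.0
    for a, b in zip(tau1, tau2):
        ca, cb = min(a, k + 1), min(b, k + 1)
        total += abs(ca - cb) / (ca + cb)
    return total
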