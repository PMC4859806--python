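"""A compact covariance matrix adaptation evolution strategy (CMA-ES).

Implements the standard (mu/mu_w, lambda) strategy with rank-one and
rank-mu covariance updates and cumulative step-size adaptation, following
the widely used reference parameterisation.  It is a general-purpose,
derivative-free minimizer over R^n; bound handling and parameter
transformations live in the calling code.
"""

from __future__ import annotations

import numpy as np

__all__ = ["minimize_cmaes"]


def minimize_cmaes(func, x0, sigma0: float, max_evals: int,
                   rng: np.random.Generator, popsize: int | None = None,
                   ftol: float = 1e-12):
    """Minimize ``func`` over R^n.

    Returns (xbest, fbest, n_evals).  Deterministic given ``rng``'s state.
    Non-finite objective values are replaced by a large penalty so that the
    search continues.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    B = np.eye(n)
    D = np.ones(n)

    xbest = x0.copy()
    fbest = _safe(func(x0))
    evals = 1
    it = 0
    while evals + lam <= max_evals:
        it += 1
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T  # y_i ~ N(0, C)
        xs = mean + sigma * y
        fs = np.array([_safe(func(x)) for x in xs])
        evals += lam
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < fbest:
            fbest = float(fs[order[0]])
            xbest = xs[order[0]].copy()
        ysel = y[order[:mu]]
        ymean = w @ ysel
        mean = mean + sigma * ymean

        # step-size path (uses C^(-1/2) y = B D^-1 B^T y)
        cinv_y = B @ ((B.T @ ymean) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * cinv_y
        hsig = (np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * it)) / chi_n
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * ymean

        rank1 = np.outer(pc, pc)
        rankmu = (ysel * w[:, None]).T @ ysel
        C = ((1 - c1 - cmu) * C
             + c1 * (rank1 + (1 - hsig) * cc * (2 - cc) * C)
             + cmu * rankmu)
        sigma *= float(np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1)))
        sigma = min(sigma, 1e6)

        C = (C + C.T) / 2
        eigvals, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(eigvals, 1e-20))

        if fs[order[mu - 1]] - fs[order[0]] < ftol and sigma < 1e-8:
            break
    return xbest, fbest, evals


def _safe(v: float) -> float:
    v = float(v)
    return v if np.isfinite(v) else 1e10
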