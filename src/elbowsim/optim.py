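"""Derivative-free optimizers used for controller calibration.

``bayes_minimize`` is a small Bayesian-optimization loop: a Gaussian-process
surrogate (Matern 5/2 plus white noise, via scikit-learn) fitted to the
evaluated points, with the expected-improvement acquisition maximized over
a seeded random candidate pool.  ``pattern_search`` is a classical compass
(coordinate pattern) search with step halving.  Both are deterministic for
a fixed seed and budget.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["bayes_minimize", "pattern_search"]


def _expected_improvement(mu, sigma, best):
    from scipy.stats import norm
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_minimize(f, bounds, n_init: int = 10, n_total: int = 40,
                   seed: int = 0, n_candidates: int = 512):
    """Minimize a black-box scalar function over a box.

    Returns ``(x_best, f_best, (X, y))`` with the full evaluation history.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    dim = len(bounds)
    n_init = min(n_init, n_total)

    # space-filling start: stratified (Latin hypercube style) samples
    grid = (np.arange(n_init)[:, None] + rng.random((n_init, dim))) / n_init
    for j in range(dim):
        rng.shuffle(grid[:, j])
    X = lo + grid * (hi - lo)
    y = np.array([f(x) for x in X])

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.full(dim, 0.3), nu=2.5,
                       length_scale_bounds=(1e-3, 1e1))
              + WhiteKernel(1e-6, (1e-10, 1e-1)))

    while len(y) < n_total:
        # fit in the unit box with standardized objective
        Xn = (X - lo) / (hi - lo)
        y_mean, y_std = float(np.mean(y)), float(np.std(y))
        yn = (y - y_mean) / (y_std if y_std > 0 else 1.0)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      alpha=1e-10, random_state=0)
        try:
            # small-sample GP fits routinely hit kernel-bound warnings;
            # they are expected and do not affect the acquisition ranking
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Xn, yn)
            cand = rng.random((n_candidates, dim))
            # densify around the incumbent
            jitter = Xn[int(np.argmin(y))] + 0.05 * rng.standard_normal((64, dim))
            cand = np.vstack([cand, np.clip(jitter, 0.0, 1.0)])
            mu, sigma = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sigma, float(np.min(yn)))
            x_new = lo + cand[int(np.argmax(ei))] * (hi - lo)
        except Exception:   # GP degenerate: fall back to random search
            x_new = lo + rng.random(dim) * (hi - lo)
        X = np.vstack([X, x_new])
        y = np.append(y, f(x_new))

    i = int(np.argmin(y))
    return X[i].copy(), float(y[i]), (X, y)


def pattern_search(f, x0, step, bounds, budget: int = 30,
                   shrink: float = 0.5, min_step_frac: float = 1e-3):
    """Compass pattern search with step halving.

    Polls the 2*d coordinate neighbours of the incumbent; moves to the
    first improving neighbour, halves all steps when no poll improves.
    ``budget`` counts objective evaluations (the initial point included).
    Returns ``(x_best, f_best, n_evals)``.
    """
    x = np.array(x0, dtype=float)
    step = np.array(step, dtype=float)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    x = np.clip(x, lo, hi)
    fx = f(x)
    evals = 1
    min_step = min_step_frac * (hi - lo)
    while evals < budget and np.any(step > min_step):
        improved = False
        for j in range(len(x)):
            for sgn in (+1.0, -1.0):
                if evals >= budget:
                    break
                xt = x.copy()
                xt[j] = float(np.clip(xt[j] + sgn * step[j], lo[j], hi[j]))
                if math.isclose(xt[j], x[j]):
                    continue
                ft = f(xt)
                evals += 1
                if ft < fx:
                    x, fx = xt, ft
                    improved = True
                    break
            if improved or evals >= budget:
                break
        if not improved:
            step *= shrink
    return x, float(fx), evals
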