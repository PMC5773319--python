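"""Independent oracles: deliberately naive re-implementations used only
to check the package, never sharing code with it."""

import math

import numpy as np


def sigma(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def naive_nll(theta1, theta2, beta, x_rows, y):
    """Plain-loop negative log-likelihood for the 3-state cumulative logit."""
    total = 0.0
    for xi, yi in zip(x_rows, y):
        eta = sum(b * v for b, v in zip(beta, np.atleast_1d(xi)))
        p0 = sigma(theta1 - eta)
        p1 = sigma(theta2 - eta) - p0
        p2 = 1.0 - sigma(theta2 - eta)
        p = (p0, p1, p2)[int(yi)]
        total -= math.log(max(p, 1e-300))
    return total


def grid_search_mle(x, y, stages=((0.25, None), (0.02, 0.3), (0.001, 0.03))):
    """Dense grid search over (theta1, theta2, beta) for an area-only model.

    Successive refinement: a wide coarse grid, then finer grids centred
    on the previous argmin.  Vectorized but algorithmically independent
    of the package's optimizer.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)

    def nll_grid(t1, t2, b):
        # t1, t2, b are 1-D parameter axes -> full cross product
        T1, T2, B = np.meshgrid(t1, t2, b, indexing="ij")
        valid = T2 > T1
        eta = B[..., None] * x  # (..., n)
        F1 = 1.0 / (1.0 + np.exp(-(T1[..., None] - eta)))
        F2 = 1.0 / (1.0 + np.exp(-(T2[..., None] - eta)))
        P = np.stack([F1, F2 - F1, 1.0 - F2], axis=-1)
        p_obs = np.take_along_axis(
            P, np.broadcast_to(y[:, None], P.shape[:-1] + (1,))[..., :1], axis=-1
        )[..., 0]
        val = -np.log(np.maximum(p_obs, 1e-300)).sum(axis=-1)
        val = np.where(valid, val, np.inf)
        k = np.unravel_index(np.argmin(val), val.shape)
        return (t1[k[0]], t2[k[1]], b[k[2]]), val[k]

    center = None
    for step, halfwidth in stages:
        if center is None:
            t1 = np.arange(-4.0, 4.0 + step, step)
            t2 = np.arange(-4.0, 6.0 + step, step)
            b = np.arange(-6.0, 6.0 + step, step)
        else:
            c1, c2, cb = center
            t1 = np.arange(c1 - halfwidth, c1 + halfwidth + step / 2, step)
            t2 = np.arange(c2 - halfwidth, c2 + halfwidth + step / 2, step)
            b = np.arange(cb - halfwidth, cb + halfwidth + step / 2, step)
        center, best = nll_grid(t1, t2, b)
    return center, best


def dense_grid_crossing(theta1, theta2, beta, transition, lo=-40.0, hi=40.0, step=1e-4):
    """Locate a curve crossing by brute scan at fixed step; None if absent."""
    x = np.arange(lo, hi, step)
    F1 = 1.0 / (1.0 + np.exp(-(theta1 - beta * x)))
    F2 = 1.0 / (1.0 + np.exp(-(theta2 - beta * x)))
    if transition == "zero_to_one":
        diff = F1 - (F2 - F1)
    else:
        diff = (F2 - F1) - (1.0 - F2)
    diff = np.where(np.abs(diff) < 1e-12, 0.0, diff)  # underflow guard
    s = np.sign(diff)
    flips = np.flatnonzero(s[1:] * s[:-1] < 0)
    if flips.size == 0:
        return None
    i = flips[0]
    return 0.5 * (x[i] + x[i + 1])


def type7_quantile(samples, p):
    """R's default (type 7) quantile, computed from first principles."""
    s = sorted(samples)
    n = len(s)
    h = (n - 1) * p
    lo = math.floor(h)
    if lo + 1 >= n:
        return s[-1]
    return s[lo] + (h - lo) * (s[lo + 1] - s[lo])
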