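"""Locally weighted scatterplot smoothing (LOWESS).

Classic Cleveland-style LOWESS: at each evaluation point a weighted linear
regression is fit over the ``ceil(tau * n)`` nearest neighbours with tricube
distance weights, and the whole fit is robustified by iterated bisquare
reweighting of residuals.  The smoothing fraction ``tau`` controls the local
window: small values track the data closely (risking overfitting), values
near 1 approach a single global linear fit.

This implementation evaluates the smooth at arbitrary points inside the data
range, which is what the clock needs to tabulate fitted gene frequencies on
its age grid.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["lowess_fit"]


def _fit_at(x: np.ndarray, y: np.ndarray, targets: np.ndarray, k: int,
            delta: np.ndarray) -> np.ndarray:
    """Weighted local-linear fit of (x, y) at each target point.

    ``delta`` holds the current robustness weights; the per-target tricube
    distance weights are multiplied in.  Degenerate windows (zero weighted
    x-variance) fall back to the weighted mean.
    """
    d = np.abs(x[None, :] - targets[:, None])          # (m, n)
    dmax = np.partition(d, k - 1, axis=1)[:, k - 1]    # k-th nearest distance
    zero_win = dmax == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.clip(d / dmax[:, None], 0.0, 1.0)
    w = (1.0 - u ** 3) ** 3
    if zero_win.any():
        # all k nearest neighbours coincide with the target: weight them only
        w[zero_win] = (d[zero_win] == 0.0).astype(float)
    v = w * delta[None, :]
    # degenerate windows: robustness weights may zero out every in-window
    # point (tricube already vanishes at the window edge); drop them there,
    # and as a last resort weight the nearest points uniformly
    dead = v.sum(axis=1) == 0.0
    if dead.any():
        v[dead] = w[dead]
        dead = v.sum(axis=1) == 0.0
        if dead.any():
            v[dead] = (d[dead] == d[dead].min(axis=1, keepdims=True)
                       ).astype(float)
    sw = v.sum(axis=1)
    mx = (v * x[None, :]).sum(axis=1) / sw
    my = (v * y[None, :]).sum(axis=1) / sw
    xc = x[None, :] - mx[:, None]
    var = (v * xc * xc).sum(axis=1)
    cov = (v * xc * (y[None, :] - my[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0.0, cov / var, 0.0)
    return my + slope * (targets - mx)


def lowess_fit(ages: np.ndarray, values: np.ndarray, tau: float,
               eval_ages: np.ndarray, robust_iters: int = 3) -> np.ndarray:
    """Fit a LOWESS smooth of ``values`` against ``ages`` at ``eval_ages``.

    Parameters
    ----------
    ages, values
        Paired observations, at least three of them.
    tau
        Smoothing fraction in (0, 1]; each local regression uses the
        ``ceil(tau * n)`` nearest points (never fewer than 2).
    eval_ages
        Points at which the smooth is returned; must lie inside
        ``[min(ages), max(ages)]``.
    robust_iters
        Number of bisquare robustifying reweighting passes (default 3).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    t = np.atleast_1d(np.asarray(eval_ages, dtype=float))
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("ages and values must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"LOWESS needs at least 3 points, got {n}")
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if (t < x.min()).any() or (t > x.max()).any():
        raise ValueError("evaluation ages must lie within the data range")

    k = min(n, max(2, math.ceil(tau * n)))
    delta = np.ones(n)
    # residuals at machine precision carry no outlier information; below
    # this cutoff bisquare reweighting would amplify rounding noise
    noise_floor = 1e-10 * np.max(np.abs(y), initial=0.0)
    for _ in range(robust_iters):
        resid = y - _fit_at(x, y, x, k, delta)
        s = np.median(np.abs(resid))
        if s <= noise_floor:
            break
        delta = (1.0 - np.clip(np.abs(resid) / (6.0 * s), 0.0, 1.0) ** 2) ** 2
    return _fit_at(x, y, t, k, delta)
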