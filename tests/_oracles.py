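"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately coded from the definitions — pure-Python loops,
exact factorials, direct products of probabilities — and share no code with
the package internals they check.
"""

import math

import numpy as np


def lowess_oracle(x, y, tau, eval_x, robust_iters=3):
    """Loop-based locally weighted regression with tricube weights and
    bisquare robustification."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    k = min(n, max(2, math.ceil(tau * n)))

    def fit_point(x0, delta):
        d = [abs(xi - x0) for xi in x]
        dmax = sorted(d)[k - 1]
        if dmax == 0.0:
            w = [1.0 if di == 0.0 else 0.0 for di in d]
        else:
            w = [(1.0 - min(di / dmax, 1.0) ** 3) ** 3 for di in d]
        v = [wi * de for wi, de in zip(w, delta)]
        if sum(v) == 0.0:
            v = list(w)
        if sum(v) == 0.0:
            dmin = min(d)
            v = [1.0 if di == dmin else 0.0 for di in d]
        sw = sum(v)
        mx = sum(vi * xi for vi, xi in zip(v, x)) / sw
        my = sum(vi * yi for vi, yi in zip(v, y)) / sw
        var = sum(vi * (xi - mx) ** 2 for vi, xi in zip(v, x))
        cov = sum(vi * (xi - mx) * (yi - my)
                  for vi, xi, yi in zip(v, x, y))
        if var > 0.0:
            return my + (cov / var) * (x0 - mx)
        return my

    delta = [1.0] * n
    noise_floor = 1e-10 * max((abs(yi) for yi in y), default=0.0)
    for _ in range(robust_iters):
        resid = [yi - fit_point(xi, delta) for xi, yi in zip(x, y)]
        s = float(np.median([abs(r) for r in resid]))
        if s <= noise_floor:
            break
        delta = [(1.0 - min(abs(r) / (6.0 * s), 1.0) ** 2) ** 2
                 for r in resid]
    return np.array([fit_point(float(t), delta) for t in np.atleast_1d(eval_x)])


def poisson_log_pmf_oracle(k, lam):
    """log of e^{-lam} lam^k / k! via an exact integer factorial."""
    return math.log(lam ** k / math.factorial(k)) - lam


def profile_oracle(gene_ids, counts, model, lambda_scale="full"):
    """Direct-product likelihood profile for small models and counts."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    used = [(i, pos[g]) for i, g in enumerate(model.gene_ids) if g in pos]
    if lambda_scale == "full":
        total = float(sum(counts))
    else:
        total = float(sum(counts[j] for _, j in used))
    log_lik = []
    for gi in range(len(model.age_grid)):
        prob = 1.0
        for i, j in used:
            lam = model.fitted_freq[i, gi] * total
            k = int(counts[j])
            prob *= math.exp(-lam) * lam ** k / math.factorial(k)
        log_lik.append(math.log(prob))
    return np.array(log_lik)
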