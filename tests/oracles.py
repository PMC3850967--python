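"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately avoids the code path it checks: quadrature
instead of MCMC, hand-rolled ranks instead of library Spearman, textbook
sums of squares instead of the ANOVA routine, explicit Welch algebra,
and integer-arithmetic binomial tails.
"""

import math

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr


def probit_posterior_quadrature(scores, labels, prior_var=100.0,
                                grid=241, span=8.0):
    """Posterior means of (alpha, beta) by 2-D grid quadrature.

    The grid is centered on the Laplace approximation so the mass is
    covered even for diffuse priors.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)

    def neg_log_post(b):
        b = np.asarray(b, dtype=float)
        eta = b[0] + b[1] * scores
        ll = np.sum(np.where(y == 1, log_ndtr(eta), log_ndtr(-eta)))
        return -(ll - 0.5 * (b @ b) / prior_var)

    res = optimize.minimize(neg_log_post, np.zeros(2), method="BFGS")
    sds = np.sqrt(np.diag(res.hess_inv))
    a_grid = np.linspace(res.x[0] - span * sds[0], res.x[0] + span * sds[0], grid)
    b_grid = np.linspace(res.x[1] - span * sds[1], res.x[1] + span * sds[1], grid)
    A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
    eta = A.ravel()[:, None] + B.ravel()[:, None] * scores[None, :]
    ll = np.where(y[None, :] == 1, log_ndtr(eta), log_ndtr(-eta)).sum(axis=1)
    logp = ll - 0.5 * (A.ravel() ** 2 + B.ravel() ** 2) / prior_var
    w = np.exp(logp - logp.max())
    w /= w.sum()
    return float(A.ravel() @ w), float(B.ravel() @ w)


def average_ranks(x):
    """Competition-free average ranks, built from argsort only."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_by_hand(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def anova_f_by_hand(groups):
    """One-way fixed-effects F from textbook sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def welch_by_hand(x1, x2):
    """Welch t statistic and p-value from the explicit formulas."""
    from scipy.stats import t as t_dist
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x1.mean() - x2.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def binomial_lower_tail(k, n, p):
    """P(X <= k) for Binomial(n, p) by direct summation with exact combs."""
    total = 0.0
    for i in range(k + 1):
        total += math.comb(n, i) * (p ** i) * ((1 - p) ** (n - i))
    return total
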