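"""Independent oracles used by the test suite.

Everything here is written from the model definitions directly (scipy
pmfs, explicit likelihood formulas, exhaustive pair counting, grid
search) and never calls the package's fitting code, so a test comparing a
fit against these is a genuine dual-route check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import nbinom


def poisson_loglik(y, x, b0, b1):
    mu = np.exp(b0 + b1 * x)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def logistic_loglik(y, x, b0, b1):
    p = expit(b0 + b1 * x)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def ztnb_logpmf_direct(y, mu, theta):
    """Zero-truncated NB via scipy pmf ratio (naive but fine off the edges)."""
    p = theta / (theta + mu)
    return nbinom.logpmf(y, theta, p) - np.log1p(-nbinom.pmf(0, theta, p))


def ztnb_loglik(y, x, b0, b1, log_theta):
    mu = np.exp(b0 + b1 * x)
    return float(np.sum(ztnb_logpmf_direct(y, mu, np.exp(log_theta))))


def negbin_loglik(y, x, b0, b1, log_alpha):
    theta = 1.0 / np.exp(log_alpha)
    mu = np.exp(b0 + b1 * x)
    p = theta / (theta + mu)
    return float(np.sum(nbinom.logpmf(y, theta, p)))


def grid_maximize(fun, bounds, n=25, refinements=4):
    """Maximize ``fun(params)`` by successive grid refinement.

    Each pass lays an ``n``-point grid per dimension over the current
    bounds, evaluates every combination and shrinks the bounds to one grid
    step around the best point.  Returns (best_value, best_params).
    """
    bounds = [tuple(b) for b in bounds]
    best_val, best_pt = -np.inf, None
    for _ in range(refinements):
        axes = [np.linspace(lo, hi, n) for lo, hi in bounds]
        for pt in itertools.product(*axes):
            v = fun(np.array(pt))
            if v > best_val:
                best_val, best_pt = v, np.array(pt)
        steps = [(hi - lo) / (n - 1) for lo, hi in bounds]
        bounds = [
            (p - s, p + s) for p, s in zip(best_pt, steps)
        ]
    return best_val, best_pt


def auc_pair_counting(scores, labels):
    """AUC by exhaustive Mann-Whitney pair counting; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def kruskal_statistic_by_hand(scores, groups):
    """Tie-corrected two-group Kruskal-Wallis statistic from its definition."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n)
    sorted_scores = scores[order]
    i = 0
    pos = 1.0
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    h = 0.0
    for g in (0, 1):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(scores, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    return h / correction


def simulate_hurdle(rng, x, gamma0, gamma1, beta0, beta1, theta):
    """Draw from the hurdle NB model with logistic zero part on x."""
    n = len(x)
    p_pos = expit(gamma0 + gamma1 * x)
    positive = rng.random(n) < p_pos
    mu = np.exp(beta0 + beta1 * x)
    y = np.zeros(n, dtype=int)
    idx = np.flatnonzero(positive)
    while len(idx):
        draw = rng.negative_binomial(theta, theta / (theta + mu[idx]))
        y[idx] = draw
        idx = idx[draw == 0]
    return y
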