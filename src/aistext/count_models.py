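"""Univariate count-outcome models: Poisson, negative binomial, hurdle NB.

The popularity analysis regresses a retweet-style count outcome on a single
predictor (a term's per-document frequency, or later an aggregated score).
Four model kinds are supported:

``poisson_loglinear``
    Poisson GLM, log E[y] = b0 + b*x.
``poisson_loglog``
    Poisson GLM with the skew-robust predictor transform,
    log E[y] = b0 + b*log(1 + x); keeps the mean positive and handles the
    zero term-frequencies that dominate a DTM column.
``negbin``
    NB2 negative binomial, Var(y) = mu + mu^2/theta, joint ML over
    (b0, b, theta).
``hurdle_nb``
    Two-part hurdle: a logistic model for the zero/positive indicator
    (coefficients gamma) and a zero-truncated NB2 for the positive counts
    (coefficients beta, theta).  The two component likelihoods share no
    parameters, so they are maximized independently and the total
    log-likelihood is their sum.

The exponentiated count-component slope exp(beta) is the relative risk
(RR): the multiplicative change in the expected count per unit increase of
the predictor.  Screening fits the chosen model once per vocabulary term
and collects the RRs as term weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, gammaln
from statsmodels.base.model import GenericLikelihoodModel

from .dtm import DocumentTermMatrix

__all__ = [
    "TermWeight",
    "CountModelFit",
    "nb_logpmf",
    "truncated_nb_logpmf",
    "fit_poisson",
    "fit_negbin",
    "fit_hurdle_nb",
    "fit_count_model",
    "relative_risk",
    "screen_terms_count",
    "THETA_CAP",
]

THETA_CAP = 1e8

COUNT_MODEL_KINDS = ("poisson_loglinear", "poisson_loglog", "negbin", "hurdle_nb")


@dataclass(frozen=True)
class TermWeight:
    """One term's univariate effect size.

    ``weight`` is the exponentiated slope (RR for count models, OR for the
    logistic model); ``std_err`` and ``p_value`` refer to the slope on the
    log scale (Wald).  A term whose fit failed or whose slope is
    inestimable carries ``weight=None`` and ``converged=False``.
    """

    term: str
    weight: Optional[float]
    std_err: Optional[float] = None
    p_value: Optional[float] = None
    converged: bool = True
    source: str = "hurdle_count"

    @property
    def is_missing(self) -> bool:
        return self.weight is None or not np.isfinite(self.weight)


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a < 0, stable at both ends."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = a < -np.log(2.0)
    out[small] = np.log1p(-np.exp(a[small]))
    out[~small] = np.log(-np.expm1(a[~small]))
    return out


def nb_logpmf(y, mu, theta) -> np.ndarray:
    """NB2 log-pmf with mean ``mu`` and dispersion ``theta``.

    Var(y) = mu + mu^2/theta; theta -> inf recovers the Poisson.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def truncated_nb_logpmf(y, mu, theta) -> np.ndarray:
    """Zero-truncated NB2 log-pmf: log[f(y; mu, theta) / (1 - f(0; mu, theta))].

    Support is y >= 1.  The renormalizing term uses log1p/expm1 so that
    neither f(0) near 0 (large mu) nor f(0) near 1 (tiny mu) loses
    precision.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 1) or np.any(y != np.floor(y)):
        raise ValueError("zero-truncated support is the positive integers")
    mu = np.asarray(mu, dtype=float)
    log_f = nb_logpmf(y, mu, theta)
    log_f0 = theta * (np.log(theta) - np.log(theta + mu))  # = -theta*log1p(mu/theta)
    log_f0 = np.broadcast_to(np.asarray(log_f0, dtype=float), log_f.shape)
    return log_f - _log1mexp(log_f0)


@dataclass
class CountModelFit:
    """Fitted-model summary for one univariate count regression.

    ``count_coefs`` is ``[b0, b]`` (slope NaN when inestimable);
    ``zero_coefs`` is ``[g0, g]`` for hurdle fits, None otherwise.
    ``dispersion`` is theta for the NB variants.  ``aic`` satisfies
    ``aic = 2*n_params - 2*loglik``.
    """

    model_kind: str
    count_coefs: np.ndarray
    count_bse: np.ndarray
    count_pvalues: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    dispersion: Optional[float] = None
    zero_coefs: Optional[np.ndarray] = None
    zero_bse: Optional[np.ndarray] = None
    zero_pvalues: Optional[np.ndarray] = None
    n_params: int = 2
    x: Optional[np.ndarray] = field(default=None, repr=False)
    y: Optional[np.ndarray] = field(default=None, repr=False)

    def _xt(self) -> np.ndarray:
        if self.x is None:
            return np.zeros(self.n_obs)
        x = np.asarray(self.x, dtype=float)
        return np.log1p(x) if self.model_kind == "poisson_loglog" else x

    def count_mean(self) -> np.ndarray:
        """Per-observation mean of the (untruncated) count component."""
        xt = self._xt()
        b = np.where(np.isfinite(self.count_coefs), self.count_coefs, 0.0)
        eta = b[0] + (b[1] * xt if len(b) > 1 else 0.0)
        return np.exp(eta)

    def prob_positive(self) -> np.ndarray:
        """Per-observation P(y > 0) under the fitted model."""
        return 1.0 - self.prob_zero()

    def prob_zero(self) -> np.ndarray:
        """Per-observation fitted probability of a zero count."""
        if self.model_kind == "hurdle_nb":
            g = np.where(np.isfinite(self.zero_coefs), self.zero_coefs, 0.0)
            eta = g[0] + (g[1] * self._xt() if len(g) > 1 else 0.0)
            return 1.0 - expit(eta)
        mu = self.count_mean()
        if self.model_kind == "negbin":
            return np.exp(nb_logpmf(0.0, mu, self.dispersion))
        return np.exp(-mu)

    def pmf(self, c: int) -> np.ndarray:
        """Per-observation P(y = c) under the fitted model."""
        if c == 0:
            return self.prob_zero()
        mu = self.count_mean()
        if self.model_kind == "hurdle_nb":
            p_pos = self.prob_positive()
            return p_pos * np.exp(truncated_nb_logpmf(float(c), mu, self.dispersion))
        if self.model_kind == "negbin":
            return np.exp(nb_logpmf(float(c), mu, self.dispersion))
        return np.exp(c * np.log(mu) - mu - gammaln(c + 1.0))

    def predicted_mean(self) -> np.ndarray:
        """Per-observation E[y] under the fitted model."""
        mu = self.count_mean()
        if self.model_kind != "hurdle_nb":
            return mu
        theta = self.dispersion
        log_f0 = theta * (np.log(theta) - np.log(theta + mu))
        return self.prob_positive() * mu / -np.expm1(log_f0)


def _validate_xy(y, x, allow_binary: bool = False):
    y = np.asarray(y)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y must be a 1-d vector of length >= 2")
    yf = y.astype(float)
    if np.any(yf < 0) or np.any(yf != np.floor(yf)):
        raise ValueError("y must contain non-negative integers")
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if not np.all(np.isfinite(x)):
            raise ValueError("x must be finite")
    return yf, x


def _design(xt):
    return sm.add_constant(xt, has_constant="add")


def fit_poisson(y, x=None, link: str = "loglinear") -> CountModelFit:
    """ML Poisson fit of a count outcome on a single predictor.

    ``link='loglinear'`` uses log E[y] = b0 + b*x; ``link='loglog'`` uses
    log E[y] = b0 + b*log(1 + x).  A constant predictor leaves the slope
    inestimable: the intercept-only model is returned with
    ``converged=False`` and a NaN slope.
    """
    if link not in ("loglinear", "loglog"):
        raise ValueError(f"unknown link {link!r}")
    y, x = _validate_xy(y, x)
    kind = f"poisson_{link}"
    xt = None if x is None else (np.log1p(x) if link == "loglog" else x)
    degenerate = xt is not None and np.ptp(xt) == 0.0

    if xt is None or degenerate:
        res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
        coefs = np.array([res.params[0], np.nan]) if x is not None else np.array([res.params[0]])
        bse = np.array([res.bse[0], np.nan]) if x is not None else np.array([res.bse[0]])
        pv = np.array([res.pvalues[0], np.nan]) if x is not None else np.array([res.pvalues[0]])
        k = 1
        return CountModelFit(
            kind, coefs, bse, pv, float(res.llf), 2.0 * k - 2.0 * res.llf,
            converged=not degenerate, n_obs=len(y), n_params=k, x=x, y=y,
        )
    res = sm.GLM(y, _design(xt), family=sm.families.Poisson()).fit()
    return CountModelFit(
        kind, np.asarray(res.params), np.asarray(res.bse), np.asarray(res.pvalues),
        float(res.llf), 2.0 * 2 - 2.0 * float(res.llf),
        converged=bool(res.converged), n_obs=len(y), n_params=2, x=x, y=y,
    )


def fit_negbin(y, x=None) -> CountModelFit:
    """Joint ML fit of the NB2 model over (b0, b, theta).

    Equidispersed data push theta to infinity; theta is capped at
    ``THETA_CAP`` with a warning and the fit reported as converged, since
    the capped model is numerically indistinguishable from the Poisson
    limit it approaches.
    """
    y, x = _validate_xy(y, x)
    degenerate = x is not None and np.ptp(x) == 0.0
    X = np.ones((len(y), 1)) if (x is None or degenerate) else _design(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=500)
    params = np.asarray(res.params, dtype=float)
    alpha = max(float(params[-1]), 0.0)
    # alpha below any plausible SE is the equidispersion boundary
    theta = 1.0 / alpha if alpha > 1e-6 else THETA_CAP
    if alpha <= 1e-6:
        warnings.warn(
            "NB dispersion at the equidispersion boundary; theta capped at "
            f"{THETA_CAP:g} (Poisson limit)", RuntimeWarning, stacklevel=2,
        )
    nb_coefs = params[:-1]
    bse = np.asarray(res.bse, dtype=float)[:-1]
    pv = np.asarray(res.pvalues, dtype=float)[:-1]
    if degenerate:
        nb_coefs = np.array([nb_coefs[0], np.nan])
        bse = np.array([bse[0], np.nan])
        pv = np.array([pv[0], np.nan])
    k = X.shape[1] + 1
    converged = bool(res.mle_retvals.get("converged", True)) and not degenerate
    return CountModelFit(
        "negbin", nb_coefs, bse, pv, float(res.llf), 2.0 * k - 2.0 * float(res.llf),
        converged=converged, n_obs=len(y), dispersion=theta, n_params=k, x=x, y=y,
    )


class _ZeroTruncatedNB(GenericLikelihoodModel):
    """Zero-truncated NB2 likelihood; params = (beta..., log_theta)."""

    def nloglikeobs(self, params):
        beta, log_theta = params[:-1], params[-1]
        eta = np.clip(self.exog @ beta, -30.0, 30.0)
        theta = np.exp(np.clip(log_theta, -20.0, np.log(THETA_CAP)))
        return -truncated_nb_logpmf(self.endog, np.exp(eta), theta)


def fit_hurdle_nb(y, x=None) -> CountModelFit:
    """ML fit of the hurdle negative-binomial model on one predictor.

    The zero component is a logistic regression of the positive-count
    indicator on x (coefficients gamma); the count component is a
    zero-truncated NB2 of y | y > 0 on x (coefficients beta, theta).  Both
    components use the same predictor and are maximized independently; the
    reported log-likelihood is their sum, and the model-implied expected
    number of zeros matches the observed number exactly (a structural
    property of the hurdle).
    """
    y, x = _validate_xy(y, x)
    pos = y > 0
    if pos.all() or not pos.any():
        raise ValueError("hurdle model needs at least one zero and one positive count")
    degenerate = x is not None and np.ptp(x) == 0.0
    use_x = x is not None and not degenerate

    Xz = _design(x) if use_x else np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logit_res = sm.Logit(pos.astype(float), Xz).fit(disp=0, maxiter=200)
    zero_ok = bool(logit_res.mle_retvals.get("converged", True))

    yp = y[pos]
    Xp = _design(x[pos]) if use_x else np.ones((len(yp), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_glm = sm.GLM(yp, Xp, family=sm.families.Poisson()).fit()
        start = np.append(np.asarray(start_glm.params), 0.0)
        model = _ZeroTruncatedNB(yp, Xp)
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, method="nm",
                            maxiter=2000, disp=0)
    count_ok = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
    theta = float(np.exp(np.clip(params[-1], -20.0, np.log(THETA_CAP))))
    if theta >= THETA_CAP:
        warnings.warn("truncated-NB dispersion capped (Poisson limit)",
                      RuntimeWarning, stacklevel=2)

    count_coefs, count_bse, count_pv = params[:-1], bse[:-1], pvals[:-1]
    zero_coefs = np.asarray(logit_res.params, dtype=float)
    zero_bse = np.asarray(logit_res.bse, dtype=float)
    zero_pv = np.asarray(logit_res.pvalues, dtype=float)
    if x is not None and not use_x:
        nan = np.array([np.nan])
        count_coefs = np.concatenate([count_coefs, nan])
        count_bse = np.concatenate([count_bse, nan])
        count_pv = np.concatenate([count_pv, nan])
        zero_coefs = np.concatenate([zero_coefs, nan])
        zero_bse = np.concatenate([zero_bse, nan])
        zero_pv = np.concatenate([zero_pv, nan])

    loglik = float(logit_res.llf) + float(res.llf)
    k = Xz.shape[1] + Xp.shape[1] + 1
    return CountModelFit(
        "hurdle_nb", count_coefs, count_bse, count_pv, loglik,
        2.0 * k - 2.0 * loglik,
        converged=zero_ok and count_ok and not degenerate,
        n_obs=len(y), dispersion=theta,
        zero_coefs=zero_coefs, zero_bse=zero_bse, zero_pvalues=zero_pv,
        n_params=k, x=x, y=y,
    )


_FITTERS = {
    "poisson_loglinear": lambda y, x: fit_poisson(y, x, link="loglinear"),
    "poisson_loglog": lambda y, x: fit_poisson(y, x, link="loglog"),
    "negbin": fit_negbin,
    "hurdle_nb": fit_hurdle_nb,
}


def fit_count_model(y, x, model_kind: str) -> CountModelFit:
    """Dispatch to the requested count-model fitter."""
    if model_kind not in _FITTERS:
        raise ValueError(f"unknown model_kind {model_kind!r}; choose from {COUNT_MODEL_KINDS}")
    return _FITTERS[model_kind](y, x)


_SOURCES = {
    "hurdle_nb": "hurdle_count",
    "negbin": "negbin",
    "poisson_loglinear": "poisson",
    "poisson_loglog": "poisson",
}


def relative_risk(fit: CountModelFit, term: str = "") -> TermWeight:
    """Extract the relative risk exp(slope) of the count component."""
    source = _SOURCES.get(fit.model_kind, fit.model_kind)
    slope = fit.count_coefs[1] if len(fit.count_coefs) > 1 else np.nan
    if not fit.converged or not np.isfinite(slope):
        return TermWeight(term, None, converged=False, source=source)
    se = fit.count_bse[1] if len(fit.count_bse) > 1 else None
    pv = fit.count_pvalues[1] if len(fit.count_pvalues) > 1 else None
    return TermWeight(
        term, float(np.exp(slope)),
        std_err=None if se is None or not np.isfinite(se) else float(se),
        p_value=None if pv is None or not np.isfinite(pv) else float(pv),
        converged=True, source=source,
    )


def screen_terms_count(
    dtm: DocumentTermMatrix, y, model_kind: str = "hurdle_nb"
) -> list[TermWeight]:
    """Fit one univariate count model per term and collect RR weights.

    The predictor for each fit is the term's frequency column of the DTM.
    Per-term failures (all-zero columns, non-convergence, optimizer
    errors) are recorded as absent weights, never raised; the output order
    follows the DTM vocabulary.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(dtm.doc_ids):
        raise ValueError("outcome vector not aligned with DTM rows")
    source = _SOURCES.get(model_kind, model_kind)
    out = []
    for term in dtm.terms:
        x = dtm.column(term).astype(float)
        if np.ptp(x) == 0.0:
            out.append(TermWeight(term, None, converged=False, source=source))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_count_model(y, x, model_kind)
            out.append(relative_risk(fit, term))
        except Exception:
            out.append(TermWeight(term, None, converged=False, source=source))
    return out


def term_weights_to_frame(weights: Sequence[TermWeight]):
    """Term-weight table with columns term/weight/std_err/p_value/converged/source."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term": [w.term for w in weights],
            "weight": [w.weight for w in weights],
            "std_err": [w.std_err for w in weights],
            "p_value": [w.p_value for w in weights],
            "converged": [w.converged for w in weights],
            "source": [w.source for w in weights],
        }
    )
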