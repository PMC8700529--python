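"""Univariate logistic regression per term; odds-ratio weights.

Topic classification treats each vocabulary term separately: a logistic
model log(pi/(1-pi)) = b0 + b1*x of the binary topic label on the term's
frequency yields an odds ratio OR = exp(b1) per term.  ORs above one mark
terms over-represented in the positive-topic group; they are the weights
aggregated into per-document scores downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .count_models import TermWeight
from .dtm import DocumentTermMatrix

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "odds_ratio",
    "shared_terms",
    "screen_terms_logistic",
]


@dataclass
class LogisticFit:
    """Fitted univariate logistic model summary."""

    coefs: np.ndarray  # [b0, b1]
    bse: np.ndarray
    pvalues: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    model_kind: str = "logistic"
    x: Optional[np.ndarray] = field(default=None, repr=False)
    y: Optional[np.ndarray] = field(default=None, repr=False)

    def predict_proba(self, x=None) -> np.ndarray:
        x = self.x if x is None else np.asarray(x, dtype=float)
        b = np.where(np.isfinite(self.coefs), self.coefs, 0.0)
        return expit(b[0] + (b[1] * x if len(b) > 1 else 0.0))


def fit_logistic(y, x) -> LogisticFit:
    """ML logistic fit of a binary outcome on one predictor.

    Raises if only one class is present.  Under complete separation the
    slope diverges: the fit is returned with ``converged=False`` and a
    warning rather than an exception, since screening must survive
    individual pathological terms.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-d vectors of equal length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    degenerate = np.ptp(x) == 0.0
    X = np.ones((len(y), 1)) if degenerate else sm.add_constant(x, has_constant="add")
    converged = not degenerate
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = converged and bool(res.mle_retvals.get("converged", True))
    except Exception:
        # perfect separation or optimizer failure: retry with a bounded
        # number of BFGS steps to obtain a (diverging-slope) summary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=50, disp=0)
        converged = False
        warnings.warn("logistic fit did not converge (possible complete separation)",
                      RuntimeWarning, stacklevel=2)
    if converged and not degenerate and abs(res.params[1]) > 15.0:
        converged = False
        warnings.warn("diverging logistic slope (complete separation)",
                      RuntimeWarning, stacklevel=2)

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pv = np.asarray(res.pvalues, dtype=float)
    if degenerate:
        params = np.array([params[0], np.nan])
        bse = np.array([bse[0], np.nan])
        pv = np.array([pv[0], np.nan])
    k = 1 if degenerate else 2
    return LogisticFit(
        params, bse, pv, float(res.llf), 2.0 * k - 2.0 * float(res.llf),
        converged=converged, n_obs=len(y), x=x, y=y,
    )


def odds_ratio(fit: LogisticFit, term: str = "") -> TermWeight:
    """Extract the odds ratio exp(slope) as a term weight."""
    slope = fit.coefs[1] if len(fit.coefs) > 1 else np.nan
    if not fit.converged or not np.isfinite(slope):
        return TermWeight(term, None, converged=False, source="logistic")
    se = fit.bse[1]
    pv = fit.pvalues[1]
    return TermWeight(
        term, float(np.exp(slope)),
        std_err=float(se) if np.isfinite(se) else None,
        p_value=float(pv) if np.isfinite(pv) else None,
        converged=True, source="logistic",
    )


def shared_terms(dtm: DocumentTermMatrix, labels) -> np.ndarray:
    """Terms present at least once in each of the two label groups."""
    labels = np.asarray(labels)
    pos = labels == 1
    counts = dtm.counts
    import scipy.sparse as sp

    if sp.issparse(counts):
        in_pos = np.asarray((counts[pos] > 0).sum(axis=0)).ravel() > 0
        in_neg = np.asarray((counts[~pos] > 0).sum(axis=0)).ravel() > 0
    else:
        in_pos = (counts[pos] > 0).any(axis=0)
        in_neg = (counts[~pos] > 0).any(axis=0)
    return dtm.terms[in_pos & in_neg]


def screen_terms_logistic(dtm: DocumentTermMatrix, labels) -> list[TermWeight]:
    """Fit one univariate logistic model per shared term; collect OR weights.

    The vocabulary is restricted to terms occurring at least once in each
    label group (terms confined to one group would sit on the separation
    boundary and carry no usable OR).  Per-term failures are recorded as
    absent weights.
    """
    labels = np.asarray(labels, dtype=float)
    if len(labels) != len(dtm.doc_ids):
        raise ValueError("label vector not aligned with DTM rows")
    out = []
    for term in shared_terms(dtm, labels):
        x = dtm.column(term).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_logistic(labels, x)
            out.append(odds_ratio(fit, term))
        except Exception:
            out.append(TermWeight(term, None, converged=False, source="logistic"))
    return out
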