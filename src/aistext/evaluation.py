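"""Final AIS-predictor models and diagnostics.

Case I (popularity): the aggregated score becomes the single predictor of
the count outcome; model adequacy is judged by AIC, by a hanging rootogram
(square-root scale comparison of observed and model-expected count
frequencies) and by the expected-zeros difference D = observed zeros minus
the model-implied expected number of zeros.  A hurdle fit gives D = 0
structurally — its logistic zero component reproduces the observed zero
total through its score equations — while Poisson and plain NB fits on
zero-heavy data under-predict zeros (D < 0).

Case II (classification): group separation of the scores is tested with
the Kruskal-Wallis rank-sum test (equivalent to the Wilcoxon rank-sum test
for two groups, up to the form of the statistic) and classification
performance with an empirical ROC curve, trapezoidal AUC and a
Youden-J-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .count_models import CountModelFit, fit_count_model

__all__ = [
    "RootogramData",
    "ROCResult",
    "fit_final_count",
    "expected_zeros_diff",
    "rootogram",
    "kruskal_wallis",
    "roc_analysis",
]


@dataclass
class RootogramData:
    """Hanging rootogram on the square-root scale.

    For count c, the bar hangs from sqrt(expected_freq[c]) down to
    sqrt(expected_freq[c]) - sqrt(observed_freq[c]); a bar bottom near
    zero means the model reproduces that count's frequency.
    """

    count_bins: np.ndarray
    observed_freq: np.ndarray
    expected_freq: np.ndarray
    scale: str = "sqrt"
    style: str = "hanging"

    def bar_bottoms(self) -> np.ndarray:
        return np.sqrt(self.expected_freq) - np.sqrt(self.observed_freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.count_bins,
                "observed": self.observed_freq,
                "expected": self.expected_freq,
            }
        )


@dataclass
class ROCResult:
    """Empirical ROC curve with trapezoidal AUC and Youden-optimal cutoff.

    ``thresholds`` are the distinct score cutoffs in ascending order with
    per-threshold sensitivity/specificity under the rule "predict positive
    when the score is on the positive side of the cutoff" (which side that
    is depends on ``direction``).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_sens: float
    best_spec: float
    direction: str = "higher_is_positive"
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def drop_missing_ais(ais, y):
    """Remove documents whose AIS is missing (NaN) from both vectors."""
    ais = np.asarray(ais, dtype=float)
    y = np.asarray(y)
    keep = np.isfinite(ais)
    return ais[keep], y[keep], int((~keep).sum())


def fit_final_count(ais, y, model_kind: str = "hurdle_nb") -> CountModelFit:
    """Fit the final count model with the aggregated score as predictor.

    Documents with missing AIS must already be excluded; NaN scores raise.
    """
    ais = np.asarray(ais, dtype=float)
    if np.any(~np.isfinite(ais)):
        raise ValueError("ais contains missing values; drop them first (drop_missing_ais)")
    return fit_count_model(y, ais, model_kind)


def expected_zeros_diff(fit: CountModelFit, y=None) -> float:
    """D = sum_i P_fit(y_i = 0) - observed number of zeros.

    Negative D means the model predicts fewer zeros than observed
    (under-prediction, the usual failure of Poisson/NB fits on zero-heavy
    data).  For a hurdle fit the per-observation zero probability is the
    fitted logistic zero-component probability, whose total equals the
    observed zero count exactly, so D = 0 up to solver tolerance.
    """
    y = np.asarray(fit.y if y is None else y, dtype=float)
    observed = float((y == 0).sum())
    return float(fit.prob_zero().sum()) - observed


def rootogram(fit: CountModelFit, y=None, max_count: Optional[int] = None) -> RootogramData:
    """Observed vs model-expected count frequencies on bins 0..max_count.

    ``expected_freq[c] = sum_i P_fit(y_i = c)``; counts above
    ``max_count`` are outside the binned range (choose ``max_count >=
    max(y)`` to cover every observation).
    """
    y = np.asarray(fit.y if y is None else y, dtype=float)
    if max_count is None:
        max_count = int(y.max())
    bins = np.arange(max_count + 1)
    observed = np.bincount(y.astype(int), minlength=max_count + 1)[: max_count + 1]
    expected = np.array([fit.pmf(int(c)).sum() for c in bins], dtype=float)
    return RootogramData(bins, observed, expected)


def kruskal_wallis(scores, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test of the scores across two groups.

    Returns the tie-corrected statistic and its chi-square p-value (1 df
    for two groups).  Invariant under strictly increasing transforms of
    the scores.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    g0, g1 = scores[groups == 0], scores[groups == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.kruskal(g0, g1)
    return float(stat), float(p)


def roc_analysis(scores, labels, direction: str = "higher_is_positive") -> ROCResult:
    """Empirical ROC over all distinct score cutoffs.

    AUC is the trapezoidal area under (1 - specificity, sensitivity),
    equal to the Mann-Whitney probability with ties given half credit.
    The reported cutoff maximizes Youden J = sensitivity + specificity - 1,
    ties broken toward the smaller cutoff.  ``direction`` states which end
    of the score scale indicates the positive class; ``'auto'`` picks the
    orientation with AUC >= 0.5 and reports it (no silent flipping under
    the explicit directions, so an inverted score yields AUC < 0.5 as
    computed).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d vectors of equal length")
    if not np.all(np.isin(np.unique(labels), (0.0, 1.0))) or len(np.unique(labels)) < 2:
        raise ValueError("labels must be binary with both classes present")
    if direction not in ("higher_is_positive", "lower_is_positive", "auto"):
        raise ValueError(f"unknown direction {direction!r}")

    if direction == "auto":
        res = roc_analysis(scores, labels, "higher_is_positive")
        if res.auc >= 0.5:
            return res
        return roc_analysis(scores, labels, "lower_is_positive")

    sign = 1.0 if direction == "higher_is_positive" else -1.0
    degenerate = np.ptp(scores) == 0.0
    fpr, tpr, thr = roc_curve(labels, sign * scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    # drop the sentinel +inf threshold; restore original score scale
    keep = np.isfinite(thr)
    thr, tpr, fpr = sign * thr[keep], tpr[keep], fpr[keep]
    spec = 1.0 - fpr
    order = np.argsort(thr, kind="stable")
    thr, sens, spec = thr[order], tpr[order], spec[order]

    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # smallest cutoff among ties
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_cutoff=float(thr[best]),
        best_sens=float(sens[best]),
        best_spec=float(spec[best]),
        direction=direction,
        degenerate=bool(degenerate),
    )
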