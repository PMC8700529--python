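"""Aggregated influence scores: per-document summaries of term weights.

A screened vocabulary assigns each term a univariate weight w (an RR from a
count model or an OR from a logistic model).  For a document containing
terms i = 1..k with frequencies n_i, the per-term propensity score is
n_i * w_i and the document-level aggregated influence scores (AIS) are

    AIS-mean   = sum_i n_i w_i / sum_i n_i
    AIS-median = median of the multiset in which w_i appears n_i times
    AIS-sum    = sum_i n_i w_i

Terms without a usable weight (failed or inestimable fits) are silently
excluded; a document containing no weighted term has missing AIS values
and is dropped before any downstream model.  AIS-mean and AIS-median are
bounded by the smallest and largest weight used; AIS-sum is not, which is
why it degrades as a classification score when group vocabularies differ
in size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .count_models import TermWeight, screen_terms_count
from .dtm import DocumentTermMatrix
from .logistic_models import screen_terms_logistic

__all__ = [
    "AISRecord",
    "propensity_scores",
    "ais_mean",
    "ais_median",
    "ais_sum",
    "score_document",
    "score_corpus",
    "AISScorer",
]


@dataclass(frozen=True)
class AISRecord:
    """Per-document AIS summaries; all three missing iff no weighted term."""

    doc_id: str
    ais_mean: Optional[float]
    ais_median: Optional[float]
    ais_sum: Optional[float]
    n_terms_used: int

    @property
    def is_missing(self) -> bool:
        return self.n_terms_used == 0


def propensity_scores(
    doc_counts: Mapping[str, int], weights: Sequence[TermWeight]
) -> list[tuple[str, int, float]]:
    """Pair each weighted term in a document with (frequency, weight).

    Only terms with a present (finite) weight and a positive frequency in
    the document are retained; the result may be empty.
    """
    by_term = {w.term: w for w in weights}
    pairs = []
    for term, n in doc_counts.items():
        if n <= 0:
            continue
        w = by_term.get(term)
        if w is None or w.is_missing:
            continue
        pairs.append((term, int(n), float(w.weight)))
    return pairs


def _freqs_weights(pairs) -> tuple[np.ndarray, np.ndarray]:
    # accepts (term, n, w) triples or bare (n, w) pairs
    rows = [(p[-2], p[-1]) for p in pairs]
    n = np.array([r[0] for r in rows], dtype=float)
    w = np.array([r[1] for r in rows], dtype=float)
    return n, w


def ais_mean(pairs) -> Optional[float]:
    """Frequency-weighted mean of term weights; None on an empty document."""
    if not pairs:
        return None
    n, w = _freqs_weights(pairs)
    return float(np.sum(n * w) / np.sum(n))


def ais_sum(pairs) -> Optional[float]:
    """Sum of frequency x weight over the document's weighted terms."""
    if not pairs:
        return None
    n, w = _freqs_weights(pairs)
    return float(np.sum(n * w))


def ais_median(pairs) -> Optional[float]:
    """Median of the frequency-replicated weight multiset.

    Each weight w_i is replicated n_i times, the multiset sorted
    ascending; an odd total frequency takes the middle element, an even
    total the mean of the two middle elements.
    """
    if not pairs:
        return None
    n, w = _freqs_weights(pairs)
    expanded = np.repeat(w, n.astype(int))
    return float(np.median(np.sort(expanded)))


def score_document(
    doc_id: str, doc_counts: Mapping[str, int], weights: Sequence[TermWeight]
) -> AISRecord:
    pairs = propensity_scores(doc_counts, weights)
    return AISRecord(
        doc_id=doc_id,
        ais_mean=ais_mean(pairs),
        ais_median=ais_median(pairs),
        ais_sum=ais_sum(pairs),
        n_terms_used=len(pairs),
    )


def score_corpus(dtm: DocumentTermMatrix, weights: Sequence[TermWeight]) -> pd.DataFrame:
    """Score every document of a DTM; one row per document.

    Returns a DataFrame with columns doc_id, ais_mean, ais_median,
    ais_sum, n_terms_used; the three scores are NaN for documents without
    any weighted term (those rows are excluded from downstream models).
    """
    by_term = {w.term: float(w.weight) for w in weights if not w.is_missing}
    terms = dtm.terms
    usable = np.array([t in by_term for t in terms], dtype=bool)
    wvec = np.array([by_term.get(t, np.nan) for t in terms], dtype=float)

    counts = dtm.dense_counts().astype(float)
    records = []
    for i, doc_id in enumerate(dtm.doc_ids):
        row = counts[i]
        mask = usable & (row > 0)
        k = int(mask.sum())
        if k == 0:
            records.append((doc_id, np.nan, np.nan, np.nan, 0))
            continue
        n, w = row[mask], wvec[mask]
        total = n.sum()
        mean = float((n * w).sum() / total)
        med = float(np.median(np.repeat(w, n.astype(int))))
        records.append((doc_id, mean, med, float((n * w).sum()), k))
    return pd.DataFrame(
        records, columns=["doc_id", "ais_mean", "ais_median", "ais_sum", "n_terms_used"]
    )


class AISScorer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: DTM counts in, per-document AIS columns out.

    ``fit(X, y)`` screens every term of ``X`` with the configured
    univariate model against ``y`` (a count outcome for the count-model
    kinds, a binary label for ``model_kind='logistic'``) and stores the
    term weights.  ``transform(X)`` aggregates the stored weights into the
    requested summaries, returning an (n_docs, n_aggregations) float array
    with NaN rows for documents containing no weighted term.

    Parameters
    ----------
    model_kind : str
        'hurdle_nb' (default), 'negbin', 'poisson_loglinear',
        'poisson_loglog' or 'logistic'.
    aggregations : tuple of str
        Any of 'mean', 'median', 'sum'; order defines the output columns.
    terms : sequence of str, optional
        Column names of X when X is a bare array; inferred from
        DataFrame columns or a DocumentTermMatrix otherwise.

    Attributes
    ----------
    term_weights_ : list of TermWeight
    weights_ : DataFrame
        Tabular view of ``term_weights_``.
    """

    def __init__(self, model_kind: str = "hurdle_nb",
                 aggregations: tuple = ("mean", "median", "sum"),
                 terms: Optional[Sequence[str]] = None):
        self.model_kind = model_kind
        self.aggregations = aggregations
        self.terms = terms

    def _to_dtm(self, X) -> DocumentTermMatrix:
        if isinstance(X, DocumentTermMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return DocumentTermMatrix(
                [str(i) for i in X.index], np.asarray(X.columns, dtype=object), X.to_numpy()
            )
        X = np.asarray(X) if not hasattr(X, "tocsr") else X
        n_terms = X.shape[1]
        terms = self.terms if self.terms is not None else [f"term_{j}" for j in range(n_terms)]
        if len(terms) != n_terms:
            raise ValueError("terms length does not match number of columns")
        return DocumentTermMatrix(
            [str(i) for i in range(X.shape[0])], np.asarray(terms, dtype=object), X
        )

    def fit(self, X, y):
        bad = set(self.aggregations) - {"mean", "median", "sum"}
        if bad:
            raise ValueError(f"unknown aggregations: {sorted(bad)}")
        dtm = self._to_dtm(X)
        y = np.asarray(y)
        if len(y) != len(dtm.doc_ids):
            raise ValueError("y is not aligned with the rows of X")
        if self.model_kind == "logistic":
            self.term_weights_ = screen_terms_logistic(dtm, y)
        else:
            self.term_weights_ = screen_terms_count(dtm, y, self.model_kind)
        from .count_models import term_weights_to_frame

        self.weights_ = term_weights_to_frame(self.term_weights_)
        self.n_features_in_ = dtm.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "term_weights_")
        scored = score_corpus(self._to_dtm(X), self.term_weights_)
        cols = [f"ais_{a}" for a in self.aggregations]
        return scored[cols].to_numpy(dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"ais_{a}" for a in self.aggregations], dtype=object)
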