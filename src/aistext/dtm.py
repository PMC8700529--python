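"""Document-term matrix construction, sparse-term filtering and outcome joins.

The document-term matrix (DTM) is the bag-of-words container for the whole
pipeline: one row per document, one column per vocabulary term, integer
occurrence counts.  Terms whose document frequency (number of documents
containing the term at least once) does not exceed a threshold ``k`` are
treated as noise and dropped before screening; the study default is
``k = 500`` on a ~55k-document corpus.

The matrix behaves identically whether stored dense (ndarray) or sparse
(CSR); both storages are supported and interconvertible.  Matrix-market
(.mtx) export with side files for the term and document labels makes every
intermediate artifact plain text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import CleanDocument, RawDocument

__all__ = [
    "DocumentTermMatrix",
    "TermDocumentMatrix",
    "build_dtm",
    "filter_sparse",
    "transpose",
    "join_outcomes",
    "save_dtm",
    "load_dtm",
    "TokenCountVectorizer",
]


def _as_2d_counts(counts):
    if sp.issparse(counts):
        return counts.tocsr()
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError("counts must be 2-dimensional")
    return arr


@dataclass
class DocumentTermMatrix:
    """Documents x terms count matrix with aligned labels.

    Attributes
    ----------
    doc_ids : list of str
        Row labels, unique within the matrix.
    terms : ndarray of str
        Column labels (the vocabulary), unique.
    counts : ndarray or CSR matrix
        Non-negative integer occurrence counts.
    """

    doc_ids: list
    terms: np.ndarray
    counts: object

    def __post_init__(self) -> None:
        self.doc_ids = list(self.doc_ids)
        self.terms = np.asarray(self.terms, dtype=object)
        self.counts = _as_2d_counts(self.counts)
        n, m = self.counts.shape
        if n != len(self.doc_ids) or m != len(self.terms):
            raise ValueError(
                f"shape mismatch: counts {self.counts.shape} vs "
                f"{len(self.doc_ids)} docs x {len(self.terms)} terms"
            )
        if len(set(self.doc_ids)) != n:
            raise ValueError("doc_ids must be unique")
        if len(set(self.terms)) != m:
            raise ValueError("terms must be unique")

    @property
    def shape(self):
        return self.counts.shape

    @property
    def doc_freq(self) -> np.ndarray:
        """Per-term number of documents with a positive count."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts > 0).sum(axis=0)).ravel()
        return (self.counts > 0).sum(axis=0)

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def column(self, term: str) -> np.ndarray:
        """Dense count vector of one term across documents."""
        idx = np.flatnonzero(self.terms == term)
        if idx.size == 0:
            raise KeyError(term)
        col = self.counts[:, idx[0]]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense_counts(), index=self.doc_ids, columns=list(self.terms))

    def filter_sparse(self, k: int) -> "DocumentTermMatrix":
        return filter_sparse(self, k)

    def transpose(self) -> "TermDocumentMatrix":
        return transpose(self)


@dataclass
class TermDocumentMatrix:
    """Transposed view: terms as rows, documents as columns."""

    terms: np.ndarray
    doc_ids: list
    counts: object

    def __post_init__(self) -> None:
        self.terms = np.asarray(self.terms, dtype=object)
        self.doc_ids = list(self.doc_ids)
        self.counts = _as_2d_counts(self.counts)
        if self.counts.shape != (len(self.terms), len(self.doc_ids)):
            raise ValueError("shape mismatch in term-document matrix")

    @property
    def shape(self):
        return self.counts.shape

    def transpose(self) -> DocumentTermMatrix:
        return DocumentTermMatrix(self.doc_ids, self.terms, self.counts.T)


def build_dtm(docs: Sequence[CleanDocument], sparse: bool = True) -> DocumentTermMatrix:
    """Build a DTM from cleaned documents.

    The vocabulary is the sorted union of all tokens; ``counts[d, t]`` is
    the number of occurrences of term ``t`` in document ``d``.
    """
    if len(docs) == 0:
        raise ValueError("cannot build a DTM from an empty corpus")
    vocab: dict[str, int] = {}
    for doc in docs:
        for tok in doc.tokens:
            vocab.setdefault(tok, 0)
    terms = sorted(vocab)
    term_idx = {t: j for j, t in enumerate(terms)}

    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        seen: dict[int, int] = {}
        for tok in doc.tokens:
            seen[term_idx[tok]] = seen.get(term_idx[tok], 0) + 1
        for j, c in seen.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(terms)), dtype=np.int64
    )
    if not sparse:
        mat = np.asarray(mat.todense())
    return DocumentTermMatrix([d.doc_id for d in docs], np.array(terms, dtype=object), mat)


def filter_sparse(dtm: DocumentTermMatrix, k: int) -> DocumentTermMatrix:
    """Drop terms whose document frequency is <= k; rows are preserved.

    Monotone in ``k``: a larger threshold retains a subset of the terms.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    keep = np.flatnonzero(dtm.doc_freq > k)
    return DocumentTermMatrix(dtm.doc_ids, dtm.terms[keep], dtm.counts[:, keep])


def transpose(dtm: DocumentTermMatrix) -> TermDocumentMatrix:
    """Transpose a DTM into a term-document matrix (labels swapped)."""
    return TermDocumentMatrix(dtm.terms, dtm.doc_ids, dtm.counts.T)


def join_outcomes(dtm: DocumentTermMatrix, raw_docs: Sequence[RawDocument]) -> pd.DataFrame:
    """Attach outcome columns to the DTM rows, aligned by doc_id.

    Returns a DataFrame indexed by doc_id with ``outcome_count`` and
    ``topic_label`` columns (NaN where absent) followed by the term counts.
    Alignment is by identifier, never by position; a DTM document missing
    from ``raw_docs`` raises ``KeyError``.
    """
    by_id = {d.doc_id: d for d in raw_docs}
    missing = [i for i in dtm.doc_ids if i not in by_id]
    if missing:
        raise KeyError(f"doc_ids missing from raw corpus: {missing[:5]}")
    meta = pd.DataFrame(
        {
            "outcome_count": [by_id[i].outcome_count for i in dtm.doc_ids],
            "topic_label": [by_id[i].topic_label for i in dtm.doc_ids],
        },
        index=dtm.doc_ids,
        dtype=float,
    )
    return pd.concat([meta, dtm.to_dataframe()], axis=1)


def save_dtm(dtm: DocumentTermMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.terms.txt`` / ``.docs.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = dtm.counts if sp.issparse(dtm.counts) else sp.csr_matrix(dtm.counts)
    mmwrite(str(prefix) + ".mtx", mat)
    Path(str(prefix) + ".terms.txt").write_text("\n".join(dtm.terms) + "\n", encoding="utf-8")
    Path(str(prefix) + ".docs.txt").write_text(
        "\n".join(str(d) for d in dtm.doc_ids) + "\n", encoding="utf-8"
    )


def load_dtm(prefix, sparse: bool = True) -> DocumentTermMatrix:
    mat = mmread(str(prefix) + ".mtx").tocsr().astype(np.int64)
    terms = Path(str(prefix) + ".terms.txt").read_text(encoding="utf-8").splitlines()
    docs = Path(str(prefix) + ".docs.txt").read_text(encoding="utf-8").splitlines()
    if not sparse:
        mat = np.asarray(mat.todense())
    return DocumentTermMatrix(docs, np.array(terms, dtype=object), mat)


class TokenCountVectorizer(BaseEstimator, TransformerMixin):
    """Sklearn-style vectorizer over pre-tokenized documents.

    Like :class:`~sklearn.feature_extraction.text.CountVectorizer` with an
    identity analyzer, but with the document-frequency threshold expressed
    the way the screening pipeline uses it: ``fit`` keeps terms whose
    document frequency exceeds ``min_doc_freq``.

    Attributes
    ----------
    vocabulary_ : ndarray of str
        Retained terms in sorted order.
    doc_freq_ : ndarray of int
        Document frequency of each retained term in the fit corpus.
    """

    def __init__(self, min_doc_freq: int = 0, sparse: bool = True):
        self.min_doc_freq = min_doc_freq
        self.sparse = sparse

    def fit(self, X, y=None):
        docs = [CleanDocument(str(i), toks) for i, toks in enumerate(X)]
        dtm = filter_sparse(build_dtm(docs, sparse=True), self.min_doc_freq)
        self.vocabulary_ = dtm.terms
        self.doc_freq_ = dtm.doc_freq
        return self

    def transform(self, X):
        X = list(X)
        idx = {t: j for j, t in enumerate(self.vocabulary_)}
        rows, cols, vals = [], [], []
        for i, toks in enumerate(X):
            seen: dict[int, int] = {}
            for tok in toks:
                j = idx.get(tok)
                if j is not None:
                    seen[j] = seen.get(j, 0) + 1
            for j, c in seen.items():
                rows.append(i)
                cols.append(j)
                vals.append(c)
        mat = sp.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(X), len(self.vocabulary_)),
            dtype=np.int64,
        )
        return mat if self.sparse else np.asarray(mat.todense())

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.vocabulary_, dtype=object)
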