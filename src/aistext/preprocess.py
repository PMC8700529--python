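"""Deterministic cleaning of raw short-text documents into token lists.

Short social-media posts carry markup that is noise for bag-of-words
regression screening: the topic words used to harvest the corpus (which by
construction appear in every document and would dominate any model), URLs,
@mentions, the retweet marker, hashtags and punctuation.  The cleaning
pipeline here strips all of these in a fixed order and tokenizes on
whitespace, so that the same raw text always yields the same token list.

Cleaning order
--------------
1. topic words removed at token boundaries, case-insensitively, including
   their hashtag forms (``#autism`` as well as ``autism``);
2. URL tokens (anything starting with ``http``), @mentions and the retweet
   marker ``RT`` dropped;
3. characters other than ASCII letters, digits, ``#`` and whitespace
   removed (this deletes punctuation in place, as ``tm::removePunctuation``
   does);
4. lowercasing;
5. optionally, tokens starting with ``#`` dropped;
6. tokens containing digits dropped (standalone numbers and leftovers such
   as fragments of URLs), so surviving tokens are letters-only;
7. whitespace tokenization, with an optional plural stemmer applied last.

Stop words are never removed: weak function words receive near-neutral
weights in the downstream screening and are handled there.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RawDocument",
    "CleanDocument",
    "clean_text",
    "clean_document",
    "clean_corpus",
    "light_stem",
    "read_corpus_csv",
    "write_corpus_csv",
    "TextCleaner",
]


@dataclass(frozen=True)
class RawDocument:
    """A raw document plus the per-document metadata used downstream.

    ``outcome_count`` is a non-negative count outcome (e.g. number of
    retweets); ``topic_label`` is a binary topic indicator (1 = document
    belongs to the topic of interest).  Either may be absent when only one
    of the two analyses is run.
    """

    doc_id: str
    text: str
    outcome_count: Optional[int] = None
    topic_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome_count is not None and self.outcome_count < 0:
            raise ValueError(f"outcome_count must be >= 0, got {self.outcome_count}")
        if self.topic_label is not None and self.topic_label not in (0, 1):
            raise ValueError(f"topic_label must be 0 or 1, got {self.topic_label}")


@dataclass(frozen=True)
class CleanDocument:
    """Tokenized, cleaned text; tokens are lowercase and whitespace-free."""

    doc_id: str
    tokens: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))


_NON_RETAINED = re.compile(r"[^A-Za-z0-9#\s]+")
_DIGIT = re.compile(r"\d")


def light_stem(token: str) -> str:
    """Naive plural stemmer: strip one trailing ``s``.

    Tokens of length <= 3 and tokens ending in ``ss``, ``us`` or ``is``
    ("his", "this", "virus", "less") are left alone.  This is deliberately
    much weaker than a Porter stemmer: it only collapses regular plurals
    and 3rd-person verb forms ("takes" -> "take") without mangling short
    function words.
    """
    if len(token) > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def _topic_word_pattern(topic_words: Iterable[str]) -> Optional[re.Pattern]:
    words = sorted({w.lower() for w in topic_words})
    if not words:
        return None
    alts = "|".join(re.escape(w) for w in words)
    # token-boundary match so removing "flu" never touches "influence"
    return re.compile(r"(?<![A-Za-z0-9#])#?(?:%s)(?![A-Za-z0-9])" % alts, re.IGNORECASE)


def clean_text(
    text: str,
    topic_words: Iterable[str] = (),
    drop_hashtags: bool = True,
    stem: bool = False,
) -> list[str]:
    """Clean one raw text into a token list (see module docstring for order).

    Parameters
    ----------
    text : str
        Raw document text; an empty string yields an empty token list.
    topic_words : iterable of str
        Lowercase topic/query words to remove everywhere, including their
        hashtag forms.
    drop_hashtags : bool
        Drop every token beginning with ``#`` (the study default).
    stem : bool
        Apply :func:`light_stem` to each token.  Off by default.
    """
    topic_set = {w.lower() for w in topic_words}
    pat = _topic_word_pattern(topic_set)
    if pat is not None:
        text = pat.sub(" ", text)

    kept = []
    for tok in text.split():
        low = tok.lower()
        if low.startswith("http") or tok.startswith("@") or low == "rt":
            continue
        kept.append(tok)
    text = " ".join(kept)

    text = _NON_RETAINED.sub("", text).lower()

    tokens = []
    for tok in text.split():
        if drop_hashtags and tok.startswith("#"):
            continue
        tok = tok.lstrip("#") if not drop_hashtags else tok
        if not tok or tok == "#":
            continue
        if _DIGIT.search(tok):
            continue
        if stem:
            tok = light_stem(tok)
        if tok.lstrip("#") in topic_set:
            # stemming or char-stripping may re-expose a topic word
            continue
        tokens.append(tok)
    return tokens


def clean_document(
    raw: RawDocument,
    topic_words: Iterable[str] = (),
    drop_hashtags: bool = True,
    stem: bool = False,
) -> CleanDocument:
    return CleanDocument(
        doc_id=raw.doc_id,
        tokens=clean_text(raw.text, topic_words, drop_hashtags, stem),
    )


def clean_corpus(
    raw_docs: Sequence[RawDocument],
    topic_words: Iterable[str] = (),
    drop_hashtags: bool = True,
    stem: bool = False,
) -> list[CleanDocument]:
    """Clean every document in a corpus, preserving order."""
    return [clean_document(r, topic_words, drop_hashtags, stem) for r in raw_docs]


def read_corpus_csv(
    path,
    text_col: str = "text",
    outcome_col: Optional[str] = None,
    label_col: Optional[str] = None,
    id_col: Optional[str] = None,
) -> list[RawDocument]:
    """Read a UTF-8 CSV of documents into :class:`RawDocument` records.

    When ``id_col`` is None, row position is used as the document id.
    Missing outcome/label cells become ``None``.
    """
    df = pd.read_csv(path, encoding="utf-8")
    for col in (text_col, outcome_col, label_col, id_col):
        if col is not None and col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    docs = []
    for pos, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        doc_id = str(rec[id_col]) if id_col else str(pos)
        outcome = None
        if outcome_col is not None and pd.notna(rec[outcome_col]):
            outcome = int(rec[outcome_col])
        label = None
        if label_col is not None and pd.notna(rec[label_col]):
            label = int(rec[label_col])
        text = "" if pd.isna(rec[text_col]) else str(rec[text_col])
        docs.append(RawDocument(doc_id=doc_id, text=text, outcome_count=outcome, topic_label=label))
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError("doc_id values are not unique within the corpus")
    return docs


def write_corpus_csv(docs: Sequence[RawDocument], path) -> None:
    """Write documents to the same CSV schema :func:`read_corpus_csv` reads."""
    pd.DataFrame(
        {
            "doc_id": [d.doc_id for d in docs],
            "text": [d.text for d in docs],
            "outcome_count": [d.outcome_count for d in docs],
            "topic_label": [d.topic_label for d in docs],
        }
    ).to_csv(path, index=False, encoding="utf-8")


class TextCleaner(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer wrapping :func:`clean_text`.

    ``transform`` maps an iterable of raw strings to a list of token lists,
    so the cleaner slots in ahead of :class:`aistext.dtm.TokenCountVectorizer`
    in an sklearn :class:`~sklearn.pipeline.Pipeline`.
    """

    def __init__(self, topic_words=(), drop_hashtags: bool = True, stem: bool = False):
        self.topic_words = topic_words
        self.drop_hashtags = drop_hashtags
        self.stem = stem

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[list[str]]:
        return [clean_text(t, self.topic_words, self.drop_hashtags, self.stem) for t in X]
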