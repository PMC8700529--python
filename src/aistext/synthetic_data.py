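"""Seeded generator of short-text corpora with planted term effects.

Emulates the statistical structure the screening method assumes so every
pipeline stage is testable without external data:

* documents are bags of tokens drawn from a group-specific categorical
  distribution over a shared vocabulary (background terms plus optional
  topic term sets with elevated within-group occurrence weights);
* the count outcome follows a hurdle negative-binomial process driven by
  planted term effects: with eta = beta0 + sum_t logRR_t * freq_t, a
  document is positive with probability expit(gamma0 + gamma1 * eta) and a
  positive count is drawn from the zero-truncated NB with mean exp(eta)
  and dispersion theta — excess zeros and overdispersion by construction;
* the topic label records the generating group.

All randomness flows from the single seed in the spec; a fixed seed gives
a byte-identical corpus.  What the generator does NOT emulate: natural
language word order, hashtags/URLs (cleaning is exercised on hand-written
strings), or cross-term correlation (off by default, as the univariate
screen ignores it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .count_models import TermWeight
from .preprocess import CleanDocument, RawDocument

__all__ = [
    "CorpusSpec",
    "generate_corpus",
    "popularity_spec",
    "two_topic_spec",
    "worked_example_fixture",
]


def _letters(j: int) -> str:
    """Two-letter base-26 suffix: 0 -> 'aa', 27 -> 'ab' reversed scheme."""
    if not 0 <= j < 26 * 26:
        raise ValueError("at most 676 background terms supported")
    return chr(97 + j // 26) + chr(97 + j % 26)


@dataclass(frozen=True)
class CorpusSpec:
    """Generator parameters; defaults are the standard study conditions.

    ``topic_term_sets`` maps term -> relative occurrence weight within the
    owning group (group 1 first); background terms have weight 1.
    ``cross_weight`` is the occurrence weight of a topic term in the other
    group, kept positive so every term appears in both groups.
    ``planted_count_effects`` maps term -> true log relative risk entering
    the linear predictor of the count process.
    """

    n_docs_per_group: tuple = (5000, 0)
    vocabulary_size: int = 12
    doc_length: tuple = (5, 12)
    topic_term_sets: tuple = None  # defaults to ({}, {})
    planted_count_effects: Mapping = field(default_factory=dict)
    gamma0: float = -0.5
    gamma1: float = 0.8
    beta0: float = 0.3
    theta: float = 2.0
    cross_weight: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.topic_term_sets is None:
            object.__setattr__(self, "topic_term_sets", ({}, {}))
        if len(self.topic_term_sets) != 2:
            raise ValueError("topic_term_sets must hold exactly two term sets")
        if len(self.n_docs_per_group) != 2 or min(self.n_docs_per_group) < 0:
            raise ValueError("n_docs_per_group must be two non-negative integers")
        if sum(self.n_docs_per_group) == 0:
            raise ValueError("corpus must contain at least one document")
        if self.vocabulary_size < 0:
            raise ValueError("vocabulary_size must be >= 0")
        lo, hi = self.doc_length
        if lo < 1 or hi < lo:
            raise ValueError("doc_length must satisfy 1 <= min <= max")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.cross_weight < 0:
            raise ValueError("cross_weight must be >= 0")
        for g in self.topic_term_sets:
            if any(w < 0 for w in g.values()):
                raise ValueError("topic term weights must be >= 0")

    def vocabulary(self) -> list:
        # letters-only term names survive the text cleaner unchanged
        background = [f"w{_letters(j)}" for j in range(self.vocabulary_size)]
        topic = sorted(set(self.topic_term_sets[0]) | set(self.topic_term_sets[1]))
        return background + topic


def _group_probs(spec: CorpusSpec, group: int) -> np.ndarray:
    own = spec.topic_term_sets[0] if group == 1 else spec.topic_term_sets[1]
    other = spec.topic_term_sets[1] if group == 1 else spec.topic_term_sets[0]
    weights = []
    for term in spec.vocabulary():
        if term in own:
            weights.append(own[term])
        elif term in other:
            weights.append(spec.cross_weight)
        else:
            weights.append(1.0)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("term occurrence weights sum to zero")
    return w / w.sum()


def _sample_ztnb(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Zero-truncated NB2 draws by rejection; deterministic given rng."""
    out = np.zeros(len(mu), dtype=np.int64)
    pending = np.arange(len(mu))
    for _ in range(10_000):
        if len(pending) == 0:
            return out
        p = theta / (theta + mu[pending])
        draw = rng.negative_binomial(theta, p)
        out[pending] = draw
        pending = pending[np.asarray(draw) == 0]
    raise RuntimeError("zero-truncated NB rejection sampling failed to terminate")


def generate_corpus(spec: CorpusSpec, seed=None) -> list[RawDocument]:
    """Generate the corpus described by ``spec``.

    ``seed`` overrides ``spec.seed`` when given.  Group 1 documents come
    first; doc ids encode group and position.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    vocab = np.array(spec.vocabulary(), dtype=object)
    log_rr = np.array(
        [float(spec.planted_count_effects.get(t, 0.0)) for t in vocab], dtype=float
    )

    docs = []
    for group, n in zip((1, 0), spec.n_docs_per_group):
        if n == 0:
            continue
        probs = _group_probs(spec, group)
        lengths = rng.integers(spec.doc_length[0], spec.doc_length[1] + 1, size=n)
        freqs = rng.multinomial(lengths, probs)  # (n, vocab)
        eta = spec.beta0 + freqs @ log_rr
        p_pos = expit(spec.gamma0 + spec.gamma1 * eta)
        positive = rng.random(n) < p_pos
        counts = np.zeros(n, dtype=np.int64)
        if positive.any():
            counts[positive] = _sample_ztnb(rng, np.exp(eta[positive]), spec.theta)
        for i in range(n):
            tokens = np.repeat(vocab, freqs[i])
            rng.shuffle(tokens)
            docs.append(
                RawDocument(
                    doc_id=f"g{group}-{i:05d}",
                    text=" ".join(tokens),
                    outcome_count=int(counts[i]),
                    topic_label=group,
                )
            )
    return docs


def popularity_spec(
    n_docs: int = 5000,
    planted_term: str = "keyterm",
    planted_log_rr: float = 0.7,
    theta: float = 2.0,
    seed: int = 0,
    vocabulary_size: int = 12,
) -> CorpusSpec:
    """Single-group corpus with one planted popularity-driving term.

    The planted term gets double the background occurrence weight so its
    per-document frequency varies enough to identify the slope.
    """
    return CorpusSpec(
        n_docs_per_group=(n_docs, 0),
        vocabulary_size=vocabulary_size,
        topic_term_sets=({planted_term: 2.0}, {}),
        planted_count_effects={planted_term: planted_log_rr},
        theta=theta,
        cross_weight=0.0,
        seed=seed,
    )


def two_topic_spec(
    n_per_group: int = 1500,
    n_topic_terms: int = 8,
    topic_weight: float = 6.0,
    seed: int = 0,
    vocabulary_size: int = 10,
    control_terms: int = 8,
    control_weight: float = 6.0,
) -> CorpusSpec:
    """Two groups with disjoint high-probability topic term sets.

    Group 1 favours ``asd000..``-style terms, group 0 favours
    ``ctl000..`` terms, over a shared neutral background; every term still
    occurs in both groups (positive cross weight), matching the
    shared-term restriction of the logistic screen.  Raising
    ``control_terms`` while lowering ``control_weight`` produces the
    many-weak-terms control group under which the sum aggregation degrades
    as a classifier.
    """
    g1 = {f"asd{_letters(j)}": topic_weight for j in range(n_topic_terms)}
    g0 = {f"ctl{_letters(j)}": control_weight for j in range(control_terms)}
    return CorpusSpec(
        n_docs_per_group=(n_per_group, n_per_group),
        vocabulary_size=vocabulary_size,
        topic_term_sets=(g1, g0),
        cross_weight=0.5,
        seed=seed,
    )


def worked_example_fixture() -> tuple[CleanDocument, list[TermWeight]]:
    """The printed single-tweet example and its three term weights.

    The cleaned tweet text and the hurdle-model relative risks of its
    three retained vocabulary terms (take, child, see) are stored exactly
    as printed, so aggregation tests are independent of any model fit or
    of the optional stemmer.
    """
    doc = CleanDocument(
        doc_id="worked-example",
        tokens=tuple("father take his child with to see his favorite band coldplay".split()),
    )
    weights = [
        TermWeight("take", 3.6210, source="hurdle_count"),
        TermWeight("child", 4.3122, source="hurdle_count"),
        TermWeight("see", 4.529, source="hurdle_count"),
    ]
    return doc, weights
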