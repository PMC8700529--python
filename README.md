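# aistext

Aggregated influence scores (AIS) for short-text corpora: a regression-based
alternative to black-box text mining for public-health analysts working with
social-media posts (tweets, short messages, EMR snippets).

## The problem and the method

Short-text corpora produce huge, sparse document-term matrices (DTMs): most
terms occur in few documents, and modelling hundreds of term columns at once
is neither feasible nor interpretable for a typical epidemiological analysis.
The AIS method collapses the DTM into a single continuous predictor in three
steps:

1. **Univariate GLM screening.** For every vocabulary term, fit a univariate
   generalized linear model of the outcome on that term's per-document
   frequency `x`:
   - *popularity* (count outcome `y`, e.g. retweets): a hurdle
     negative-binomial model

     ```
     f(y | x) = π₀(x)                                  if y = 0
              = (1 − π₀(x)) · f_NB(y; μ(x), θ) / (1 − f_NB(0; μ(x), θ))   if y > 0
     ```

     with logit π₀ linear in `x` and log μ = β₀ + βx. The term weight is the
     relative risk **RR = exp(β̂)** from the zero-truncated count component
     (Poisson and plain NB2 variants are available for comparison);
   - *topic classification* (binary label): logistic regression
     logit P(Y=1) = β₀ + β₁x, weight **OR = exp(β̂₁)**.
2. **Aggregation.** For a document containing terms `i = 1..k` with
   frequencies `nᵢ` and weights `wᵢ`:

   ```
   AIS-mean   = Σ nᵢwᵢ / Σ nᵢ
   AIS-median = median of the multiset where wᵢ is repeated nᵢ times
   AIS-sum    = Σ nᵢwᵢ
   ```

   Terms without a usable weight are excluded; documents with no weighted
   term get missing scores and are dropped downstream.
3. **Final model.** The AIS becomes the single predictor of the outcome:
   a hurdle NB / NB fit for popularity (diagnosed with hanging rootograms
   and the expected-zeros difference D), or a Kruskal–Wallis test plus ROC
   analysis (trapezoidal AUC, Youden-J cutoff) for classification.

The hurdle model matters because count outcomes from social media are both
overdispersed and zero-heavy: its two parts (a logistic zero/positive model
and a zero-truncated NB for positives) have separable likelihoods, and it
reproduces the observed number of zeros exactly (D = 0 structurally).

## Worked example

Screen a synthetic two-topic corpus (1000 documents per group, disjoint
high-frequency topic vocabularies) and classify by AIS-median:

```python
import numpy as np
from aistext import (
    generate_corpus, two_topic_spec, clean_corpus, build_dtm, filter_sparse,
    screen_terms_logistic, score_corpus, roc_analysis, kruskal_wallis,
)
from aistext.evaluation import drop_missing_ais

docs = generate_corpus(two_topic_spec(n_per_group=1000, seed=42))
dtm = filter_sparse(build_dtm(clean_corpus(docs)), 3)   # drop terms in <= 3 docs
labels = np.array([d.topic_label for d in docs], dtype=float)

weights = screen_terms_logistic(dtm, labels)
scores = score_corpus(dtm, weights)
s, lab, n_dropped = drop_missing_ais(scores["ais_median"].to_numpy(), labels)
stat, p = kruskal_wallis(s, lab)
roc = roc_analysis(s, lab)
```

Output:

```
asdaf: OR = 18.956 (p = 5.32e-74)
asdah: OR = 13.230 (p = 2.57e-77)
asdad: OR = 12.556 (p = 2.65e-78)
documents scored: 2000 (dropped 0 without weighted terms)
Kruskal-Wallis H = 1501.1, p = 0.00e+00
AIS-median AUC = 1.000, cutoff = 1.127, sens = 0.999, spec = 0.992
```

The three largest odds ratios all belong to planted topic-1 terms (`asd…`),
the rank test confirms the two groups' score distributions differ, and a
single cutoff on the AIS-median separates the topics almost perfectly — the
whole DTM has been reduced to one interpretable column.

An sklearn-style interface is available for pipeline composition:
`TextCleaner` → `TokenCountVectorizer` → `AISScorer(model_kind=...)` is a
standard transformer chain, with `AISScorer.fit(X, y)` performing the
screening and `transform(X)` emitting the AIS columns.

## Command line

```bash
aistext simulate --output corpus.csv --seed 1 --n-docs 2000
aistext run-case1 --config case1.yaml     # popularity pipeline
aistext run-case2 --config case2.yaml     # classification pipeline
```

Stage subcommands (`clean`, `dtm`, `screen-count`, `screen-logistic`,
`ais`, `evaluate`) exchange plain CSV/MTX/JSON artifacts, so stages compose
and every run is reproducible from its config and seed.

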