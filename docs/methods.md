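# Methods

## Model and procedure

The package screens each vocabulary term of a document-term matrix (DTM)
with a univariate generalized linear model and aggregates the exponentiated
slopes into per-document scores.

**Count screening (popularity).** For outcome counts `y` and a term's
frequency column `x`, the hurdle negative-binomial model factors into

* a logistic model of the positive-count indicator, logit P(y>0) = γ₀ + γ₁x;
* a zero-truncated NB2 model of y | y>0 with log μ = β₀ + βx and dispersion
  θ (Var = μ + μ²/θ for the untruncated parent).

The two components share no parameters, so they are maximized
independently and the total log-likelihood is the sum — the test suite
checks this structurally. The same single predictor is used in both parts:
the screen is univariate, so there is no separate covariate set for the
zero process. The term weight is RR = exp(β̂) from the count component.
Plain NB2 and two Poisson variants are provided for model comparison. The
"log-log" Poisson variant is implemented as a log-link GLM on the
transformed predictor log(1+x): this keeps the fitted mean positive,
handles the zero frequencies that dominate DTM columns, and is the common
reading of a double-log specification for count GLMs on skewed predictors.

**Logistic screening (classification).** logit P(label=1) = β₀ + β₁x per
term; weight OR = exp(β̂₁). The screened vocabulary is restricted to terms
occurring at least once in each label group; terms confined to one group
sit on the separation boundary and carry no estimable OR. Balancing the
two groups' sample sizes is the caller's responsibility — the library
never resamples.

**Aggregation.** With per-document frequencies nᵢ and weights wᵢ:
AIS-mean = Σnᵢwᵢ/Σnᵢ, AIS-sum = Σnᵢwᵢ, and AIS-median = the median of the
multiset in which wᵢ appears nᵢ times (odd total frequency → middle
element; even → mean of the two middle elements). The multiset
construction subsumes the order-statistic notation used when all nᵢ = 1;
ties among equal weights cannot affect the value. Terms with absent
weights are silently excluded; a document with no weighted term has
missing scores and is dropped before any downstream fit, with the dropped
count logged and reported. Mean and median are bounded by the smallest and
largest weight used; the sum is not, which is why it degrades as a
classification score when one group's documents simply contain more
weighted terms.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` (`filter_sparse`, CLI `-k`) | 500 | drop terms with document frequency ≤ k; 500 matches the reference corpus scale (~55k documents) and should be scaled down for smaller corpora (tests use 0–3) |
| `model_kind` | `hurdle_nb` | screening/final count model; `negbin`, `poisson_loglinear`, `poisson_loglog` for comparison |
| `drop_hashtags` | on | hashtag tokens are dropped after character filtering |
| `stem` | off | naive plural stemmer (strips one trailing "s", except after ss/us/is or in ≤3-letter words); off by default because the cleaning contract is defined without stemming |
| θ cap | 1e8 | NB dispersion cap; equidispersed data drive θ → ∞, and the capped model is numerically the Poisson limit. The boundary is declared when the fitted NB2 α = 1/θ falls below 1e−6, far below any plausible standard error |

## Numerical choices

* Zero-truncated NB log-pmf: log f(y) − log(1 − f(0)) with
  log f(0) = −θ·log(1+μ/θ) and the complement via `log1p`/`expm1` branches,
  so neither f(0)→0 (large μ) nor f(0)→1 (tiny μ) loses precision; verified
  against exact rational arithmetic.
* Truncated-NB maximization: BFGS on (β₀, β, log θ) starting from a Poisson
  GLM on the positive counts, with a Nelder–Mead fallback if BFGS reports
  non-convergence; standard errors from the numerical observed-information
  inverse, p-values Wald. Linear predictors are clipped at ±30 during
  optimization to keep early iterations finite.
* Poisson/logistic/NB2 fits delegate to statsmodels (IRLS / Newton-type ML).
* No multiple-testing correction is applied across terms — the weights feed
  an aggregation, not a discovery list.
* Constant predictors (a term appearing with identical frequency everywhere,
  or a constant AIS) leave the slope inestimable: fits return the
  intercept-only model flagged `converged=False`, and screening records an
  absent weight rather than raising.
* Complete separation in a logistic fit is caught and flagged
  (`converged=False`, absent OR) after a bounded number of BFGS steps.
* ROC: empirical curve over all distinct cutoffs; AUC by trapezoid, equal to
  Mann–Whitney with half credit for ties. The reported cutoff maximizes
  Youden J = sens + spec − 1, ties broken toward the smaller cutoff (a single
  conventional rule, since several cutoffs can attain the maximum). Scores
  oriented the "wrong" way are reported as computed (AUC < 0.5) unless
  `direction="auto"` is requested, which picks and reports the orientation.
* Expected-zeros difference D = Σᵢ P_fit(yᵢ=0) − #{yᵢ=0}: negative when the
  model under-predicts zeros. The hurdle's logistic zero component satisfies
  its score equations, so its fitted zero probabilities sum to the observed
  zero count and D = 0 exactly.
* Rootograms are hanging, square-root scale, data-only (count, observed,
  expected columns); plotting is left to the caller.
* Kruskal–Wallis uses the tie-corrected statistic with a χ² p-value (1 df
  for two groups); for two groups this is equivalent to the Wilcoxon
  rank-sum test up to the form of the statistic.

## Synthetic corpora

The generator emulates the data structure the method assumes: bags of
tokens drawn from group-specific categorical distributions over a shared
vocabulary, and a count outcome from the hurdle NB process
η = β₀ + Σ logRRₜ·freqₜ, P(positive) = expit(γ₀ + γ₁η), positives from the
zero-truncated NB(e^η, θ). Defaults are γ₀ = −0.5, γ₁ = 0.8, β₀ = 0.3,
θ = 2 — a regime with roughly 30–50 % zeros and variance far above the
mean, matching the zero-heavy overdispersed setting the method targets.
Convenience constructors provide the two standard designs: a single-group
corpus with one planted term (log-RR 0.7, double background occurrence
weight, 12 background terms, document lengths uniform on 5–12 — short-text
scale) and a two-group corpus with disjoint high-weight topic vocabularies
whose terms still occur in both groups.

What the generator does **not** emulate: word order and syntax, realistic
token frequency (Zipf) profiles, hashtags/URLs/mentions (cleaning is
exercised on hand-written strings instead), or correlation between term
occurrences. Passing tests therefore demonstrate correctness of the
estimators and aggregation under the assumed generating process, not
robustness to the messiness of real social-media text.

Problem sizes in the test suite were chosen to make the statistical checks
sharp but cheap: parameter-recovery and calibration checks use n = 5000
(10 seeds), model-ordering checks n = 2000, structural identities n ≤ 1500.

## Design notes and limitations

* The worked-example fixture stores the cleaned reference tweet and its
  three published weights as printed constants, so aggregation tests do not
  depend on any fitted model or on the optional stemmer (which exists only
  because the reference cleaning maps "takes" → "take").
* Tokens containing digits are dropped entirely (not just standalone
  numbers): the cleaning contract promises letters-only tokens, and mixed
  alphanumeric fragments in short texts are mostly codes and truncated URLs.
* "Sparse term" means low *document* frequency (number of documents
  containing the term), not low total occurrence count.
* Screening fits are independent per term; nothing corrects for the
  correlation between term columns, which is a stated assumption of the
  method, not an oversight.
* Scores are evaluated in-sample, as the method prescribes; no
  cross-validation or AUC confidence intervals are provided.
* Multinomial (>2 topic) classification and multi-score extensions are out
  of scope.
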