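# Methods

This note records the model, its parameters and the design choices made
where the procedure was genuinely open, so that results can be read —
and challenged — without reverse-engineering the code.

## Corpus model and tokenization

The unit of analysis is an *abstract record* (identifier, title, body);
title and body concatenated form the tokenization unit.  Tokens are
maximal runs between whitespace, comma and semicolon; leading and
trailing sentence punctuation (`.()[]{}:"'?!`) is stripped, case is
folded, and internal hyphens and digits are preserved so that
expressions like `st-segment`, `5-ht3` and `pge2` survive as single
tokens.  Stop words are removed from the bag (a packaged list of ~130
English function words, overridable per run; the list is purely
grammatical so that content filtering is left to the statistical
filters).  Each abstract yields an unordered *set* of tokens for
document-frequency purposes and a multiset for term-frequency purposes.

Drug–abstract matching is defined as a contiguous, case-insensitive
token-sequence match of the drug's name in the abstract's pre-stop-word
token stream.  This is the reproducible offline analogue of a keyword
query against a literature database; it makes no claim of equivalence
with server-side query expansion (automatic term mapping), which cannot
be reproduced without the live service.  Multi-word generic names
("valproic acid") must match as a contiguous sequence.  With synonyms
enabled, trade names normalized by `normalize_trade_name` — trailing
strength tokens (`100`, `12.5mg`, `40%`) and a packaged, editable
formulation-suffix vocabulary (`SR`, `syrup`, `forte`, …) stripped —
match as well; the matched set with synonyms is by construction a
superset of the set without.

Stemming, when enabled, applies the Porter (1980) suffix-stripping
algorithm, implemented in `_porter.py` and verified against the
algorithm's published worked examples.  Stemming is a many-to-one token
map, so it can only shrink vocabularies.

## Frequency measures

For drug *d* with *N(d)* matched abstracts and total token count
*T(d)*:

| measure | definition | range |
|---|---|---|
| cdf | df(w,d) / N(d) | [0, 1] |
| ctf | Σᵢ nᵢ(w) / T(d) | [0, 1] |
| ctf-icdf | ctf(w,d) · ln(N(d) / df(w,d)) | [0, ∞) |

The ctf normalization by *T(d)* is chosen so that, like cdf, the score
is comparable across drugs with very different corpus sizes; an
unnormalized count would correlate trivially with *N(d)* and be removed
wholesale by the common-token filter.  The icdf logarithm is natural;
tokens absent from a drug's abstracts are absent from its score map
(implicitly zero).  A token present in every abstract of a drug has
ctf-icdf exactly 0 — the measure deliberately disagrees with cdf (which
is 1) on saturated tokens.  Scores are kept at full double precision;
ranking is threshold-based and sensitive to ties, so no rounding occurs
before modeling.

## Vocabulary filters

*Rare*: a token is removed when its abstract count summed over all
drugs' matched sets is below 2.  The sum is global, not per-drug — a
per-drug reading would empty the vocabulary.

*Common*: for each token, Pearson r is computed between its score
vector across the full drug universe (zeros included for drugs lacking
it) and the abstract counts *N(d)*; the token is removed when
r² > 0.33.  Tokens with (numerically) zero variance are retained: a
constant score is no evidence of corpus-size dependence, and r is
undefined there.  With fewer than three drugs the filter is a no-op
with a warning.  For ctf and ctf-icdf runs the identical procedure is
applied with the respective measure substituted for cdf.

Both filters are monotone: raising the rare threshold or lowering the
r² cutoff can only shrink the surviving vocabulary.

## Token ranking

A token's discriminative power for a characteristic (positive drug set
**C** within universe **D**) is the area under the ROC curve traced by
sweeping a threshold down through all observed score values, with
TPR(t) and FPR(t) the fractions of positives and negatives scoring ≥ t.
This equals the normalized Mann–Whitney statistic with half credit for
tied pairs, which is how it is computed (rank-sum over the score
vector, drugs missing a score contributing 0).  The statistic is
invariant under strictly increasing transforms of the scores.  Tokens
are ordered by descending AUC with a lexicographic tie-break — the tie
policy is arbitrary but must be deterministic across platforms.  The
default feature count is the top 20 tokens; the count is configurable
but no sweep is performed.

## Classifiers

Four families operate on the drugs × top-20 token-score table:

* **nb** — Gaussian naive Bayes.  Variances are floored via a smoothing
  term of 10⁻⁶ × (largest feature variance) so constant columns
  survive; with scores in [0, 1] this floors variances near 10⁻⁶.
* **ibk** — k-nearest neighbour with inverse-distance weighting.  k is
  selected on the training rows by an internal stratified
  cross-validated AUC search over k = 1…10 (folds = min(5, class
  counts); ties go to the smaller k); the chosen k is recorded in the
  model metadata.
* **svm_linear / svm_rbf** — C = 1; RBF gamma = 1 / (n_features ×
  feature variance).  cdf features are used as-is (already bounded);
  for ctf and ctf-icdf the SVMs standardize columns and store the
  scaler with the model.

The ranking score is the positive-class probability for nb/ibk and the
decision value for the SVMs.  Both are valid ROC inputs; decision
values avoid the extra stochastic calibration fit that SVM
probabilities would require, and the score kind is stored with the
model and can be overridden at scoring time.  Training is deterministic
given the seed; models serialize to a single archive with algorithm,
hyperparameters, token list and seed embedded, and reload to
bit-identical scores.

## Cross-validation protocol

Label → randomise → stratify: with |C| ≥ 10 positives, five independent
shuffles each split into 10 stratified folds (per-fold positive counts
differ by at most one); with 2 ≤ |C| < 10, one cycle of |C| folds so
every test fold holds exactly one positive.  Characteristics with
fewer than two positives are refused with an explicit non-evaluable
status rather than evaluated by an invented scheme.  Per-cycle shuffle
seeds derive from the master seed by a fixed counter scheme
(`seed·100 + cycle`) and are recorded in the output.

Inside **each** training split the full selection pipeline — rare
filter, common filter, ROC ranking, top-20 — is recomputed from the
training drugs only.  The common filter does not use labels, but it is
still recomputed per split for strict hygiene; the cost is negligible.
Feature *values* for test drugs are per-drug statistics of each drug's
own abstracts and carry no cross-drug information.

Aggregation: each cycle's test-fold scores are pooled into one ROC
AUC, and the reported AUC is the arithmetic mean over cycles (5 values,
or 1 for reduced-fold runs).  Per-fold AUCs with a single positive are
degenerate, which is why pooling is the aggregation unit; per-fold
AUCs are still logged where defined.  The standard error uses the
Hanley–McNeil closed form at n_pos = |C|, n_neg = |D\C|
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)), and a characteristic is flagged
significant when mean AUC − 1.645·SE > 0.5 (one-sided, α = 0.05).
A deliberate bug mode (`leak_features=True`) selects features on all
drugs including test folds; it exists solely to quantify the benefit of
the per-fold guard and inflates null-data AUC essentially always.

## Synthetic corpus generator

The generator emulates the statistical structure the method assumes —
drug-conditioned document frequencies with characteristic-linked
enrichment — not language.  Defaults (the study conditions): 200 drugs;
abstracts per drug log-normal with median 30 (σ = 0.6, minimum 5) —
enough abstracts to estimate cdfs meaningfully while keeping the full
pipeline fast on one CPU; abstract length Poisson with mean 80 over a
1,500-token Zipf-weighted background vocabulary (exponent 1.1 — heavy
tails exercise the filters realistically); each abstract contains its
drug's name, guaranteeing the index match.  Planted structure, all
recorded in a truth manifest:

* 20 *rare* tokens with exactly one global occurrence (configurations
  requesting ≥ 2 occurrences are rejected as infeasible for the rare
  filter);
* 20 *common* tokens with per-abstract probability
  0.15 + 0.7·(N(d) − min)/(max − min), linear in N(d), so their cdf
  correlates with corpus size well above the r² cutoff;
* per characteristic, 20 *signal* tokens occurring with probability
  0.6 per positive-drug abstract vs 0.05 per negative-drug abstract,
  and 20 positive drugs — a strong, unambiguous signal whose expected
  cdf equals the occurrence probability;
* a trade-name synonym per drug used in ~5% extra abstracts, so
  synonym-enabled matching is a strict superset.

Null label sets (`null_characteristic`) draw positives uniformly at
random with no effect on any token distribution.

What passing tests on this generator do **not** show: robustness to
real linguistic variation (morphology, negation, multi-word concepts),
publication bias, heterogeneous abstract lengths per journal, or query
expansion effects — the generator's tokens are exchangeable within
their roles, real text's are not.

## Numerical and degenerate-input choices

* AUC needs at least one positive and one negative; otherwise raised.
* Drugs with zero matched abstracts stay in the universe with empty
  score maps (they contribute zeros; dropping them would silently
  shrink **D**).
* Zero-variance guard in the common filter: variance ≤ 10⁻¹² is
  treated as constant (retained).
* SVM decision values under row permutation agree only to the solver's
  stopping tolerance (~10⁻³); tests assert at that precision.
* All randomness flows from explicit seeds; generated corpora, fold
  plans and result files are byte-identical across reruns with the
  same master seed.

## Known limitations

The null-calibration significance flag is mildly anticonservative on
small corpora: a random positive set can by chance be genuinely
separable corpus-wide by the best of ~1,400 candidate tokens (the
maximum of that many correlated AUC statistics, each with null SD
≈ √((n₁+n₂+1)/(12·n₁·n₂)) ≈ 0.07 at 20/180, reaches ≈ 0.70), and
leakage-free cross-validation then honestly reports an elevated AUC
that the Hanley–McNeil test flags.  Expect the one-sided flag to fire
on roughly 5–15% of null characteristics at these sizes rather than
the nominal 5%.  This is a property of screening with many candidate
features on a fixed corpus, not of information leakage — the paired
leaky/clean comparison separates the two cleanly.
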