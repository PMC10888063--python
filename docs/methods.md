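# Methods

## The index

CADI summarises, per region and calendar year, how intensely a population
searches for words related to anxiety and depression. Three modelling
commitments define it:

* **Relevance weighting.** Each dictionary word contributes in proportion
  to φ(i,y) = α(i)·β(i,y): a word matters more when it is semantically
  close to the targets (α from CBOW cosine similarity, clipped to [0, 1])
  and nationally salient that year (β, the yearly mean national trend).
  Weights w(i,y) = φ/Σφ are renormalised within each year, so the index is
  always a convex combination of per-word scores.
* **Efficacy-coefficient scaling.** Each word's population-adjusted
  regional trend γ̄ = γ/δ is min–max normalised across regions within the
  (word, year) cell and mapped onto [100 − τ, 100]. τ (default 40,
  admissible (0, 100]) fixes the index's dynamic range to [60, 100]. The
  min and max include the region being scored, so the extremes are
  attained exactly. The scaling makes the index invariant to any positive
  affine transformation of a word's trend scale — platform-specific units
  of the trend provider cannot leak into cross-region comparisons.
* **Penetration adjustment.** CADI~(r,y) = CADI(r,y)·π(y)/π(y−1) removes
  the mechanical year-over-year growth of the Internet-using population.
  The ratio is adjacent-year exactly as stated, not compounded from a base
  year; the first year of a span has no predecessor and uses ratio 1.

Numerical choices: a word whose trend does not separate regions at all
(max = min) is scored at the midpoint 100 − τ/2, keeping its weight active
while conveying no regional information — dropping it would silently
renormalise the other weights. An unbalanced panel (a word observed in
some regions only) is an error, not an imputation.

## Dictionary construction

Documents shorter than 15 characters are removed (a document with exactly
15 is kept); an optional user predicate stands in for manual topical
screening. Candidate words must appear at least once as a noun or
adjective, have ≥ 2 characters, not be stopwords, and reach a minimum
corpus frequency (default 5 — an explicit parameter because no canonical
cutoff exists). Tokenisation is pluggable: the default parses
`surface/POS` tagged tokens; a jieba adapter (lazy import) serves real
Chinese text.

Embeddings are trained with an in-package CBOW/negative-sampling trainer
(numpy SGD): dimension 100, window 5, 20 epochs, minimum count 2, 5
negatives, linearly decayed learning rate, single-threaded and
deterministic under the seed. Relevance is the mean cosine similarity of
a word's input vector to the two target vectors, clipped to [0, 1] so
downstream weights stay nonnegative; averaging over the two targets (vs a
maximum or a merged token) is a design choice. The targets themselves are
excluded from the dictionary — they are the probes, not members.

## Validation and association

Weighted prevalence per region is Σw·y/Σw over survey respondents
(records with a missing indicator dropped listwise). The correlation
suite reports Pearson, Kendall τ-b (tie-corrected) and Spearman
coefficients; with n ≤ 9 paired regions the two-sided p-values are exact,
enumerating all n! permutations; otherwise asymptotic. Zero variance
leaves a coefficient undefined (NaN with a warning), never 0.

The regression layer pools region-years and fits, on a design of
intercept + eight covariates + year dummies (earliest year as reference):
ordinary least squares with conventional standard errors, and quantile
regression at q = 0.5 minimising the check loss. QRM standard errors are
case-resampling bootstrap (500 replicates, seeded); p-values are normal
approximations. An intercept-only median regression is solved directly as
the sample quantile with linear interpolation, which gives the even-n
midpoint convention exactly — iterative solvers only guarantee a point in
the minimising interval. Subgroups split regions at the mean per-capita
GDP over all rows; a region is assigned wholly by its own multi-year
mean, ties to the high group. Published six-year applications of this
design list only four year dummies where reference coding implies five;
this package always emits one dummy per non-reference year and leaves any
column dropping to the collinearity check, which names dependent columns
rather than silently removing them.

## The synthetic scenario

One latent severity s(r,y) ties all six generated streams together:
covariates (iid standard normal) generate s linearly — defaults IE −1,
ACP +1, all other effects 0, residual sd = `noise_sd` (default 0.1) — a
clear planted signal against unit-variance covariates; trends are
base(i) + λ·s·relevance(i) + noise truncated at 0 (λ = 1; planted words
carry relevance 0.8, background words 0.05, i.e. nearly irrelevant but
not silent); survey respondents report a disorder with logistic
probability in standardised s around a 12% base prevalence, with
lognormal sampling weights. The corpus is built from tagged pseudo-tokens
(so the POS/length filters are testable without any segmenter): emotional
documents (half of the corpus) contain the target words, skew their
content toward planted words in proportion to the co-occurrence excess
(default 0.8), and additionally place a planted word adjacent to each
target occurrence at that rate; at excess 0 planted and background words
are exchangeable by construction. The default scale is 31 regions over
2016–2021 (186 region-years), 20 words, 2000 documents.

Two deliberate simplifications: regional populations are equal within a
year by default (a heterogeneity knob exists), because the per-capita
adjustment γ/δ with region-specific δ would otherwise decouple the
trend ranking from the severity ranking and make end-to-end rank recovery
unassertable; and the national trend is defined as the population-weighted
mean of the regional ones, keeping the two streams internally consistent.
The generator does not attempt realistic language, query seasonality,
platform effects, or shocks; passing tests therefore demonstrate that the
pipeline recovers structure it is designed to recover, not that the index
is valid on real search data.

Simulation-heavy checks run on reduced trend sampling — monthly for the
rank-recovery study, yearly for the regression-size study (300 panels) —
since noise-free recovery is frequency-invariant and coarser sampling
averages away less noise, i.e. it is the conservative direction.

## Known limitations

* α from a small CBOW corpus is noisy; the [0,1] clip hides anti-correlated
  words rather than down-weighting them.
* The index is purely cross-sectionally normalised within (word, year);
  it orders regions within a year but level comparisons across years rest
  entirely on the penetration adjustment.
* QRM bootstrap p-values are normal approximations; with small subgroups
  they are optimistic.
* The survey validation treats one weight column as the whole design;
  stratification and clustering effects are out of scope.
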