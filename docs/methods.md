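# Methods

This note documents the statistical procedures implemented in
`patientpulse`, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Spam filtering

Accounts dedicated to news or advertisement reposting are detected by
duplicate counting: a post is a *duplicate* when its normalized text
(lowercased, punctuation stripped, whitespace collapsed) exactly equals
an earlier post by the same author, counted across the whole corpus.
Near-duplicate (edit-distance) matching was considered and rejected:
exact matching keeps every flagged account auditable by inspection, and
the duplicate behavior of repost bots is literal copying. The default
tolerance is `max_duplicates = 1` — a single repost is tolerated, two or
more repeats flag the account. The second heuristic, a ranked list of
the most prolific authors, is deliberately left as a human-in-the-loop
report: deciding whether a prolific account belongs to a patient is an
expert judgement we do not automate.

## Subtopic tagging and term selection

Tokenization lowercases, splits on whitespace and strips surrounding
punctuation while preserving internal hyphens and apostrophes. Matching
is token-exact with no stemming, because the shipped dictionaries mix
stems and inflected forms ("bleed", "complications"); stemming would
silently change what the printed word lists mean. The cost is that
"bleeding" does not match the entry "bleed" — a documented limitation.
Two-word entries ("health care", "reaction allergy") are matched as
adjacent token bigrams. Terms are selected at a minimum corpus count of
50 occurrences (inclusive), configurable.

The Gini index G(w) = Σᵢ pᵢ(w)² is implemented over the closed,
attainable range [1/k, 1]: the uniform vector attains 1/k and a
degenerate vector attains 1, so the bounds are checked as achievable
values rather than an open interval. Classes default to the four
subtopics; k is configurable.

## Sentiment scoring

The scorer counts token hits in positive and negative word lists and
labels each post by the sign of the difference; ties and lexicon-free
posts are neutral. This transparent word-count scorer is the package's
sentiment stage by design — the lexicon is a plain-text plug-in point,
so richer resources (e.g. a subjectivity-clue lexicon) can be dropped in
without code changes. Negation scope ("not better") is not modeled in
this version; on real text this biases polar posts toward the wrong
sign at a rate the noise parameter of the generator can emulate, and on
such corpora classifier accuracy degrades linearly with the noise rate
(tested at three binomial standard errors).

## Term–sentiment association

Daily aggregation is the analysis granularity: for each candidate term,
the predictor series is the number of posts mentioning the term per
calendar day (zero-filled over the full corpus range), and the response
series are the daily shares of positive and of negative posts. The
Granger test fits, by ordinary least squares, the restricted model
y_t ~ 1 + y_{t−1..t−L} and the unrestricted model adding x_{t−1..t−L},
and refers F = ((RSS_r − RSS_u)/L) / (RSS_u/(n_eff − 2L − 1)) to
F(L, n_eff − 2L − 1), with n_eff = n − L.

Open design points and their resolutions:

- **Lag order** — a single user-specified lag (default 1 day) rather
  than information-criterion selection, keeping the test a single
  pre-registered comparison; a multi-lag scan is available and applies a
  Bonferroni correction across the scanned lags.
- **Two response series** — each term is tested against the positive
  and the negative share separately and ranked by the smaller p-value,
  so a term coupled to either polarity is surfaced and both raw
  p-values are reported.
- **Multiplicity across terms** — raw p-values by default (candidate
  lists are short and hypothesis-driven); an optional
  Benjamini–Hochberg correction across terms can be enabled.
- **Degenerate candidates** — a term absent from the corpus yields a
  constant mention series; the test returns a flagged, nonsignificant
  result (F = 0, p = 1) instead of aborting a batch ranking.
- **Stationarity** — shares and counts are bounded series; no
  differencing or prewhitening is applied. The Monte-Carlo calibration
  below is the empirical check that the test holds its nominal level on
  the white-noise null used by the generator.

The implementation is validated three ways: against an explicit
normal-equation least-squares oracle (agreement to 1e-6 relative on
small instances), against an established econometrics library's
sum-of-squares F-test, and by Monte-Carlo calibration — on independent
white-noise pairs (n = 500, 200 replicates) the empirical rejection rate
at α = 0.05 must lie in [0.01, 0.11], and on coupled series
(y_t = 0.8·x_{t−1} + ε, n = 500) p < 0.01 in at least 95 of 100 runs.

## Rater agreement

Two raters score each post on the ordered 3-point scale −1/0/+1. The
k×k confusion matrix is summarized by weighted Cohen's kappa
κ = (P_o(w) − P_e(w))/(1 − P_e(w)) with quadratic ("square") weights
w_ij = 1 − ((i−j)/(k−1))²: unit diagonal, 0.75 for adjacent categories,
0 for the extremes at k = 3. P_o(w) = Σ w_ij n_ij / N is the weighted
observed agreement; P_e(w) = Σ w_ij r_i c_j / N² the chance term from
the marginals. The "square weighted" reading of the agreement statistic
is forced by the arithmetic of the reference contingency table this
stage is validated on: the weighted-agreement numerator 228 decomposes
as 177·1 + 68·0.75 + 16·0 only under quadratic weights, and the
resulting kappa is exactly 5261/8132 = 0.6470 at four decimals.

Numerical choices: with integer cells all quantities are rational, so
the computation uses exact fractions end to end and rounds only for
display (4 decimals for kappa); marginal percentages round half-up to
integers. The weighted observed agreement (87.36% on the reference
table) is reported alongside raw percent agreement (67.8%), clearly
labeled, since the two are easily confused. Likert levels are treated
as equally spaced scores. Verbal interpretation uses the Landis–Koch
bands (<0 poor, ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80
substantial, ≤1 almost perfect). Kappa confidence intervals and
multi-rater generalizations are out of scope.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes
in a scraped patient-community corpus, with full ground truth:

- **Accounts** — `n_accounts` (default 100) authors post counts drawn
  from a Poisson distribution (mean 20, at least one post each) at
  uniformly random times over the window October 2011 – August 2015,
  the period the emulated corpus covers; platform is Facebook with
  probability 0.7. Real corpora have no published per-account activity
  statistics, so these defaults are conventional, not calibrated.
- **Spam** — a `spam_fraction` (default 0.1) of accounts post a fixed
  advertisement text; the first two posts of each spam account are
  always identical, guaranteeing a duplicate pair, and later posts
  repeat it with probability 0.6.
- **Subtopics** — each genuine post receives, per dictionary, one
  uniformly chosen term with probability `subtopic_term_rate`
  (default 0.3); injected occurrences are recorded exactly.
- **Sentiment** — labels are drawn from `sentiment_mix`, default
  36/27/37 positive/neutral/negative, the mix observed among the
  drug-opinion posts this corpus emulates. A post labeled ±1 carries
  strictly more lexicon words of that polarity; a `polarity_noise` rate
  renders a post's wording as a different label while the ground-truth
  label is kept, emulating scorer errors.
- **Coupling** — with `coupling_beta` ≠ 0, the standardized mention
  count of `coupled_term` on day t multiplies the positive (and divides
  the negative) mix weight of day t + lag posts by exp(β·z), planting a
  lag-1 Granger signal at the daily-aggregate level, which is where the
  association stage operates.
- **Closed vocabulary** — texts are assembled from dictionary terms,
  lexicon words, neutral fillers disjoint from both, and a unique
  serial token that makes genuine texts pairwise distinct. Every
  downstream count is therefore exactly recoverable.

What passing these tests shows: the pipeline's bookkeeping, matching
rules and statistics are correct on corpora satisfying its assumptions.
What it does not show: robustness to natural language (negation,
misspelling, sarcasm, code-switching), to spam that paraphrases instead
of copying, or to platform effects — none of which the generator
attempts to mimic.

## Problem sizes

The test suite and the acceptance script run on deliberately scaled
corpora — tens to hundreds of accounts, one- to four-year windows,
thousands of posts — and on 100–200-replicate Monte-Carlo batches;
these sizes give the calibration checks binomial standard errors of a
few percent while keeping a full run under a minute on one core. The
agreement stage runs on the full 261-pair expert fixture, which is the
complete rated dataset, not a sample.
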