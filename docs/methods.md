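# Methods

## Problem setting

Evidence synthesis for medical guidelines starts with title-abstract
screening: two clinicians independently label every record a literature
search returned as relevant or irrelevant, a research methodologist
re-evaluates the clinicians' inclusions, and a final full-text pass fixes
the definitive inclusion set. Screening-prioritization tools reorder the
unread pool with a classifier that is retrained after every human label,
so likely-relevant records are read first. How much work that saves
depends on the quality of the human labels: clinician over-inclusions
that a methodologist later relabels irrelevant are *noisy labels*, and a
model asked to reach 95% recall of a noisy label set must hunt down
records that carry no textual signal of relevance.

`screensim` simulates this workflow end to end on labeled corpora
(real ones read from CSV/RIS, or synthetic ones with controlled noise)
and measures how screening performance changes across the three
adjudication stages.

## Active-learning simulation

One simulated run works exactly like a prioritized screening session:

1. **Prior knowledge.** One relevant record and ten irrelevant records
   (the irrelevant set drawn once per dataset and shared across runs)
   form the initial training data. A batch of runs varies the relevant
   prior — by default one run per relevant record — to average out the
   influence of the starting paper. A stage with fewer than two relevant
   records is infeasible (one is needed for training, one as a target)
   and is reported as NA rather than simulated.
2. **Features.** TF-IDF weighted unigrams (lowercased tokens of ≥ 2 word
   characters, smoothed idf `ln((1+D)/(1+df)) + 1`, L2-normalized rows),
   fit once on the full corpus before the run. The pool's text is visible
   to a screener from the start, so there is no information leak in
   fitting the vocabulary up front; it also keeps feature columns stable
   across iterations.
3. **Classifier.** Multinomial naive Bayes with additive smoothing
   (default constant 3.822, matching the documented default of the
   reference screening tooling; configurable). Because prevalence is
   1–25%, relevant training records are up-weighted by
   `balance_ratio × n_irrelevant / n_relevant` so the effective class
   shares stay balanced as the labeled set grows; without this the
   posterior collapses toward the majority class.
4. **Query rule.** Strict argmax of the posterior relevance score. Ties
   are broken deterministically by an initial seeded shuffle of the pool
   (lowest post-shuffle index wins), so a corpus of identical texts is
   screened in seeded-shuffle order and every trace is bitwise
   reproducible from (corpus, prior set, config).
5. **Loop.** The top-scoring record's true stage label is revealed, the
   model retrains (every `retrain_every` labels; default 1), and the loop
   continues until the pool is exhausted. There is no stopping rule: the
   metrics need the complete ordering.

The result of a run is a `ScreeningTrace`: the permutation of the
non-prior pool in screening order with true labels. Priors are excluded
from every metric numerator and denominator.

## Outcome measures

With `N` the pool size, `R` the number of relevant pool records and
`s[k]` the number of relevant records among the first `k` screened:

- **Recall curve** — `s[k]` as a function of `k`.
- **WSS@95** — with `m = ceil(0.95·R)` and `n*` the smallest `k` with
  `s[k] ≥ m`: `100 × ((N − n*)/N − 0.05)`. This is the standard
  definition: work saved at 95% recall, net of the 5% allowance. Best
  case `100×(0.95 − m/N)`, worst case −5. `ceil` means that with R = 5
  relevant records, 95% recall requires all 5.
- **RRF@10** — `100 × s[ceil(0.10·N)] / R`: percent of relevant records
  found after screening 10% of the pool.
- **TD / ATD** — a relevant record found at position `k` has time to
  discovery `k/N`; ATD is the mean TD pooled over records and runs,
  reported both as a fraction and as an equivalent abstract count
  (fraction × mean pool size). Records with high mean TD are
  hard-to-find and flag candidate noisy labels.

Under a uniform-random screening order the position of the `m`-th
relevant record has expectation `m(N+1)/(R+1)` (negative
hypergeometric), giving a closed-form random-reading baseline used in
the tests and the acceptance script.

Multi-run aggregation computes each metric per run, then the mean and
sample SD over runs; cross-dataset totals are unweighted means and SDs
of the per-dataset means, with infeasible stages excluded and their
count reported.

## Rater agreement

Cohen's κ is computed from the 2×2 contingency of jointly labeled pairs
(`p_o` observed, `p_e` chance agreement from the marginals,
`κ = (p_o − p_e)/(1 − p_e)`). Pairs with a missing label on either side
are dropped listwise and counted. When both raters are constant, κ is
undefined and reported as an explicit NA/error carrying the contingency
— degenerate agreement is reported, never fabricated as 0.

## Synthetic corpus generator

The generator emulates the statistical structure of guideline-screening
datasets — it is the test bed, not a stand-in for any particular real
corpus:

- **Text.** A two-class unigram multinomial mixture over pseudo-words.
  The vocabulary splits into a relevant-signal third, an
  irrelevant-signal third and a shared remainder; each class mixes a
  uniform distribution over its signal block (weight `s/(1+s)` for
  signal strength `s`) with a uniform distribution over the whole
  vocabulary. `s = 0` makes classes indistinguishable; `s = inf` gives
  disjoint vocabularies (perfect separability). Titles are 6 tokens,
  abstracts Poisson-length (mean `doc_length`, default 60). No grammar
  is simulated: the downstream featurizer is bag-of-words, so unigram
  statistics are the only thing that matters.
- **Truth and raters.** Truth is Bernoulli(prevalence), default 0.05 on
  400 records. Each rater flips relevant→irrelevant with probability
  `rater_fn` (default 0.10, the conventional human misclassification
  rate) and irrelevant→relevant with `rater_fp` (default 0.03). With
  probability `rater_correlation` a record's two flip decisions share
  one latent uniform draw; this yields the closed form
  `P(both flip | class) = ρp + (1−ρ)p²` used by `expected_kappa` and by
  `calibrate_to_kappa`, which inverts it to find `(ρ, fn)` for a target
  κ (raising an error with the attainable range when the target is out
  of reach — e.g. κ = 1 with any noise, or negative κ, which would need
  anti-correlated raters). The defaults model independently screening
  raters (ρ = 0) and imply κ ≈ 0.53, matching the low-to-moderate
  agreement (mean κ ≈ 0.5) of the screening datasets this emulates.
- **Stages.** The consolidated clinician column is the OR of the two
  raters (union-style triage: a record flagged by either clinician moves
  forward). The methodologist stage removes a fraction
  `methodologist_exclusion` (default 0.49 — the observed share of
  clinician inclusions later relabeled irrelevant) of clinician
  inclusions, targeting false positives first and spilling into true
  positives only when the false positives are exhausted; the full-text
  stage removes a further `fulltext_exclusion` (default 0.133) the same
  way. Nesting `fulltext ⊆ methodologist ⊆ clinician` therefore holds by
  construction on every corpus.

### What the generator does not capture

Real clinician over-inclusions are *near-topic* records — papers that
look relevant but fail PICO or design criteria — so their text resembles
the relevant class. The generator draws false inclusions uniformly from
the irrelevant class, whose text carries no relevance signal at all.
Synthetic clinician-stage noise is therefore *harder* than real noise:
clinician-stage WSS@95 on default synthetic corpora sits near the random
baseline, whereas on real guideline data it is substantially positive.
The stage ordering (clinician ≤ methodologist ≤ full-text) and the
monotone degradation with noise are preserved and are what the tests
assert; absolute clinician-stage levels on synthetic corpora should not
be read as predictions for real data. Likewise pseudo-word text says
nothing about how well TF-IDF represents real abstracts.

## Numerical and design choices

- Duplicate detection in preprocessing is exact match on the normalized
  title (case-folded, punctuation/whitespace collapsed); DOI or fuzzy
  matching would be an extension. Records with empty or whitespace-only
  abstracts are removed (the feature extractor needs text). Label cells
  accept only {0, 1, "", NA}; anything else is an error, never coerced.
- Model text is `title + " " + abstract`, title first, both screened
  fields.
- Undefined sample SD (a single run or dataset) is NaN, never 0.
- The noise-degradation experiment regenerates an infeasible corpus from
  the next child seed, with bounded retries; its trend statistic is the
  Spearman ρ between noise rate and replicate-level mean WSS@95.
- RNG discipline: a master seed drives per-dataset seeds (irrelevant
  priors, tie-break shuffles) and per-replicate seeds in experiments;
  all derived seeds stay below 2³¹ and every artifact is bitwise
  reproducible from its config.

## Problem sizes

The test suite and the acceptance script run on synthetic corpora of
120–400 records with 1–2 runs per stage in the multi-dataset
experiments, 10–20 replicates per noise rate, and 10⁴ permutations for
the Monte-Carlo baselines — sizes at which every qualitative effect the
package asserts (separability, noise degradation, stage ordering,
calibration) is comfortably detectable in seconds to a couple of
minutes on one CPU.

## Known limitations

- One classifier/feature pair (TF-IDF + multinomial naive Bayes); no
  uncertainty sampling, stopping rules, or alternative models.
- Unweighted κ for two raters only; no Fleiss, weighting, or bootstrap
  CIs.
- Cross-dataset totals are unweighted by corpus size by design; weighted
  variants are out of scope.
- RIS support is read-only and minimal (TI/AB/ID tags).
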