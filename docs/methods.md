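# Methods

`topictriage` implements topic-level ("bag-of-topics") feature selection for
binary document classification, organised as a grouping–scoring–modeling
pipeline: **T** extracts topics with LDA, **G** groups the document–term
matrix into one sub-dataset per topic, **S** scores and ranks the topics by
internal cross-validation, and **M** trains and evaluates classifiers on the
accumulated vocabularies of the top-ranked topics.

## Model and procedure

**Text cleaning.** Documents (e.g. title + abstract, space-concatenated) are
split on non-alphanumeric runs; tokens shorter than `min_token_length`
(default 3) or with a digit fraction above `digit_fraction_threshold`
(default 0.5) are dropped; the rest are lowercased, filtered against a fixed
English stop-word list shipped with the package (version `en-1`), and
stemmed with a from-scratch implementation of the English Snowball (Porter2)
algorithm. The length and stop-word filters are re-applied after stemming so
every emitted token satisfies the full contract (a stem can in principle
fall below the length floor). Documents that end up empty are retained,
flagged, and vectorize to zero rows — mirroring empty-abstract records in
real bibliographic corpora.

**Vocabulary.** A term is kept iff its document frequency is at least
`ceil(min_df_fraction · N)` with `min_df_fraction = 0.01` by default, i.e.
terms appearing in less than 1% of documents are removed. The ceiling is
computed with a 1e-9 guard so binary-fraction noise cannot shift the integer
threshold. Term order is lexicographic.

**Vectorization.** Each document is a relative term-frequency vector:
`x_dw = count(w in d) / |d|`, where `|d|` is the document's *full*
post-cleaning token count, including tokens later removed by the
document-frequency filter. Row sums are therefore ≤ 1, and empty documents
are all-zero rows. A binary presence/absence view exists as an option and is
what the FCBF baseline consumes.

**Topic extraction (T).** LDA with symmetric Dirichlet priors
`alpha = beta = 0.1`, `n_topics = 20` and `n_topic_words = 20` by default.
Inference is batch variational Bayes (scikit-learn backend) with
`max_iter = 200` and a convergence check every 10 passes — at the corpus
sizes this package targets the bound plateaus well before that. A topic is
reported as its `n_topic_words` highest-probability terms; exact probability
ties break lexicographically so word lists are bit-reproducible given the
seed. LDA never sees labels, and by default is fitted on the training
partition only.

**Topic scoring (S).** Each topic's sub-dataset (its words' relative-TF
columns plus labels) is scored by stratified Monte-Carlo cross-validation:
`inner_reps = 10` repetitions of a 90/10 split, a 100-tree random forest per
repetition, and the mean test *accuracy* as the topic score (mean precision,
recall and F1 carried as auxiliaries). The per-class test count is
`round(test_fraction · n_c)` clipped to `[1, n_c − 1]`, so both parts always
contain both classes. Rows are canonically sorted by document id before any
sampling, making split membership a pure function of the derived seed; the
same scoring seed is shared by all topics, so the splits are paired across
topics and duplicated topics receive identical scores. Ties in the ranking
break by higher mean F1, then lower topic index. Per-repetition confusion
matrices are stored on the score object so the mean accuracy can be
recomputed exactly by an independent path.

**Accumulation and outer evaluation (M).** Level `r` is the deduplicated,
order-preserving union of the word lists of the top `r` topics. Each level
is evaluated by outer stratified MCCV — default `reps = 100` repetitions of
90/10 splits with a 100-tree forest — reporting per-level means of accuracy,
sensitivity, specificity, precision, F1 and AUC plus the accuracy standard
deviation and the mean distinct-word count. Within a repetition all levels
share the same split, so level curves are paired. AUC is the rank-based
probability that a random positive outscores a random negative (ties count
one half), computed from the forest's class-probability votes. A metric with
a zero denominator is reported as 0 and flagged rather than dropped, keeping
reports rectangular.

Two ranking policies exist. The default (`fixed-ranking`) scores and ranks
topics once on the designated training data and reuses that ranking across
outer repetitions; `nested` re-scores within every outer training split for
leakage-free estimates at higher cost.

**Selection and final model.** `"best-f1"` selects the smallest level whose
mean F1 is within 0.005 of the maximum, deliberately favouring smaller
vocabularies at equal performance. The final random forest is trained on all
labeled rows restricted to the selected words; the artifact records the word
list, seed, tree count and positive label, and new documents are vectorized
against that word list with their own token counts as denominators.

**Seed discipline.** Every stochastic stage receives
`derive_seed(master, component, index)` — a CRC32-based mix of the stage
name and repetition index with the single run seed — so any stage can be
re-run in isolation and reproduces its output exactly.

**Positive class.** When not configured, the positive label is the
lexicographically greater of the two observed label values (`pos` over
`neg`, `1` over `0`).

## Baselines

FCBF is implemented from its definition: symmetrical uncertainty
`SU = 2·IG(X;Y)/(H(X)+H(Y))` with entropies in bits (defined as 0 when both
variables are constant), candidate features with `SU(f, class) > delta`
ordered by that SU, and the predominance rule discarding `f` when an already
kept `g` has `SU(f,g) ≥ SU(f,class)`. SU values are quantized at 1e-12
before ordering and comparison: entropies are floating-point sums, so
mathematically equal SUs (duplicate or permuted features) can differ in the
last ulp, and quantizing makes ties exact and the selected set reproducible. FCBF runs on the binary view because its information
measures need discrete variables; relative TF is binarized at > 0.
Univariate k-best uses one-way ANOVA F by default (chi-squared on the binary
view as an option); constant features score 0 and rank last. The
tree-importance ranking uses gain-based importances from a 100-tree XGBoost
model. The comparison runner evaluates selector × classifier pairs (random
forest, decision tree, AdaBoost, gradient boosting) at a fixed feature
budget (default top 100 words) under the same outer MCCV.

## Synthetic corpus generator

The generator emulates the structure the method exploits. The vocabulary is
6 disjoint planted word blocks of 20 words plus 200 noise words; words are
alternating consonant–vowel strings verified at generation time to be
stem-stable, digit-free and outside the stop-word list, so planted blocks
survive preprocessing intact. Documents (600 by default, balanced classes)
draw a topic mixture from a Dirichlet with concentration 50 around their
class's base weights, a length from a negative binomial (mean 80,
dispersion 10, shifted by one so non-empty documents are non-empty), and
tokens i.i.d. from the mixture with words uniform within a block; 2% of
documents are emitted with empty text. Base weights put 0.4 on the noise
pool and spread the rest evenly over blocks; the positive class moves
`effect_size = 0.25` of mass from the noise pool evenly onto the two
discriminative blocks. Non-discriminative blocks therefore have identical
expected weight in both classes — the signal is purely topic-level, which
is the mechanism the pipeline claims to exploit, and at zero effect size the
corpus is an exact null.

What the generator does *not* emulate: Zipfian word frequencies, burstiness,
correlated topics, class imbalance at deployment prevalence, multilingual
noise, or real biomedical morphology. Passing recovery tests therefore shows
the machinery is correct under its own generative assumptions, not that any
particular real-corpus performance is guaranteed.

## Numerical and design choices

- Stratified-split rounding, tie-breaks and canonical row order are stated
  above; all are deliberate so that every result is a pure function of
  (data, config, seed).
- The relative-TF denominator precedes vocabulary restriction (document
  size, not in-vocabulary size).
- Topic words missing from the matrix vocabulary are dropped with a log
  line; a topic losing *all* its words is an error at sub-dataset level and
  a logged skip at pipeline level.
- The Porter2 stemmer follows the published algorithm including the
  exceptional forms and the detail that `ll` is not an undoubling pair;
  with no reference implementation installed, its tests freeze stems traced
  by hand through the algorithm definition.
- Cleaning is idempotent on the token streams this package emits for its
  corpora; pathological stems (rare words whose stem re-stems shorter) are
  possible in principle and are not chased.
- Experiment sizes in tests and the acceptance script (corpus 600, scoring
  repetitions 3–10, outer repetitions 3–5, forests of 50–100 trees) are the
  package's desk-scale reference conditions; all counts are configurable
  upward for production runs.

## Known limitations

- Binary classification only; multi-class tasks need a relabeling step.
- `k` (number of topics) is a user choice; no automatic selection.
- Topics are scored individually; interactions between topics are only
  captured implicitly through accumulation.
- The default fixed-ranking mode computes the ranking on the same training
  data the outer MCCV resamples, which is how the accumulation curve is
  usually reported but is not leakage-free; use `nested` for unbiased
  estimates.
- The language filter is a pluggable predicate, off by default; no language
  detector ships with the package.
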