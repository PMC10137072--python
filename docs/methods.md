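# Methods

This note documents the models and procedures behind `levelmap`, the
parameters that matter, the numerical conventions, and what the
synthetic corpora do and do not establish about real data.

## Problem and pipeline

The package triages literature evidence fragments — short published
passages each linking a candidate therapeutic target (an Ensembl gene)
to a disease — onto the molecular level at which the association was
studied: DNA/RNA, protein, or metabolite. The pipeline is staged as
filter → dictionary screen → diverse review sample → manual-review
model → naive Bayes automated review → reports. Each stage is an
importable module with plain-text interchange formats (JSONL, TSV, CSV)
so stages can be run and audited independently.

## Annotation-based filtering

Evidence fragments are retained only when their (Ensembl gene id,
PubMed id) pair is backed by a protein-annotation record passing nine
criteria: protein-level existence; annotation group within the four
general-annotation hierarchies (plain, generic-function,
generic-interaction, medical); GOLD annotation quality; no caution /
domain-info / sequence-caution / variant-info category; no negative
evidence; GOLD evidence quality; publication-type evidence carrying a
PubMed id; at least one of four accepted evidence descriptors (physical
interaction / experimental / direct assay evidence used in manual
assertion, experimental evidence); and a one-to-one protein↔Ensembl
gene mapping (records mapping to zero or several genes are excluded,
not expanded). A publication reference without a PubMed id and a
non-publication evidence type are treated as the same defect
(`publication_with_pmid`), keeping the criterion count at nine while
enforcing both checks. Excluded records are tallied under every
criterion they violate, so the fixture of nine single-violation records
yields exactly one exclusion per criterion.

Deduplication keys on (case-folded whitespace-collapsed text, target
gene, disease): the narrowest key that removes true repeats without
merging distinct target–disease claims. It runs before screening and
keeps the first occurrence.

## Dictionary screening

A fragment joins a category iff at least one of the category's terms
occurs in its text. Matching is case-insensitive and substring-based —
method names legitimately appear inside longer tokens
(`co-immunoprecipitation`) — except for whole-word-only terms, matched
between word boundaries (`(?<!\w)term(?!\w)`, word characters =
letters, digits, underscore). Membership is multi-label; spans are
0-based half-open character offsets into the original text, and all
occurrences are recorded for highlighting and term-profile vectors.

The packaged dictionary (`data/method_terms.tsv`, 70 terms: 33 DNA/RNA,
21 protein, 16 metabolite) follows the IUPAC bioanalytical-chemistry
grouping — Genomics and Nucleic Acid Analysis → DNA/RNA; Enzymatic,
Immunoanalytical and Proteomics methods → protein; Metabolomics,
Lipidomics and Glycomics → metabolite — and is curated so that the 15
packaged reference fragments screen to exactly their reviewed
categories. It is deliberately compact rather than exhaustive; real
corpora will need a fuller term list, supplied as the same TSV format.

Highlighting wraps target-name occurrences in `[..]` and matched term
spans in `{..}`. Overlapping spans are merged left-greedily (same-kind
overlaps union; a span overlapping an earlier span of the other kind is
dropped), and stripping the four bracket characters recovers the
original text provided it contained none of them — bracket characters
in source text are not escaped.

## Diversity-maximizing review sampling

The review sample of k fragments per category minimizes

    f(S) = w_text Σ_{i<j∈S} cos(x_i, x_j) + w_terms Σ_{i<j∈S} cos(t_i, t_j)

where x_i are word-count vectors of the fragment texts and t_i are
counts of matched dictionary terms (term profiles). Both weights
default to 1; the two objectives are combined on raw counts. Cosine
similarity of nonnegative count vectors lies in [0, 1]; an all-zero row
is defined to have similarity 0 to everything, including itself, so
zero-profile fragments do not distort the objective.

The optimizer is a k-of-n subset genetic algorithm: population 100,
200 generations, tournament selection of size 2, union crossover
(child drawn from the parents' gene union), per-position swap mutation
with probability 0.01, and single-individual elitism. All randomness
flows from one `numpy` generator seeded by the config, so runs are
bit-reproducible; ties in the final population break to the
lexicographically smallest id set. Because the initial population is
100 seeded random subsets and the best individual always survives, the
result is never worse than the best of 100 random samples. The
hyperparameters are pragmatic defaults for this instance family, not a
tuned optimum: on every tested instance with n ≤ 12 the GA matches the
exhaustive-enumeration oracle (`brute_force_select`, guarded at 10⁶
subsets), and at the production scale used in the acceptance run
(k = 200 from n = 1000) it improves on random sampling by a wide
margin. Selection at that scale takes a few seconds per category.

## Manual-review model

Each sampled fragment is answered three questions: (1) does the
fragment allow judging the method category, (2) are the highlighted
terms sufficient for that judgment, (3) is the level of study
mentioned. Validation of the screened category follows question 3
(`validated=True` requires `q3=True`). Term–answer associations count,
for every term matched in a reviewed fragment's screened category, the
record's answer; the "answer" is the conjunction q1 ∧ q2 by default,
with `q1` and `q2` modes available since either per-question reading is
defensible. Rankings take the top/bottom n terms by positive/negative
prevalence (count / total), ties broken by larger total then term
surface.

## Naive Bayes automated review

One binary classifier per category. Fragments are tokenized by
*distinct* case-folded words, which makes the Bernoulli event model the
natural choice: P(t|c) = (n_{t,c} + α)/(n_c + 2α) with α = 1 (Laplace),
priors = class frequencies, likelihood over the full training
vocabulary (absent tokens contribute 1 − P), out-of-vocabulary tokens
ignored. The positive class is the validated fragments of the
category's review pool and the negative class the invalidated ones from
the same pool — the classifier is applied within that category's
screened fragments, so its negatives should come from there too; a
multinomial event model over token counts is available behind
`event_model="multinomial"`. The decision threshold is posterior 0.5
with exact ties going negative, a conservative choice that favors
"unrelated". Posterior computation is exact to ~10⁻¹⁵ against an
independent rational-arithmetic Bayes-rule evaluator and matches
scikit-learn's `BernoulliNB` probabilities; the hand-computed
four-document posterior is 0.9.

Evaluation is stratified 5-fold cross-validated balanced accuracy
((sensitivity + specificity)/2). Folds come from scikit-learn's
`StratifiedKFold` with a seeded shuffle after sorting examples by
fragment id, so fold assignment is reproducible and invariant to input
order. Corpus triage applies each category's fitted model to all of
that category's screened fragments; confirmed + unrelated always
partition the category list.

## Synthetic corpora

`SyntheticConfig` plants every property the pipeline must detect:

- `n_per_category` (default 500; 1000 in the review-sampling run) —
  base fragments per category.
- `fragment_length` (8–30 words) and `background_vocab_size` (500) —
  fragments are distinct draws from a neutral background vocabulary
  (`w0421`-style tokens that cannot contain a dictionary term). The
  generator refuses configs whose vocabulary is smaller than the
  maximum length.
- `term_injection_rate` (1.0) — probability a fragment receives one of
  its category's substring terms (multi-word phrases inserted
  contiguously, last, so nothing splits them). Screening on a fully
  injected corpus recovers the planted categories with zero misses and
  zero spills.
- `homograph_rate` (0.05) — probability of embedding a whole-word-only
  term strictly inside a longer token (`xgagx`), which must never fire.
- `duplicate_rate` (0.17) — the fraction of the *emitted* corpus that is
  duplicate records: n·r/(1−r) extra copies are appended and the order
  shuffled, so deduplication retains 1 − r ≈ 83%.
- `false_positive_rate` (0.4) — probability a term-bearing fragment is
  planted invalid (the term used in a non-method sense).
- `context_clarity` (0.44) — probability a term-bearing fragment
  carries three class-pure context tokens (from disjoint per-category
  positive/negative blocks of 20). Because context tokens are the only
  class signal and are perfectly pure, the Bayes-optimal rule is
  correct exactly on context-bearing fragments and can do no better
  than the majority class elsewhere, giving the closed-form optimum
  balanced accuracy (1 + clarity)/2 independent of the class balance.
  The default 0.44 puts the ceiling at 0.72, and cross-validated naive
  Bayes tracks it: the mean over 10 seeds × 3 categories at
  n_per_category = 500 lands within ±0.05 (single runs scatter roughly
  ±0.07, which is why the recovery check averages over seeds). For
  corpus-triage rate recovery the acceptance run uses clarity 1.0, so
  the unrelated fraction equals the planted false-positive rate up to
  binomial noise.

Simulated reviews map planted validity onto the three questions
(valid → yes/yes/yes, invalid → no/no/no); the annotation fixture emits
one passing record per requested (gene, pmid) pair plus exactly nine
records violating one criterion each.

What passing on synthetic corpora shows — and what it does not: the
machinery is correct (parsing, matching, optimization, probability
arithmetic, bookkeeping) and planted rates are recovered at the stated
tolerances. It does not show that the compact dictionary, the
independence assumptions of naive Bayes, or bag-of-words features are
adequate for real biomedical prose, where terms are ambiguous in
context-dependent ways the generator's clean context blocks do not
imitate. Real-corpus figures (overall category counts, false-positive
ranges) depend on the evidence snapshot and the full dictionary and are
outside what desk-scale synthetic runs can certify.

## Numerical conventions and edge cases

- Spans: 0-based, half-open, into the original (not case-folded) text.
- Cosine similarities clipped to [0, 1]; matrices symmetrized; zero
  rows get a zero diagonal.
- Subset objective of an empty or singleton set is 0; it is monotone
  non-decreasing under superset growth (similarities are nonnegative).
- GA final-population ties resolved at 10⁻¹² absolute tolerance, then
  lexicographically.
- `fit` refuses single-class data and non-positive α;
  `cross_validate` refuses classes smaller than the fold count;
  balanced accuracy of a constant classifier is exactly 0.5.
- Report TSVs print floats via `repr` so write → read → write is
  byte-identical; text summaries round to 1–2 decimals.
- Malformed evidence lines are skipped with a logged line number,
  never guessed at; empty review categories are omitted rather than
  zero-divided.
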