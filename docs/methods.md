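# Methods

## Pipeline model and assumptions

`dilic` treats literature triage as supervised classification over
interpretable lexical features. The central assumptions are (i) the
signal distinguishing adverse-event-related articles lives in content
words — nouns and adjectives — of titles and abstracts, so verbs,
adverbs and function words can be discarded; (ii) short within-sentence
co-occurrences (pairs, triplets) carry information beyond single words;
and (iii) external drug-safety knowledge (which drugs carry a hepatic
adverse-event warning) is informative about a document's class even
before any training.

### Text normalization

Sentence segmentation, tokenization, part-of-speech filtering,
lemmatization and stemming are implemented in-package (`dilic.nlp`) as
small rule-based components:

- the segmenter splits on terminal punctuation but not after a fixed
  abbreviation list (`Fig.`, `e.g.`, `et al.`, single initials) or inside
  decimal numbers;
- the tagger classifies tokens into NOUN / ADJ / OTHER using closed-class
  and verb lexicons, adjective suffix rules, and a noun default — so
  out-of-vocabulary technical terms and drug names (effectively proper
  nouns) are kept, which is the behaviour a biomedical pipeline needs;
- normalization is lowercase → rule-based plural lemmatization → classic
  Porter stemming, in that order, and the *same* normalizer is applied to
  drug-lexicon names so lexicon matching is exact on canonical forms.

These components are deliberately simple; they are the package's
reference behaviour and are frozen by the unit tests. A statistical
tagger would change which tokens survive but not the downstream
machinery.

### Keyword sets and transactions

Keyword sets are formed **within a sentence** (cross-sentence
combinations grow combinatorially and blur locality). Duplicate stems in
a sentence collapse before combination generation, the canonical form is
the sorted items joined by `|`, and multiplicities accumulate over the
document's sentences. The default maximum combination size is 3 and
sentences are capped at 25 surviving distinct stems (with a warning)
because C(n,3) growth makes longer sentences disproportionately
expensive without adding discriminative short patterns.

### Mining and scoring

Apriori runs with items = keyword-set canonical strings and
document-presence support (an article counts once however often a
pattern occurs in it), recorded per class. Level-wise join + prune is
the classic algorithm; an exhaustive enumerator with the identical
output contract serves as the independent oracle in tests. Default
minimum support is 0.01 of documents.

For classifier features the pipeline mines itemsets of size 1: each
feature is one keyword set. Keyword sets already encode multi-token
combinations up to the text-level maximum, so itemsets of several
keyword sets are conjunctions of n-grams — redundant for classification
and combinatorially heavy. `mine_patterns` itself supports itemsets up
to any size (default 3) and all lattice invariants are tested at size 3.

Class scores use a pseudo-count (default 1.0) so patterns seen in only
one class stay off the {0,1} boundary; scores always sum to 1 across the
two classes.

### Weighting

The total document weight sums four terms — frequency, length, FDA and
SIDER presence — over the document's present keyword sets. The published
form of this weighting defines a per-document scalar; per-pattern cells
are needed for a classifier with per-feature resolution, so the matrix
stores `score⁺(p) · (W_f·freq + W_l·len)` per present pattern, the two
weighted lexicon-hit columns, and the total weight `W_T` as an extra
column. This preserves every ingredient of the scalar weighting while
letting the model attend to individual patterns — the main interpretive
choice in the package, and the one most worth revisiting against real
data. Lexicon hits are scored at the document level (number of distinct
flagged drugs present, per source). Defaults `W_fda = W_sider = 2 >
W_f = W_l = 1` realize the "flagged drugs weigh more" rule and are
configurable.

### Classification

Six scikit-learn back ends sit behind one enum (logistic, elastic net,
random forest, gradient boosting, SVM, neural net); linear and kernel
models get a standardization step. Gradient boosting is the default
(≤ 200 trees, depth ≤ 3). Model selection is by mean stratified k-fold
CV accuracy (default 5 folds, seeded), ties broken by the fixed enum
order. Zero-variance training columns are dropped and logged; the kept
and full column manifests travel with the model, and prediction on a
matrix whose columns disagree with the manifest is a hard error. The
positive label requires probability **strictly greater** than the cutoff
(default 0.5), so cutoff 1.0 yields no positives and cutoff 0.0 labels
everything positive. Undefined metric ratios (e.g. precision with no
predicted positives) are reported as NaN with a warning, never as 0.

### Stratified split

The discovery split shuffles within each class with a seeded generator
and assigns the first `floor(f·class_size)` documents to training. With
7,177 positive and 7,026 negative articles at f = 0.8 this yields
5,741/5,620 training and 1,436/1,406 test documents per class. The seed
is recorded in the split metadata; no particular historical seed is
assumed.

## Synthetic study corpus

The generator emulates a balanced curated corpus: `n_pos = n_neg = 500`
documents of 3–6 sentences with 4–8 noun-like background tokens each
(vocabulary 400), 10 planted keyword patterns of lengths cycling 1/2/3,
and 20 drugs of which half are DILI-flagged. A planted pattern occurs in
a positive document with probability 0.4 and in a negative one with
0.4/8 (enrichment 8); flagged drugs are mentioned with probability 0.12
in positives vs 0.04 in negatives, unflagged drugs with 0.04 in both.
All randomness flows from one seeded generator (default seed 42) and the
ground truth is emitted alongside the corpus.

Two structural choices matter:

- **Planted phrases occupy their own short sentences.** Keyword sets are
  within-sentence, so inserting two planted phrases into the same
  sentence would manufacture conjunction features with roughly the
  *squared* enrichment of either phrase, which then outrank every
  planted pattern. Real key phrases are clause-local; dedicated
  sentences (padded with two background tokens) model that.
- **Proper sub-combinations are injected class-neutrally**
  (probability 0.2 per document in both classes). Without this, every
  subset of a planted pattern inherits the full pattern's enrichment
  exactly and is indistinguishable from it by class score; in real text
  the words of a discriminative phrase also occur separately in
  unrelated contexts. The neutral injections dilute subsets toward a
  class score of 0.5 while leaving the full pattern's enrichment intact.

What passing tests on this corpus show: the mining, scoring, weighting
and classification machinery recovers planted multi-token enrichment
structure and class-separable documents at realistic corpus sizes. What
they do not show: performance on real abstracts, where patterns overlap,
token frequencies are Zipfian, POS tagging is imperfect, and label noise
exists. The generator makes no attempt at realistic language modelling.

## Numerical and degenerate-input choices

- Support thresholds use `ceil(min_support · n)` with a 1e-9 slack
  against floating-point round-up (e.g. `(2/3)·3` in binary arithmetic
  exceeds 2).
- Pattern output order is (length, lexicographic items); ranking by
  class score breaks ties by total support, then token length, then
  items — all deterministic.
- A document yielding no keyword sets produces an empty transaction and
  a warning; an all-stop-word corpus fails mining with a clear error.
- A pattern's per-document frequency is the minimum of its items'
  frequencies (the number of complete co-occurrences it can assemble).
- Pattern-vs-transaction vocabulary mismatch (different separator or
  normalizer, so no pattern matches any document) is a hard error rather
  than a silently all-zero matrix.

## Problem sizes

The test suite exercises mining equivalence on 100+ random corpora of up
to 15 items and 30 transactions, and the end-to-end properties on the
default 1,000-document synthetic corpus; the acceptance script uses the
same sizes. These are desk-scale choices: the pipeline is linear in
documents and the default feature space stays in the hundreds of
columns, so larger corpora raise runtime, not methodology.

## Known limitations

- The rule-based tagger misclassifies some adjectives ending in verbal
  suffixes ("increased ALT") as OTHER; such tokens drop out of keyword
  sets.
- Brand-name matching is single-token exact after normalization;
  misspellings and abbreviations are not resolved.
- Titles and abstracts are weighted equally when merged.
- The elastic-net and MLP back ends can be slow on wide matrices; the
  default GBM is the tested reference configuration.
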