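# dilic — literature triage for drug-induced liver injury

Drug-induced liver injury (DILI) is a leading cause of drug withdrawal, and
the evidence about it is scattered across an enormous, fast-growing
literature. Curators who maintain DILI reference lists must separate the
abstracts that actually concern hepatic adverse events from the far larger
mass that merely mention a drug or the liver. `dilic` implements an
interpretable triage pipeline for that task: it turns titles and abstracts
into part-of-speech-filtered keyword sets, mines class-discriminative
frequent patterns, weights them with external drug-safety knowledge, and
trains a binary classifier that labels each article as DILI-related or not.

## The method

1. **Keyword sets.** Each document (title + abstract) is split into
   sentences; within a sentence only nouns and adjectives survive, stop
   words are removed, and every surviving token is normalized
   (lowercase → lemmatize → Porter stem). All unordered combinations of
   distinct normalized tokens of size 1..L (default L = 3: singletons,
   pairs, triplets) become the document's *keyword sets*, with
   sentence-level occurrence counts as frequencies.
2. **Pattern mining.** Apriori runs over the keyword-set items with
   document-presence support, counted separately in the positive and
   negative class. A mined pattern's class score is its smoothed class
   ratio
   `score⁺ = (n⁺ + s) / (n⁺ + n⁻ + 2s)`,
   so `score⁺ + score⁻ = 1` for every pattern.
3. **External drug cohorts.** From an FDA-style approved-drug table and a
   SIDER-style side-effect table, every drug whose adverse-event field
   mentions a DILI term (hepatotoxicity, liver injury, …) enters a
   normalized lexicon; exact matches between lexicon names and a
   document's keyword sets are counted per source.
4. **Weighted features.** A document's total weight is

   `W_T = Σᵢ W_f·freqᵢ·keyᵢ + Σᵢ W_l·lenᵢ·keyᵢ + W_fda·fda + W_sider·sider`

   where `keyᵢ ∈ {0,1}` marks the presence of keyword set *i*, `freqᵢ` its
   frequency, `lenᵢ` its token length, and the FDA/SIDER terms boost
   documents mentioning flagged drugs (defaults `W_fda = W_sider = 2` vs
   `W_f = W_l = 1`). Per-pattern feature cells are the class-score-modulated
   frequency+length weights; the matrix feeds any of six classifier
   back ends (logistic, elastic net, random forest, GBM, SVM, MLP), with
   gradient boosting as the default and model selection by stratified CV
   accuracy. A document is labelled positive when its predicted
   probability exceeds the cutoff (default 50%).

A seeded synthetic-corpus generator with planted class-enriched patterns
and a partially DILI-flagged drug lexicon makes every stage testable
without external data.

## Worked example

```bash
dilic synth --seed 42 --out data/           # synthetic corpus + cohorts
dilic train --corpus data/corpus.tsv --fda data/fda.tsv --sider data/sider.tsv \
            --family gbm --model-out model.bin
dilic predict --model model.bin --corpus data/corpus.tsv --out preds.tsv
dilic evaluate --pred preds.tsv --truth data/corpus.tsv
```

The same run through the library:

```python
from dilic import SynthConfig, generate_corpus, evaluate_holdout, PipelineConfig

docs, truth = generate_corpus(SynthConfig(seed=42))   # 500 + 500 documents
result = evaluate_holdout(docs, None, PipelineConfig(), split_seed=0)
print(result.metrics.as_dict())
```

prints

```
{'tp': 91, 'fp': 6, 'fn': 9, 'tn': 94, 'accuracy': 0.925,
 'precision': 0.9381443298969072, 'recall': 0.91, 'f1': 0.9238578680203046}
```

i.e. on the held-out 20% (200 documents) of the default synthetic corpus
the default GBM recovers the planted class structure with 92.5% accuracy;
`dilic.rank_patterns` puts 8 of the 10 planted keyword patterns in the
top ten by positive-class score.

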