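# phenosim

Phenotype-similarity matrices over concept-annotated disorder records,
benchmark evaluation by ROC/AUC, and enrichment-driven prioritization of
candidate disease genes.

`phenosim` is aimed at people who assemble targeted gene panels for groups
of clinically similar disorders: given records of human disorders annotated
with controlled-vocabulary concepts (the shape produced by running a
concept mapper such as MetaMap over OMIM-style entries), it answers two
questions —

1. **Which disorders are phenotypically similar?**  Each record becomes a
   sparse concept-frequency vector; vectors are weighted and compared by
   cosine similarity.
2. **Which genes are likely to underlie a disorder group?**  Genes known to
   be associated with the group (seeds) define enrichment features for every
   other gene — guilt-by-association through protein–protein interaction
   (PPI) neighborhoods and gene-set collections — and an SVM trained on
   seeds vs random negatives ranks all candidates.

## The model

**Similarity.**  For a corpus of `N` records, a concept appearing in
`n_c` records receives the IDF-style *global weight*

    w_global(c) = log2(N / n_c)

and, within a record where it occurs `r_c` times (max frequency `r_max`),
the augmented-frequency *local weight*

    w_local(c) = 0.5 + r_c / (2 · r_max)

Four schemes are supported: `unweighted` (raw frequencies), `global`,
`local`, and `global_local` (their product, the MimMiner-style weighting).
Similarity of two records is the cosine of the angle between their weighted
vectors, in [0, 1].  Matrices are evaluated against ground-truth pair sets
(phenotypic series: subtypes of one disorder; linked records: one record's
text referencing another) by labeling every off-diagonal pair positive iff
it is in the benchmark and computing the ROC AUC over similarity scores.

**Prioritization.**  For a gene `g`, the set of its PPI partners is tested
for over-representation of the seed genes by a one-sided Fisher's exact
test (hypergeometric upper tail, `p = P(X ≥ k)` with universe `M`, set
size `K`, `n` seeds, `k` seeds in the set).  Each of seven gene-set
collections contributes the lowest enrichment p among the sets containing
`g`.  The resulting 8-dimensional vectors (transformed to −log10 p) train
an SVM with seeds as positives and randomly sampled non-seeds as negatives;
uninformative seeds (no feature p < 0.05) are pruned first, and candidates
are ranked by decision score.

## Worked example

`examples/02_weighting_benchmark.py` generates a 200-record corpus with 20
planted disorder clusters, builds all four similarity matrices, and scores
them against the cluster ground truth:

```
ROC AUC by weighting scheme (truth-series pairs):
    unweighted: 0.9752
        global: 1.0000
         local: 0.9953
  global_local: 1.0000

global weighting vs link-derived pairs: AUC = 0.9824
```

Global weighting wins because the generator plants generic concepts that
recur across clusters, and the IDF term discounts exactly those.  The
decile table printed next shows the per-decile true-pair fraction rising
from 0 to 1 with the similarity score: a high cosine score almost always
marks a genuinely similar pair.

`examples/04_gene_prioritization.py` runs the gene-ranking loop on a
200-gene network with a 20-gene planted disease module (10 seeds observed,
10 held out) and reports, e.g.:

```
held-out recovery: AUC = 0.828 (9 positives among 180 candidates)
```

i.e. the held-out module genes concentrate near the top of the ranking.
The other examples (`01_similarity_matrix.py`, `03_enrichment_features.py`)
walk through corpus construction/nearest-neighbor queries and the raw
feature matrix.

A thin CLI mirrors the library:
`phenosim simulate|build-corpus|build-matrix|query|evaluate|enrich|rank`
(see `phenosim --help`).

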