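# Methods

This note records the models implemented in `phenosim`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical and design decisions a maintainer should know about.

## Corpus construction

A disorder record arrives with a title concept sub-vector and a textual
concept sub-vector (frequencies of controlled-vocabulary concepts).  The
pipeline assumes concept mapping and semantic-type restriction happened
upstream; `phenosim` consumes the already-annotated records.  Cleaning
proceeds in a fixed order:

1. keep only phenotype records — type prefix `#`, `%` or `none` (gene
   records `*`, `+`, `^` are excluded);
2. merge the two sub-vectors by entry-wise addition;
3. drop stoplisted concepts (a small shipped list of generic terms such as
   "disease"; users supply their own list for real corpora);
4. alternately drop records with empty vectors and concepts whose document
   count is 1, iterated to a fixed point.

The singleton/empty-record interaction is why step 4 iterates: deleting a
singleton concept can empty a record, whose removal can turn other concepts
into singletons.  The fixed point makes the result order-independent, and
`build_corpus` is idempotent on its own output (tested).

**Title cleaning.**  Subtype designators are stripped from titles so that
subtypes of one disorder share a main title: terminal arabic numerals,
strict roman numerals, single letters and `TYPE <token>` suffixes are
removed repeatedly, then trailing separators trimmed.  The roman-numeral
pattern is the strict form (`M{0,3}(CM|CD|D?C{0,3})...`), so English words
that merely spell with roman letters ("MILD") are never stripped; genuinely
ambiguous terminal words that parse as roman numerals (e.g. "MIX") would
be, a known and accepted limitation.  Mixed alphanumeric designators
("2A" as a bare token) are not recognized; in running text they almost
always follow "TYPE", which is handled.

## Weighting schemes and similarity

With `N` records and a concept in `n_c` of them, the global weight is
`log2(N / n_c)`; within a record the local weight is
`0.5 + r_c / (2 r_max)`.  The four schemes:

| scheme        | entry value                          |
|---------------|--------------------------------------|
| `unweighted`  | raw frequency                        |
| `global`      | `log2(N / n_c)` (presence-based)     |
| `local`       | `0.5 + r_c / (2 r_max)`              |
| `global_local`| product of the two weights           |

The global scheme is presence-based — the IDF *replaces* the frequency
rather than multiplying it — because the global formula contains no
frequency term and the within-record frequency is exactly what the local
scheme contributes; the product scheme then reduces correctly to either
factor.  A concept present in every record gets weight 0 and drops out; a
record zeroed entirely by weighting is excluded from the matrix with a
logged warning rather than an error, mirroring the elimination of
unmappable records during corpus construction.

Similarity is the cosine of the angle between weighted vectors, computed
as a normalized sparse Gram matrix; weights are non-negative so scores lie
in [0, 1].  The matrix is symmetrized exactly and the diagonal pinned to 1.
Matrices match a brute-force pairwise oracle to 1e-12 under all four
schemes (tested on corpora up to 50 records).  Neighbor queries rank by
descending score with ties broken by ascending record id — determinism is
worth more than any particular tie order.

## Benchmarks and evaluation

Ground-truth similar pairs come from (a) phenotypic series — all unordered
within-series pairs, deduplicated across series — and (b) linked records —
pairs where one record references the other, restricted to `#`/`%`
prefixed records.  Evaluation labels *every* off-diagonal matrix pair
positive iff it is in the benchmark; no negative subsampling is done by
default, since at package scales the full pair universe is cheap and the
labeling rule is then applied verbatim.  ROC curves and trapezoid AUC come
from scikit-learn (`drop_intermediate=False`), which groups tied scores
into single threshold steps; the AUC matches an exhaustive
rank-statistic oracle (P(pos > neg) + ½ P(tie)) to 1e-9.

The decile-overlap analysis bins pairs with nonzero score into
`n_intervals` equal-width intervals over (0, max score] and reports the
positive fraction per bin (empty bins report a missing fraction).
Equal-width binning is the simplest reading of "intervals"; equal-count
binning would also be defensible but changes no qualitative conclusion on
the synthetic fixtures.

## Enrichment features

The one-sided Fisher's exact test is computed as the hypergeometric upper
tail `P(X ≥ k)` via `scipy.stats.hypergeom.sf`, floored into (0, 1] (an
underflowed tail is reported as the smallest positive float rather than 0).
`k = 0` gives p = 1 by construction: the least extreme observation must be
non-significant.  The implementation is cross-checked against an exact
integer-combinatorics oracle for every configuration with universe ≤ 60.

Universes are resource-conditioned: the PPI feature uses the network node
set; each collection feature uses the union of the collection's genes and
the seeds.  Each resource is thereby tested on what it can see, and genes
absent from a resource receive the non-informative p = 1 instead of being
dropped, so every candidate stays rankable.  A gene's PPI neighborhood
excludes the gene itself.  Feature vectors have exactly 8 columns (1 PPI +
7 collections; fewer collections must be padded explicitly).  The default
feature transform is `−log10 p` capped at 300 — raw p-values bunch near 0
where margin classifiers are poorly conditioned — with `raw_p` retained as
an option.  Gene symbols are uppercased; alias resolution is out of scope
(it requires an external mapping resource).

## SVM prioritization

Seeds are positives.  Seeds with no feature p below `prune_alpha`
(default 0.05, the conventional significance level; `alpha ≥ 1` is the
keep-everything boundary) carry no guilt-by-association signal and are
pruned from the core training set.  Negatives are a uniform random sample
of non-seed genes of size `round(negative_multiplier × |core|)`; the
default multiplier 1.0 keeps classes balanced.  Features are standardized
per column with training-set mean/sd, and the SVM default is a linear
kernel with C = 1: eight monotone features do not need a nonlinear
boundary, and the linear kernel keeps rankings interpretable and stable.
Candidates are ranked by decision score, ties again lexicographic.

The end-to-end helper `run_prioritization` falls back to training on the
full seed set (with a warning) when pruning would remove every seed, so a
signal-free input still yields a ranking — an uninformative one — instead
of an error; the lower-level `prune_uninformative_seeds` keeps its strict
error contract.

The validation filter recomputes, for each putative disease gene, the
enrichment of its neighborhood for seeds (p_in) and for all other genes
(p_out), removing the gene iff p_out < p_in; isolated or absent genes are
kept with a warning since the test is undefined for them.

## Synthetic generators

`simulate_corpus` plants clusters: 200 records round-robin over 20
clusters, each cluster owning an 8-concept signature carried by members
with probability 0.8, plus 8 noise concepts per record drawn uniformly
(without replacement) from the 40-concept non-signature pool, frequencies
uniform on 1..5.  The small noise pool is deliberate: noise concepts recur
in ~20% of records each, emulating the generic high-document-frequency
vocabulary of real disorder text, while signature concepts stay rare —
this is precisely the structure IDF weighting exploits, so the weighting
comparison is meaningful rather than rigged by construction order.  Ground
truth doubles as both benchmark forms: one series per cluster, and one
reference from each record to a random co-member.

`simulate_disease_module` wires a 200-gene Erdős–Rényi background at
p_out = 0.02 with a 20-gene module densified at p_in = 0.3, and builds 7
collections of 5 sets (sizes 10–30) in which one planted set holds 70% of
the module genes padded with random genes.  Half the module (10 genes) is
observed as seeds, half held out.  Erdős–Rényi plus a planted module is
the simplest graph null with a recoverable signal; it does not reproduce
the heavy-tailed degree distributions of real PPI networks.

What passing tests show — and do not.  The generators demonstrate that the
pipeline recovers planted structure under clean, exchangeable noise: real
corpora have correlated concepts, topic structure and heterogeneous record
lengths, and real networks have hubs that inflate neighborhood tests.
Performance numbers on these fixtures therefore validate the machinery,
not expected field performance on curated disease databases.

Problem sizes throughout (200 records / 200 genes, 10 replicate seeds)
were chosen so a full pipeline run takes well under a minute while keeping
the planted-signal estimates stable across seeds.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); every simulator, the negative sampler and
  the SVM are deterministic given their config, and two identical runs
  produce byte-identical ranking files (tested).
- Cosine values are clipped into [0, 1] and the matrix symmetrized by
  averaging, removing float asymmetry from the sparse product.
- Zero-variance feature columns get sd = 1 during standardization.
- Degenerate inputs error loudly: empty corpus after filtering, zero
  positives or negatives in a ROC, empty seed list or universe in an
  enrichment test, single-class SVM training.
- ROC-ready structures store descending thresholds; monotone
  transformations of scores leave the AUC unchanged (tested).

## Known limitations

- The subtype-stripping rule is a documented regex, not a reconstruction
  of any curator's exact behavior.
- The shipped stoplist is a token default; real corpora need a curated one.
- Collection features treat collections as opaque configuration; no
  specific collection semantics (pathways vs ontology terms) are modeled.
- No negative-sample bagging: a single negative draw per run keeps the
  contract simple, at the cost of sampling noise in the ranking for weak
  signals.
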