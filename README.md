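# omicsrules

Network-aware association rule mining for paired gene-expression /
DNA-methylation data, with TOPSIS multi-criteria rule ranking.

Given matched expression and methylation matrices for two sample groups
plus a protein–protein interaction (PPI) edge list, the pipeline:

1. **preprocess** — matches genes/samples across omics, zero-mean
   normalizes each gene row, runs a moderated t-test (empirical-Bayes
   variance shrinkage, BH correction) per omics, collapses probes to the
   best probe per gene, and keeps genes significant in *both* omics that
   are present in the PPI universe.
2. **discretize** — codes each gene/sample as `GENE+` (up-regulated and
   hypo-methylated) or `GENE-` (down-regulated and hyper-methylated),
   discordant states yield no item; samples become transactions.
3. **netdist** — combines co-expression and co-methylation correlations
   (optionally weighted by a functional-similarity matrix) into a [0,1]
   similarity, masks its complement with the PPI adjacency, and computes
   all-pairs weighted shortest distances. Distances drive *dynamic*
   per-gene-pair support/confidence/lift thresholds: pairs closer than
   the median distance get a stricter (higher) cutoff than the user
   minimum, distant pairs a laxer one.
4. **mining** — FP-growth frequent directional gene sets, re-filtered by
   each set's dynamic support threshold; every antecedent/consequent
   bipartition becomes a rule kept only if confidence and lift clear the
   set's dynamic cutoffs.
5. **ranking** — TOPSIS: support/confidence/lift are benefit criteria,
   the rule's average network distance is a cost criterion; rules are
   ranked by relative closeness to the positive ideal solution.
6. **evaluate** (optional) — per-rule nearest-shrunken-centroid
   classification with repeated stratified 10-fold CV (accuracy,
   sensitivity, specificity, AUC).

A synthetic-data module generates paired datasets with planted,
PPI-connected differential modules so the whole pipeline is testable
without downloads. `omicsrules.benchmarks` bundles published reference
tables (from a high-grade soft-tissue sarcoma study, GEO GSE52392) used
to validate the ranking and summary arithmetic.

## CLI

```sh
# generate a synthetic dataset with 2 planted 3-gene modules
omicsrules simulate --out data/ --n-genes 30 --n-modules 2 --seed 1

# full pipeline
omicsrules run-all \
    --expression data/expression.tsv --methylation data/methylation.tsv \
    --labels data/labels.tsv --ppi data/ppi_edges.tsv \
    --min-support 0.3 --min-confidence 0.5 --out results/

# re-rank an existing rule table
omicsrules rank --rules results/rules.tsv --out results/ranked.tsv
```

Inputs are plain TSV/CSV (matrices: first column gene/probe ID, header =
sample IDs; labels: sample/label columns; PPI: two gene IDs per line,
optional weight). A YAML/JSON config file (`--config`) can replace the
flags; flags win on conflict.

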