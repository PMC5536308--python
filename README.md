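# gexpipe

A multi-omics differential-expression pipeline for comparing mutant
conditions against a matched wild-type baseline on both the proteome and the
transcriptome, with overlap statistics and functional profiling on top:

* **proteomics** — spike-in SILAC analysis: parse a MaxQuant-style
  `proteinGroups` TSV, form per-replicate "ratio of ratios"
  `(H/L)_baseline / (H/L)_mutant` (the common heavy reference cancels, so
  results are oriented mutant/baseline), median-scale each replicate,
  log2-transform, and run one-sample t-tests; DE at `|FC| > 1.5` and
  `p < 0.05` with a ≥2-replicate rule.
* **rnaseq** — count-based DE: technical-run summing, TMM normalisation,
  method-of-moments common NB dispersion, a conditional two-sided NB exact
  test on library-size-equalised group sums, BH-FDR, per-replicate CPM-ratio
  fold changes with SEM; DE at `|FC| > 1.5` and BH-adjusted `p < 0.01`, with
  an optional `log2(CPM) > 8` high-expression filter for enrichment input.
* **overlap** — permutation significance of every Venn region between
  per-condition significant sets: B iterations of uniform fixed-size subset
  resampling per condition, reporting observed count, permutation median and
  2.5–97.5 percentiles, `log2(obs/median)`, and a two-sided empirical
  p-value with add-one correction.
* **ontology** — term enrichment/depletion on an acyclic is-a DAG using
  two-tailed Fisher's exact tests with the elim decorrelation pass
  (children first; significant children's genes removed from ancestors) and
  a minimum node size (default 10). Evidence codes ND/IEA/NR are excluded
  before true-path propagation.
* **classes** — gene-class profiling: two-sample KS tests of a class versus
  the rest, observed/expected class counts in the over-/under-expressed
  sets with Fisher p-values, and cross-omics Pearson correlations stratified
  by significance category.
* **simulate** — synthetic inputs with exact ground truth (log-normal SILAC
  ratio noise with missingness, NB counts with configurable Venn-region DE
  structure, random single-root DAGs, class labels), so every stage is
  testable offline.

## CLI

```sh
# generate a synthetic dataset with ground truth
gexpipe simulate --n-genes 2000 --n-proteins 500 --seed 1 --out data/

# single stages
gexpipe proteomics --protein-groups data/proteinGroups.tsv --mutant mutA --out prot.tsv
gexpipe rnaseq --counts data/counts.tsv --samples data/samples.tsv --mutant mutA --out rna.tsv
gexpipe overlap --membership members.tsv --iterations 10000 --seed 1 --out overlap.tsv
gexpipe go --terms data/dag_terms.tsv --edges data/dag_edges.tsv \
    --annotations data/annotations.tsv --universe universe.txt \
    --interesting de.txt --out go.tsv
gexpipe classes --results rna.tsv --class-table data/classes.tsv --out-prefix cls

# everything from one YAML config
gexpipe all --config config.yaml --seed 1 --out results/
```

A minimal config:

```yaml
output_dir: results
seed: 1
iterations: 10000
universe_mode: intersection
simulate:            # or an `inputs:` block pointing at existing files
  n_genes: 2000
  n_proteins: 500
  conditions: [wt, mutA, mutB, mutC]
  overlap_spec: {mutA: 80, mutB: 80, mutC: 80, mutA+mutB+mutC: 20}
  de_fraction: 0.2
  nb_dispersion: 0.05
```

All output tables are TSV with `# key: value` provenance headers
(thresholds, seed), floats at 6 significant digits and `NA` for undefined
values; `manifest.json` records seeds, thresholds and file paths so a run
can be reproduced exactly.

## Notes and conventions

* Protein and transcript fold changes are both reported as
  mutant / baseline on the log2 scale.
* All DE thresholds are strict inequalities.
* Zero-variance proteins receive an undefined p-value (`NA`) and are never
  called DE.
* The NB exact test uses the "sum of outcomes no more probable than
  observed" two-sided convention by default; a doubled-tail variant is
  available (`tail="doubled"`).
* The elim pass uses the two-tailed Fisher test by default; an
  enrichment-only one-sided variant is available via `alternative="greater"`.
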