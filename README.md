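# lsepipe

Genome-scale detection of positive-selection footprints in lineage-specific
expanded (LSE) gene families versus single-copy genes, in a phylogenetic
codon-model framework.

The pipeline:

1. **Reconciliation** — rooted gene trees are reconciled against a species
   tree by LCA mapping; internal nodes are labelled duplication/speciation.
2. **Cluster extraction** — *ultraparalog* (UP) clusters are maximal
   single-species subtrees (LSE expansions); *superortholog* (SO) clusters
   are maximal all-speciation subtrees (≤1 gene per species). Clusters are
   partitioned into UP1/UP2/SO1/SO2 by per-tree co-occurrence and sampled
   one-per-tree.
3. **Alignment QC** — whole-cluster rejection on internal stop codons or
   lengths not divisible by three; codon-column cleaning from an external
   reliability mask (GUIDANCE-style scores) or a gap-fraction fallback;
   minimum of 4 sequences post-cleaning.
4. **Site models** — GY94 codon model (61 sense codons) with site-class
   mixtures M1a/M2a/M8a/M8, fitted by bounded multi-start maximum
   likelihood over a Felsenstein-pruning engine; LRTs (df 2 and 1) with
   Bonferroni correction; per-codon empirical-Bayes P(ω>1) with sites
   flagged strictly above 0.95; synonymous/nonsynonymous site opportunities
   by κ-weighted mutation enumeration.
5. **Branch ω** — analytic substitution mapping (posterior expected nbNS /
   nbS per branch via the eigendecomposition integral), branch
   ω = (nbNS/NSsites)/(nbS/Ssites), zero-substitution filters, and the
   ω<1 / ω>1 / ω>1.2 classification with internal/external splits.
6. **Statistics** — Fisher exact tests by cluster-size category
   (clusters/codons/branches), Mann–Whitney ω comparisons, sliding-window
   dS tests, Spearman correlation of cluster counts vs divergence time,
   and the dataset/branch summary tables.

A first-class synthetic-data module simulates complete studies (two-clade
species tree, duplication/loss gene families with LSE bursts, codon
alignments under known ω mixtures) with full ground truth, so everything is
testable offline.

## CLI

```sh
# generate a synthetic study with ground truth
lsepipe simulate --seed 1 --families 50 --codons 300 --outdir study/

# run the complete workflow
lsepipe run-all study/ --seed 1 --outdir results/

# or stage-wise
lsepipe reconcile study/ --outdir results/
lsepipe fit study/ --outdir results/ --config config.yaml
```

`results/` receives `clusters.tsv`, `sites.tsv`, `branches.tsv`, the
dataset/branch-summary/Fisher tables, sliding-window results, and a
`manifest.json` whose filter counts reconcile exactly with the per-record
tables. Runs are bit-reproducible from config + seed.

Configuration is a single YAML file; all thresholds (minimum cluster size
6, posterior cutoff 0.95, ω cutoffs 1 / 1.2, window width 0.01, window
minimum 100, model list, seed) are keys with the published defaults
(`lsepipe show-config` prints them).

## Layout

```
src/lsepipe/
  geneticcode.py   codon tables, syn/nonsyn/transition classification
  gy94.py          GY94 generators, spectral decomposition, F3x4
  sitemodels.py    M1a/M2a/M8a/M8 mixture specifications
  likelihood.py    61-state pruning engine with pattern compression
  fit.py           ML fitting, LRT, Bonferroni, NEB site calls, site counts
  mapping.py       per-branch expected substitution counts, branch ω
  reconcile.py     LCA reconciliation, UP/SO extraction, categories
  qc.py            CDS validation and alignment cleaning
  stats.py         Fisher / Mann–Whitney / windows / Spearman / summaries
  simulate.py      synthetic studies with ground truth
  pipeline.py      orchestration, manifest, report tables
  cli.py           click command line
```
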