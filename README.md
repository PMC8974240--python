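# panelqtl

Desk-scale analysis pipeline for inbred diversity panels: structured-panel
simulation with planted truth, REML/BLUP phenotype summaries, mixed-linear-model
(MLM) genome-wide association with kinship and principal-component covariates,
rule-based QTL region calling with cross-panel merging and effect-sign
splitting, cross-trait co-location and allele-effect pivot analysis,
candidate-gene proximity annotation, and Gaussian Bayesian-network learning of
trait relationships under growth-stage blacklists.

## Modules

| module                | what it does |
|-----------------------|--------------|
| `panelqtl.simulate`   | Balding–Nichols-style structured genotypes (optional local LD via Markov copying), replicated phenotypes generated from a planted truth set (QTL effects, trait DAG, environment/replicate structure), JSON truth round trip |
| `panelqtl.phenostats` | two/three-component REML variance components and BLUPs (exact closed form on balanced one-way designs), LSmeans, natural-log transforms, Pearson correlations with t-tests |
| `panelqtl.gwas`       | centered cross-product kinship, genotype PCA, panel subsetting with rare-allele flags, per-marker REML MLM scans (EMMA-style eigendecomposition, F or Wald tests), allele statistics oriented to the most common allele |
| `panelqtl.regions`    | significance clustering (200 kb chaining, ±50 kb flanks), stringency flags (single-SNP, all-rare), cross-panel merging (800 kb gap + sign-consistency rule), QTL naming, ≤500 kb co-location, pivot tables, gene-window annotation |
| `panelqtl.bn`         | partial-correlation tests, Semi-Interleaved HITON-PC screening, stage blacklists, BIC hill climbing, 10-fold cross-validated structure selection with arc strengths |
| `panelqtl.io` / `panelqtl.cli` / `panelqtl.pipeline` | HapMap/VCF/TSV/BED/GFF3/DOT/JSON readers and writers with provenance headers, YAML configuration, subcommand CLI, end-to-end orchestration |

Coordinates are 1-based inclusive throughout; only the BED export converts to
0-based half-open.

## CLI

```bash
# everything end to end on a simulated demo panel
panelqtl all --seed 1 --outdir out/

# or stage by stage
panelqtl simulate --seed 1 --n-snps 5000 --outdir out/
panelqtl pheno --phenotypes out/phenotypes.tsv --log-trait As --log-trait Si --out out/blups.tsv
panelqtl gwas --genotypes out/genotypes.vcf --trait-matrix out/blups.tsv \
    --subpops out/subpops.tsv --trait StHD --panel All --n-pcs 3 --out out/assoc.tsv
panelqtl regions --assoc out/assoc.tsv --out out/qtl.tsv --bed out/qtl.bed
panelqtl bn --trait-matrix out/blups.tsv --seed 1
```

`panelqtl all` also accepts `--config config.yaml`; the YAML mirrors
`panelqtl.pipeline.PipelineConfig` (paths, panel definitions with PC counts,
thresholds: sig 5.0, extend 200 kb, flank 50 kb, merge gap 800 kb, co-location
gap 500 kb, gene window 1 Mb, min SNPs 2, min alternate-allele carriers 6, and
the network-learning block).

Default synthetic-panel effect sizes (see `simulate.default_truth`) are chosen
by the implementers so that planted QTL explain enough variance to be
recoverable at desk scale; real-panel heritabilities are not published and are
therefore not emulated quantitatively.

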