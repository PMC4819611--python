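# blastohet

Single-cell transcriptome heterogeneity analysis of mouse pre-implantation
blastomeres.

## The problem

In the first days of mouse development, blastomeres of the 2-, 4- and
8-cell embryo look identical, yet cell fate begins to be biased at these
stages. Full-length single-cell RNA-seq of *every* sister blastomere of
complete embryos makes it possible to ask two quantitative questions:

1. **Are cells of the same embryo more similar to each other than to
   cells of other embryos?** Answered by comparing Spearman correlations
   of expression profiles within versus between embryos (same collection
   batch only), with Welch's unequal-variance *t* test.
2. **Which genes vary between sister blastomeres more than technical
   noise allows?** Answered by fitting the technical trend of the squared
   coefficient of variation against the mean of normalized counts,

   CV²(μ) = a₁/μ + α₀,

   on genes with mean normalized count > 10, and testing each gene with
   T_g = (m−1)·CV²_g / CV²_fit(μ_g) against χ²_{m−1} (m cells), calling
   genes with Benjamini–Hochberg adjusted p < 0.1 highly variable. To ask
   the question *within* embryos, the per-gene linear model
   g_ijk = A_i + B_ik + ε_ijk is first fitted on log₁₀ expression and the
   embryo effect B removed (ĝ = g − B) before re-running the CV² test.

Around this core the package provides the full supporting pipeline:
per-cell QC (fraction of mapped reads, genes > 10 RPM, mitochondrial
fraction; outlier screen), dual median-of-ratios size factors (ERCC-like
spike-in based for depth, endogenous-gene based for depth + RNA content),
log₁₀(x+1) transformation, empirical-Bayes (ComBat-style) batch
adjustment controlling for stage and division pattern with the
zero-clamping rule, PCA, target-gene-set enrichment (two-of-three support
rule + Fisher's exact test) and co-expression clustering of variable
target genes (Spearman distance 1−ρ, complete linkage, dynamic top-down
tree cut).

Because every stage needs ground truth to be testable, the package ships
a first-class synthetic-data generator that emulates the study design:
complete embryos at 2/4/8 cells plus 16/32-cell embryos, spike-ins at
fixed amounts, per-cell capture scalings, planted highly variable genes
(optionally organized in co-expression modules), per-embryo expression
shifts, per-batch location/scale distortions and planted target-gene
catalogs — with the planted truth returned alongside the counts.

## Worked example

```python
from blastohet import PipelineConfig, SyntheticConfig, run_pipeline

summary = run_pipeline(
    PipelineConfig(out_dir="run", seed=1, synthetic=SyntheticConfig())
)
print(summary["hvg_counts"])       # {2: 156, 4: 202, 8: 184}
print(summary["welch"][4])         # {'t': 23.94, 'p': 1.02e-44}
print(summary["enrichment"])       # {'stage': 4, 'odds_ratio': 7.87, 'p_value': 1.10e-25}
print(summary["n_coexpression_clusters"])  # 2
```

On the default synthetic study (8 two-cell, 16 four-cell, 4 eight-cell,
6 sixteen-cell and 6 thirty-two-cell embryos; 2000 genes, 10% planted
highly variable with excess CV² 0.5) this prints 156/202/184 embryo-
adjusted variable genes at the 2-/4-/8-cell stages — the planted 200 are
recovered with F1 ≈ 0.86 at the 4-cell stage. Intra-embryo correlations
exceed inter-embryo ones (mean ρ 0.896 vs 0.839 at the 4-cell stage,
Welch p ≈ 1e-44) because the generator plants per-embryo expression
shifts; the planted target catalog is enriched among variable genes
(odds ratio 7.9, Fisher p ≈ 1e-25); and the two planted anti-correlated
co-expression modules are found as exactly 2 clusters.

The same pipeline runs from the shell:

```bash
blastohet run --seed 1 --out-dir run          # default synthetic study
blastohet simulate --seed 1 --out-prefix sim  # counts + ground truth
blastohet hvg --matrix sim.mtx --genes sim.genes.tsv --cells sim.cells.tsv \
    --stage 4 --within-embryo --out-prefix hvg4
```

Real data enter as a MatrixMarket (or TSV) genes × cells count matrix
with `genes.tsv` (id, spike-in flag, mito flag) and `cells.tsv` (id,
embryo, stage, batch, division pattern) sidecars.

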