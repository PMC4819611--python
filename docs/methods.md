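# Methods

## Scope and data model

The package analyses a genes × cells matrix of read counts from
full-length single-cell RNA-seq of mouse pre-implantation blastomeres.
Cells carry an embryo of origin, a developmental stage (2, 4, 8, 16 or
32 cells), a collection batch and, where scored, the 2→4-cell division
pattern (ME/EM/MM/EE; NA otherwise). Genes carry two flags: ERCC-like
spike-in and mitochondrial. Stages 2/4/8 are "complete-embryo" stages:
every sister blastomere of an embryo is assumed captured, which is what
makes intra- vs inter-embryo comparisons and the embryo-effect model
well posed.

## Quality control

Three per-cell metrics: fraction of mapped reads assigned to features
(1, flagged as assumed, when mapped totals are unavailable), number of
genes above 10 reads per million (strict >, RPM denominator = total
endogenous counts of the cell), and fraction of endogenous reads on
mitochondrial genes. The original screen identifies outliers visually on
a PCA of these metrics; here the screen is an explicit, deterministic
rule so it can be tested: a cell is flagged iff it is on the worse side
of the cohort mean on **all three** metrics (low mapped fraction, low
gene count, high mito fraction) *and* at least one metric lies more than
`mad_k` (default 3) raw median absolute deviations from the cohort
median. The metric PCA is still computed and returned for reporting.
There is no published numeric threshold; `mad_k = 3` is this package's
default. Flagged cells are dropped before normalization (a flag keeps
them for diagnostics).

## Normalization

Median-of-ratios size factors: the reference for gene g is its geometric
mean across cells (genes with any zero excluded from the reference set);
cell j's factor is the median over reference genes of count/reference,
rescaled to geometric mean 1 across cells to remove the arbitrary global
scale. Two factor sets are computed — on spike-ins (sequencing depth
only) and on endogenous genes (depth plus per-cell RNA content); gene-
level analyses use the endogenous basis by default, switchable by flag,
since the original analysis computes both without stating which feeds
which figure. If no gene is nonzero in every cell, the estimator falls
back to genes nonzero in ≥ 95% of cells with per-cell medians over the
available ratios (warned); with no such genes it raises. Log expression
is log₁₀(normalized + 1), so zeros map to zero exactly.

## Highly variable genes

Per gene, CV² = var/μ² of normalized counts across the m cells of the
analysis (unbiased variance, m−1). The technical trend CV²(μ) = a₁/μ + α₀
is fitted on genes with μ > 10 by a gamma-family GLM with identity link
of CV² on 1/μ; if the iterative fit fails to converge or yields a
non-positive trend over the data range, an ordinary-least-squares fit is
used and the fallback recorded. The test statistic is
T_g = (m−1)·CV²_g/CV²_fit(μ_g), referred to χ²_{m−1}; the named method
and the BH < 0.1 threshold are published, the χ² construction is the
canonical completion of that variance-ratio test. BH adjustment runs over
eligible genes only; genes below the mean filter get NA p-values and are
never called. No minimum-biological-dispersion term is applied. Ties at
the threshold resolve by strict `<`.

The trend is fitted per analysis (per stage in the pipeline), since
variable-gene counts are reported per stage.

## Embryo-effect model

On log₁₀ expression, g_ijk = A_i + B_ik + ε_ijk with A_i the gene's mean
over all cells and B_ik the embryo-mean deviation (closed-form least
squares; Σ_k n_k B_ik = 0 by construction). The adjusted values are
ĝ = g − B. The within-embryo variability test then needs normalized-
count-scale input, while the regression is defined on log values; the
package back-transforms 10^ĝ − 1 (clamped at 0) by default before
re-fitting the trend — testing on ĝ directly is available behind a
switch (`back_transform=False`) since the published text does not state
which scale was used.

With a finite number of embryos, removing embryo means leaves per-gene
heteroskedastic technical noise (the multiplicative embryo effect also
scales Poisson variance), so purely inter-embryo variability collapses
to a small residual call rate rather than literally zero; the tests
assert a several-fold collapse.

## Intra- vs inter-embryo comparison

Per complete-embryo stage, genes with mean normalized count below 10 (on
that stage's cells) are removed, and every unordered cell pair is scored
by Spearman's ρ (average-rank ties). Pairs are intra- (same embryo) or
inter-embryonic (different embryos, same batch); cross-batch pairs are
excluded entirely so batch differences cannot masquerade as biology. The
two groups are compared by Welch's two-sided unequal-variance t test
with Welch–Satterthwaite degrees of freedom.

**Statistical caveat.** Each cell participates in many pairs, so the
pair-level ρ values are not independent; the test ignores this,
following the published procedure. Empirically this makes the test
conservative under embryo-label permutation (cell-level random effects
cancel in the intra−inter difference, so its true variance is far below
the independence-based estimate): permutation p-values concentrate near
1 rather than being uniform. Detection of real embryo structure is
nevertheless reliable (≥ 90% power at the default planted effect).

## Batch adjustment

Parametric empirical-Bayes location/scale adjustment on log₁₀(x+1):
per-gene model with batch indicators plus stage and division-pattern
covariates; gene-wise standardization; per-batch location (γ) and scale
(δ²) estimates shrunk toward normal / inverse-gamma batch-level priors
(moment-matched) by the standard iterative conditional solution
(tolerance 1e-4, cap 500 iterations — non-convergence is an error);
reconstruction without batch terms, covariates retained; any value ≤ 0
set to exactly 0. Genes under 10 mean normalized counts pass through
unadjusted and flagged. Division-pattern NA cells form their own design
level so that all cells are adjusted; covariate levels that are exact
linear combinations of already-included columns (NA is determined by
stage, for instance) are pruned with a warning, whereas a covariate
confounded with *batch* is an error naming the collinear columns.
`gamma_star` is stored in standardized units; `BatchModel.location_shifts()`
rescales it to data units. A test cross-checks the adjusted values
against an independent implementation of the same estimator (agreement
to ~1e-6).

Analyses downstream of the adjustment (per-stage variable genes, PCA,
target clustering) run on the adjusted values back-transformed to the
normalized scale (10^y − 1); the intra/inter correlation comparison
stays on unadjusted normalized counts with the same-batch rule, mirroring
the published order of operations.

## Enrichment and co-expression clustering

Target catalogs merge by a support rule (default: present in ≥ 2 of 3
lists), intersected with the universe of genes with any raw count in the
analysed cells. Association between targets and variable genes is a
two-sided Fisher exact test on the 2×2 classification over that
universe; odds ratio is the sample cross-product with the ∞ convention
for empty off-diagonals. Per-set `min_support` is configurable because
the published catalogs are built asymmetrically (a two-of-three rule for
one factor, a single list for the other).

Clustering of a gene set: gene × gene Spearman matrix across cells,
distance 1 − ρ (not 1 − |ρ|, so anti-correlated genes separate),
complete-linkage agglomeration, then a top-down dynamic tree cut: a merge
node is a distinct split when its height exceeds both children's internal
heights by at least `min_gap` (default 0.15 on the 1−ρ scale); each side
of an accepted split becomes a cluster if it has ≥ `min_cluster_size`
(default 20) leaves, unless it splits distinctly again; everything else
is label 0 (unassigned). With no real structure no split is accepted and
no clusters form — the no-spurious-module property. The published
algorithm's numeric parameters are not given; `min_gap` is this
package's separation parameter. Constant genes are excluded (correlation
undefined). The dendrogram exports as Newick.

## Synthetic data generator

Counts for endogenous gene g in cell j of embryo k:
Poisson(s_j · μ_g · θ_gj · 10^{b_gk}) with s_j ~ logN(0, 0.25) (the true
size factor), μ_g ~ logN(3.0, 1.3) (median ≈ 20 counts), θ_gj a
unit-mean gamma multiplier with variance 0.5 for the planted 10% highly
variable genes (Poisson-gamma ⇒ negative-binomial marginal, matching the
CV²_tech + CV²_bio decomposition the test assumes) and 1 otherwise, and
b_gk ~ N(0, 0.1) per-embryo log₁₀ shifts (exactly removable by the
linear model). Spike-ins are Poisson(s_j·c_i) on a fixed geometric
ladder c_i ∈ [1, 10⁴] with no biological, embryo or batch term. Planted
variable genes are drawn from genes with μ_g > 10 — planting excess
variability below the detection floor would make recovery benchmarks
meaningless. A fraction (default 0.4) of planted variable genes is
organized into co-expression modules (default 2) sharing a per-cell
latent factor through a log-normal multiplier with the same excess CV²;
with two modules the second loads negatively, giving one correlated and
one anti-correlated block. Three target-gene lists are planted so that a
two-of-three rule recovers a core of module/variable genes plus matched
non-variable genes, with per-list decoys.

Embryos split round-robin within stage across 2 batches by default (so
stage and batch stay unconfounded and same-batch embryo pairs exist at
every stage). Batch distortions are per-batch per-gene location shifts
(N(0, 0.2)) and scale factors (gamma, shape 6, unit mean — typical
distortions up to ~1.5×) applied on the depth-corrected log₁₀ scale
(counts/s_j + 1), centered on gene × stage means, then rescaled by s_j
and re-rounded to integers: this is the scale on which the downstream
batch model operates, so the adjustment model is correctly specified up
to count discretization. The study design default is 8/16/4 embryos at
the 2/4/8-cell stages plus 6 morulae and 6 blastocysts (400 cells),
2000 genes, 50 spike-ins, 5% mitochondrial genes.

The stated magnitudes of embryo, batch and capture variation are free
parameters of the generator, not estimates from any dataset — no
quantitative magnitudes are published for them. Division-pattern labels
are metadata only; no expression effect is planted.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: stage-specific mean expression changes
(the dominant signal in real embryos; the synthetic PCA therefore does
not group cells by stage), zero inflation or dropout beyond Poisson
sampling, gene–gene correlation outside the planted modules, gene-length
or GC effects, and any association between division pattern and
expression.

## Numerical choices

- Variance uses the m−1 denominator throughout.
- Size factors: arithmetic median of ratios (not the log-space median),
  matching the cited estimator; geometric-mean-1 rescaling.
- Gamma-GLM fit capped at 100 IRLS iterations; fallback OLS recorded on
  the fit object.
- Welch test: the only special case is both groups constant and equal
  (t = 0, p = 1); a zero-variance group against a different mean yields
  ±∞ and p = 0.
- EB batch iteration: relative-change convergence at 1e-4, cap 500.
- PCA: full SVD via scikit-learn on gene-centered values; components
  clipped to the data dimensions with a warning.
- All randomness in the pipeline flows from the single config seed; runs
  are byte-reproducible (the manifest stores a config hash that excludes
  the output directory).

## Known limitations

- The pair-level Welch comparison is conservative (see the caveat
  above); a permutation or mixed-model alternative would calibrate it
  but is deliberately out of scope as it is not the published procedure.
- The χ² form of the variability test is approximate for counts; at
  modest means and strong multiplicative effects the per-gene technical
  CV² disperses around the trend, leaving a small residual call rate
  after embryo adjustment.
- The dynamic tree cut implements the top-down ("tree") variant only;
  the hybrid variant is out of scope.
- The manifest records per-stage content hashes but the pipeline does
  not do incremental re-execution; stale stages are detectable, not
  skipped.
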