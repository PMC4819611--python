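"""Highly variable gene detection via the CV²-vs-mean technical trend.

For each gene, the squared coefficient of variation of its normalized
counts across cells, CV² = var/μ², is compared with a technical trend
fitted as CV²(μ) = a1/μ + α0 on genes with mean normalized count above
``min_mean`` (default 10, which limits the skew from lowly expressed
genes). Under pure technical (Poisson-like) noise the statistic

    T_g = (m − 1) · CV²_g / CV²_fit(μ_g)

is approximately chi-square with m − 1 degrees of freedom (m cells);
genes whose upper-tail probability survives a Benjamini–Hochberg
adjustment below the FDR threshold (default 0.1) are called highly
variable. The trend is fitted by a gamma-family GLM with identity link
of CV² on 1/μ, falling back to ordinary least squares when the
iterative fit does not converge (recorded on the fit object).

To separate within-embryo from between-embryo variability, the per-gene
linear model g_ijk = A_i + B_ik + ε_ijk is fitted on log10 expression
(gene i, cell j, embryo k): A_i is the gene's mean over all cells and
B_ik the embryo-mean deviation. The embryo effect is removed as
ĝ = g − B, and the CV² test re-run on the back-transformed values
10^ĝ − 1 (clamped at 0), so that it again operates on the normalized
count scale on which the trend is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, NumericalError
from .normalize import LogMatrix, NormalizedMatrix


@dataclass
class CV2Fit:
    a1: float
    a0: float
    genes_used: list
    min_mean: float
    method: str  # "glm_gamma" | "ols"
    negative_fit_warning: bool = False

    def predict(self, mean: np.ndarray | float) -> np.ndarray | float:
        return self.a1 / np.asarray(mean, dtype=float) + self.a0


@dataclass
class HVGResult:
    """Per-gene variability table plus the trend fit that produced it.

    ``table`` is indexed by gene id with columns ``mean``, ``cv2``,
    ``cv2_fit``, ``stat``, ``p``, ``p_adj``, ``is_variable``. Genes below
    the mean filter carry NaN p-values and are never called variable.
    """

    table: pd.DataFrame
    fit: CV2Fit
    fdr: float
    provenance: str = "normalized"

    @property
    def variable_genes(self) -> set:
        return set(self.table.index[self.table["is_variable"]])


@dataclass
class EmbryoAdjustedMatrix:
    """Log-scale expression with per-embryo effects removed."""

    values: np.ndarray  # genes x cells, ĝ = g − B
    genes: pd.DataFrame
    cells: pd.DataFrame
    grand_mean: pd.Series  # A_i per gene
    embryo_effects: pd.DataFrame  # genes x embryos, B_ik
    source: LogMatrix


def _gene_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, var / mean**2, np.nan)
    return mean, cv2


def fit_cv2_trend(
    matrix: NormalizedMatrix | None = None,
    min_mean: float = 10.0,
    *,
    values: np.ndarray | None = None,
    gene_ids: pd.Index | None = None,
    endogenous_only: bool = True,
) -> CV2Fit:
    """Fit CV² = a1/μ + α0 on genes with mean normalized count > min_mean."""
    if matrix is not None:
        mask = matrix.endogenous_mask() if endogenous_only else np.ones(len(matrix.gene_ids), bool)
        values = matrix.values[mask]
        gene_ids = matrix.gene_ids[mask]
    if values.shape[1] < 3:
        raise InsufficientDataError("CV² trend needs at least 3 cells")
    mean, cv2 = _gene_moments(values)
    eligible = (mean > min_mean) & np.isfinite(cv2)
    if eligible.sum() < 2:
        raise InsufficientDataError(
            f"only {int(eligible.sum())} genes exceed mean {min_mean}; need >= 2"
        )
    mu = mean[eligible]
    y = cv2[eligible]
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])

    a0 = a1 = None
    method = "glm_gamma"
    if np.all(y > 0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
                res = glm.fit(maxiter=100)
            if res.converged and np.all(np.isfinite(res.params)):
                a0, a1 = float(res.params[0]), float(res.params[1])
        except Exception:
            a0 = a1 = None
    if a0 is None or (a1 / mu + a0 <= 0).any():
        method = "ols"
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])

    fit = CV2Fit(
        a1=a1,
        a0=a0,
        genes_used=list(gene_ids[eligible]),
        min_mean=min_mean,
        method=method,
    )
    if np.any(fit.predict(mu) <= 0):
        fit.negative_fit_warning = True
        warnings.warn("fitted CV² trend is non-positive over part of the data range", stacklevel=2)
    return fit


def test_hvg(
    matrix: NormalizedMatrix | None = None,
    fit: CV2Fit | None = None,
    fdr: float = 0.1,
    *,
    values: np.ndarray | None = None,
    gene_ids: pd.Index | None = None,
    endogenous_only: bool = True,
    provenance: str = "normalized",
) -> HVGResult:
    """Chi-square test of each gene's CV² against the fitted trend.

    Eligible genes (mean > ``fit.min_mean``) get T = (m−1)·CV²/CV²_fit
    and p = P(χ²_{m−1} ≥ T); BH adjustment runs over eligible genes only
    and a gene is variable iff p_adj < fdr (strict). Eligible genes whose
    fitted CV² is non-positive are excluded with a warning.
    """
    if fit is None:
        raise ValueError("a CV2Fit is required")
    if matrix is not None:
        mask = matrix.endogenous_mask() if endogenous_only else np.ones(len(matrix.gene_ids), bool)
        values = matrix.values[mask]
        gene_ids = matrix.gene_ids[mask]
    m = values.shape[1]
    mean, cv2 = _gene_moments(values)
    fitted = fit.predict(mean)
    eligible = (mean > fit.min_mean) & np.isfinite(cv2)
    bad_fit = eligible & (fitted <= 0)
    if bad_fit.any():
        warnings.warn(
            f"{int(bad_fit.sum())} genes excluded: fitted CV² non-positive", stacklevel=2
        )
        eligible &= fitted > 0

    stat = np.full(len(mean), np.nan)
    p = np.full(len(mean), np.nan)
    stat[eligible] = (m - 1) * cv2[eligible] / fitted[eligible]
    p[eligible] = stats.chi2.sf(stat[eligible], df=m - 1)
    p_adj = np.full(len(mean), np.nan)
    if eligible.any():
        p_adj[eligible] = multipletests(p[eligible], method="fdr_bh")[1]
    is_variable = np.zeros(len(mean), dtype=bool)
    is_variable[eligible] = p_adj[eligible] < fdr

    table = pd.DataFrame(
        {
            "mean": mean,
            "cv2": cv2,
            "cv2_fit": fitted,
            "stat": stat,
            "p": p,
            "p_adj": p_adj,
            "is_variable": is_variable,
        },
        index=gene_ids,
    )
    return HVGResult(table=table, fit=fit, fdr=fdr, provenance=provenance)


def call_hvg(
    matrix: NormalizedMatrix, min_mean: float = 10.0, fdr: float = 0.1
) -> HVGResult:
    """Convenience composition: fit the trend, then test every gene."""
    fit = fit_cv2_trend(matrix, min_mean=min_mean)
    return test_hvg(matrix, fit, fdr=fdr)


def regress_embryo_effect(
    log_matrix: LogMatrix, embryo_labels: pd.Series | None = None
) -> EmbryoAdjustedMatrix:
    """Remove per-embryo shifts from log expression, gene by gene.

    Closed-form least squares for g_ijk = A_i + B_ik + ε: A_i is the
    gene's mean over all cells, B_ik the embryo-mean minus A_i (so that
    Σ_k n_k B_ik = 0), and ĝ = g − B. No iteration is involved.
    """
    if embryo_labels is None:
        embryo_labels = log_matrix.cells["embryo"]
    labels = pd.Series(embryo_labels).reindex(log_matrix.cell_ids)
    if labels.isna().any() or (labels.astype(str) == "").any():
        bad = labels.index[labels.isna() | (labels.astype(str) == "")][0]
        raise ValueError(f"cell {bad!r} has no embryo label")
    g = log_matrix.values
    A = g.mean(axis=1)
    embryos = pd.Index(pd.unique(labels))
    B = np.empty((g.shape[0], len(embryos)))
    Bcells = np.empty_like(g)
    lab = labels.to_numpy()
    for k, e in enumerate(embryos):
        cols = lab == e
        B[:, k] = g[:, cols].mean(axis=1) - A
        Bcells[:, cols] = B[:, k][:, None]
    return EmbryoAdjustedMatrix(
        values=g - Bcells,
        genes=log_matrix.genes,
        cells=log_matrix.cells,
        grand_mean=pd.Series(A, index=log_matrix.gene_ids, name="grand_mean"),
        embryo_effects=pd.DataFrame(B, index=log_matrix.gene_ids, columns=embryos),
        source=log_matrix,
    )


def intra_embryo_hvg(
    log_matrix: LogMatrix,
    embryo_labels: pd.Series | None = None,
    min_mean: float = 10.0,
    fdr: float = 0.1,
    back_transform: bool = True,
) -> tuple[HVGResult, EmbryoAdjustedMatrix]:
    """Call highly variable genes after removing the embryo effect.

    With ``back_transform`` (default) the adjusted log values are mapped
    back to the normalized-count scale as 10^ĝ − 1 clamped at 0 before
    the CV² trend and test; otherwise the test runs on ĝ directly.
    """
    adjusted = regress_embryo_effect(log_matrix, embryo_labels)
    endo = ~log_matrix.genes["is_spikein"].to_numpy()
    if back_transform:
        values = np.maximum(10.0 ** adjusted.values[endo] - 1.0, 0.0)
        provenance = "embryo_adjusted_backtransformed"
    else:
        values = adjusted.values[endo]
        provenance = "embryo_adjusted_log"
    gene_ids = log_matrix.gene_ids[endo]
    fit = fit_cv2_trend(values=values, gene_ids=gene_ids, min_mean=min_mean)
    result = test_hvg(
        values=values, gene_ids=gene_ids, fit=fit, fdr=fdr, provenance=provenance
    )
    return result, adjusted
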