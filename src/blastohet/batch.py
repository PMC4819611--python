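"""Empirical-Bayes location/scale batch adjustment of log expression.

The adjuster follows the standard parametric ComBat recipe: per-gene
linear model with batch indicators plus biological covariates (stage and
2->4-cell division pattern), gene-wise standardization, per-batch
location (γ) and scale (δ²) estimates shrunk toward batch-level priors
(normal prior on γ, inverse-gamma prior on δ²) by the usual iterative
conditional solution, reconstruction of the data without the batch
terms but with the covariate effects retained, and finally the clamping
rule: any adjusted value that is zero or negative is set to exactly 0
(the input is log10(x+1) >= 0, so this restores the floor of the scale).

Genes whose mean normalized count falls below ``min_mean_filter`` are
passed through unadjusted and flagged; the filter limits the influence
of lowly expressed genes whose log values are dominated by zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError
from .normalize import LogMatrix


@dataclass
class BatchModel:
    batches: list
    gamma_hat: pd.DataFrame  # batch x gene, raw location estimates
    delta2_hat: pd.DataFrame  # batch x gene, raw scale estimates
    gamma_star: pd.DataFrame  # batch x gene, shrunk location
    delta2_star: pd.DataFrame  # batch x gene, shrunk scale
    priors: dict  # batch -> {gamma_bar, tau2, a_prior, b_prior}
    covariate_columns: list
    adjusted_genes: pd.Index
    passthrough_genes: pd.Index
    n_iterations: dict  # batch -> EB iterations used
    pooled_variance: pd.Series | None = None  # per adjusted gene, data units

    def location_shifts(self) -> pd.DataFrame:
        """Shrunk batch location shifts on the log-expression (data) scale.

        ``gamma_star`` lives in standardized units (per-gene pooled SD);
        this rescales it back for comparison with planted or known shifts.
        """
        if self.pooled_variance is None:
            return self.gamma_star
        return self.gamma_star * np.sqrt(self.pooled_variance)


def _design_matrix(cells: pd.DataFrame, batch: pd.Series, covariates: list[str]):
    """Batch one-hots plus drop-first dummies for each covariate.

    Missing division-pattern values form their own level (all cells are
    adjusted; none dropped). Raises if the design is rank deficient,
    naming the collinear columns.
    """
    batch_d = pd.get_dummies(batch, prefix="batch").astype(float)
    parts = [batch_d]
    for cov in covariates:
        col = cells[cov].astype(str).replace({"": "NA"})
        d = pd.get_dummies(col, prefix=cov, drop_first=True).astype(float)
        parts.append(d)
    design = pd.concat(parts, axis=1)
    # covariate columns aliased with already-accepted columns (e.g. a
    # division-pattern level that only occurs at particular stages) are
    # pruned; a batch column that fails this check means batch is
    # confounded with the covariates, which is unrecoverable
    batch_cols = batch_d.columns.tolist()
    kept: list[str] = batch_cols.copy()
    dropped: list[str] = []
    confounded: list[str] = []
    Xb = batch_d.to_numpy()
    for name in design.columns:
        if name in batch_cols:
            continue
        col = design[[name]].to_numpy()
        if np.linalg.matrix_rank(np.hstack([Xb, col])) == len(batch_cols):
            confounded.append(name)  # explained by batch alone
            continue
        trial = kept + [name]
        if np.linalg.matrix_rank(design[trial].to_numpy()) == len(trial):
            kept.append(name)
        else:
            dropped.append(name)
    if confounded:
        raise ConfigurationError(
            f"covariates confounded with batch; collinear columns: {confounded}"
        )
    if dropped:
        warnings.warn(f"aliased covariate columns dropped: {dropped}", stacklevel=3)
    return design[kept], batch_cols


def _postvar(sums2: np.ndarray, n: int, a: float, b: float) -> np.ndarray:
    return (0.5 * sums2 + b) / (n / 2.0 + a - 1.0)


def combat_adjust(
    log_matrix: LogMatrix,
    batch: pd.Series | None = None,
    covariates: tuple[str, ...] = ("stage", "division_pattern"),
    min_mean_filter: float = 10.0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[LogMatrix, BatchModel]:
    """Remove batch location/scale effects from a log matrix.

    Returns the adjusted :class:`LogMatrix` (same genes/cells; filtered
    genes passed through untouched) and the fitted :class:`BatchModel`.
    A single batch is an identity pass-through with a warning.
    """
    cells = log_matrix.cells
    if batch is None:
        batch = cells["batch"]
    batch = pd.Series(batch).reindex(log_matrix.cell_ids).astype(str)
    batches = sorted(batch.unique())
    gene_ids = log_matrix.gene_ids
    Y = log_matrix.values.astype(float)

    adjust_mask = log_matrix.norm_means.to_numpy() >= min_mean_filter
    adjusted_genes = gene_ids[adjust_mask]
    passthrough = gene_ids[~adjust_mask]

    if len(batches) < 2:
        warnings.warn("single batch: nothing to adjust", stacklevel=2)
        out = LogMatrix(
            values=np.maximum(Y, 0.0),
            genes=log_matrix.genes,
            cells=log_matrix.cells,
            norm_means=log_matrix.norm_means,
        )
        empty = pd.DataFrame(index=batches, columns=adjusted_genes, dtype=float)
        model = BatchModel(
            batches=batches,
            gamma_hat=empty,
            delta2_hat=empty.copy(),
            gamma_star=empty.copy(),
            delta2_star=empty.copy(),
            priors={},
            covariate_columns=[],
            adjusted_genes=adjusted_genes,
            passthrough_genes=passthrough,
            n_iterations={},
        )
        return out, model

    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ConfigurationError(f"each batch needs >= 2 cells; too small: {small}")

    design, batch_cols = _design_matrix(cells, batch, list(covariates))
    X = design.to_numpy()
    n_batch = len(batches)
    n_cells = X.shape[0]

    D = Y[adjust_mask]  # genes x cells
    # per-gene OLS of the full model
    Bhat, *_ = np.linalg.lstsq(X, D.T, rcond=None)  # coefs x genes
    n_per_batch = np.array([(batch == b).sum() for b in batches], float)
    grand = (n_per_batch / n_cells) @ Bhat[:n_batch]  # weighted batch intercept
    var_pooled = ((D - (X @ Bhat).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    # standardized data: remove grand mean and covariate effects
    stand_mean = grand[:, None] + (X[:, n_batch:] @ Bhat[n_batch:]).T
    Z = (D - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((n_batch, D.shape[0]))
    delta2_hat = np.empty_like(gamma_hat)
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        gamma_hat[bi] = Z[:, cols].mean(axis=1)
        delta2_hat[bi] = Z[:, cols].var(axis=1, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    priors = {}
    n_iterations = {}
    for bi, b in enumerate(batches):
        g = gamma_hat[bi]
        d2 = delta2_hat[bi]
        gamma_bar = g.mean()
        tau2 = g.var(ddof=1)
        m, s2 = d2.mean(), d2.var(ddof=1)
        if s2 <= 0:
            raise NumericalError(f"batch {b!r}: degenerate scale estimates")
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        priors[b] = {"gamma_bar": gamma_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior}

        cols = (batch == b).to_numpy()
        nb = cols.sum()
        Zb = Z[:, cols]
        g_old = g.copy()
        d_old = _postvar(((Zb - g_old[:, None]) ** 2).sum(axis=1), nb, a_prior, b_prior)
        converged = False
        for it in range(1, max_iter + 1):
            g_new = (nb * tau2 * g + d_old * gamma_bar) / (nb * tau2 + d_old)
            sums2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = _postvar(sums2, nb, a_prior, b_prior)
            change = max(
                np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
                np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                converged = True
                break
        if not converged:
            raise NumericalError(
                f"batch {b!r}: EB iteration did not converge in {max_iter} steps"
            )
        gamma_star[bi] = g_old
        delta2_star[bi] = d_old
        n_iterations[b] = it

    if (delta2_star <= 0).any():
        raise NumericalError("non-positive shrunk scale estimate")

    # reconstruct without batch terms, keep covariate effects
    adjusted = Z.copy()
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        adjusted[:, cols] = (Z[:, cols] - gamma_star[bi][:, None]) / np.sqrt(
            delta2_star[bi]
        )[:, None]
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    out_values = Y.copy()
    out_values[adjust_mask] = adjusted
    # clamp rule: values <= 0 after removal are set to exactly 0
    out_values[adjust_mask] = np.where(
        out_values[adjust_mask] <= 0, 0.0, out_values[adjust_mask]
    )

    def frame(a):
        return pd.DataFrame(a, index=batches, columns=adjusted_genes)

    model = BatchModel(
        batches=batches,
        gamma_hat=frame(gamma_hat),
        delta2_hat=frame(delta2_hat),
        gamma_star=frame(gamma_star),
        delta2_star=frame(delta2_star),
        priors=priors,
        covariate_columns=design.columns.tolist(),
        adjusted_genes=adjusted_genes,
        passthrough_genes=passthrough,
        n_iterations=n_iterations,
        pooled_variance=pd.Series(var_pooled, index=adjusted_genes, name="pooled_variance"),
    )
    out = LogMatrix(
        values=out_values,
        genes=log_matrix.genes,
        cells=log_matrix.cells,
        norm_means=log_matrix.norm_means,
    )
    return out, model
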