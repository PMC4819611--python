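"""Intra- vs inter-embryonic similarity and PCA embeddings.

For each complete-embryo stage (2, 4, 8 cells) every unordered pair of
cells is scored by the Spearman correlation of their expression profiles
(genes with mean normalized count below 10 at that stage removed). Pairs
are labeled intra-embryonic (same embryo) or inter-embryonic (different
embryos collected in the same batch); cross-batch pairs are excluded so
that batch differences do not masquerade as inter-embryo differences.
The two groups of coefficients are compared by Welch's unequal-variance
t test. Each cell participates in many pairs, so the pair values are not
independent; the test treats them as such (see the methods note for this
caveat of the procedure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import InsufficientDataError
from .normalize import LogMatrix, NormalizedMatrix


@dataclass
class CorrelationComparison:
    stage: int
    pairs: pd.DataFrame  # columns cell_a, cell_b, rho, kind ("intra"|"inter")
    welch_t: float | None = None
    welch_p: float | None = None

    @property
    def intra_values(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "intra", "rho"].to_numpy()

    @property
    def inter_values(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "inter", "rho"].to_numpy()

    @property
    def n_intra(self) -> int:
        return int((self.pairs["kind"] == "intra").sum())

    @property
    def n_inter(self) -> int:
        return int((self.pairs["kind"] == "inter").sum())


@dataclass
class Embedding:
    coordinates: pd.DataFrame  # cells x components
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # genes x components
    top_loadings: dict  # component -> {"positive": [...], "negative": [...]}
    gene_subset: list


def pairwise_spearman(
    matrix: NormalizedMatrix,
    stage: int,
    min_mean: float = 10.0,
) -> CorrelationComparison:
    """Spearman correlation for every cell pair at one stage.

    Ranks use average tie handling. The gene filter (mean >= min_mean) is
    applied on the cells of the requested stage only.
    """
    cells = matrix.cells
    sel = (cells["stage"] == stage).to_numpy()
    if sel.sum() < 2:
        raise InsufficientDataError(f"stage {stage} has fewer than 2 cells")
    sub = matrix.subset_cells(sel)
    endo = sub.endogenous_mask()
    vals = sub.values[endo]
    keep = vals.mean(axis=1) >= min_mean
    if keep.sum() < 2:
        raise InsufficientDataError("fewer than 2 genes pass the mean filter")
    vals = vals[keep]

    # rank within each cell, then Pearson of the rank vectors
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    rho = np.corrcoef(ranks.T)

    emb = sub.cells["embryo"].to_numpy()
    batch = sub.cells["batch"].to_numpy()
    ids = sub.cell_ids.to_numpy()
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if emb[i] == emb[j]:
                kind = "intra"
            elif batch[i] == batch[j]:
                kind = "inter"
            else:
                continue
            rows.append((ids[i], ids[j], float(rho[i, j]), kind))
    pairs = pd.DataFrame(rows, columns=["cell_a", "cell_b", "rho", "kind"])
    if pairs.empty or (pairs["kind"] == "intra").sum() == 0 or (pairs["kind"] == "inter").sum() == 0:
        raise InsufficientDataError(
            f"stage {stage}: need both intra- and inter-embryo (same batch) pairs"
        )
    return CorrelationComparison(stage=stage, pairs=pairs)


def welch_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t statistic and p with Welch–Satterthwaite df.

    The only special case is both samples being constant and equal, which
    returns (0, 1); otherwise the textbook formula applies as-is.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Welch test needs >= 2 values per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(x.mean() - y.mean()), 0.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def welch_test(comparison: CorrelationComparison) -> CorrelationComparison:
    """Complete a comparison with the Welch test of intra vs inter values."""
    t, p = welch_statistic(comparison.intra_values, comparison.inter_values)
    comparison.welch_t = t
    comparison.welch_p = p
    return comparison


def compare_intra_inter(
    matrix: NormalizedMatrix, stage: int, min_mean: float = 10.0
) -> CorrelationComparison:
    """pairwise_spearman followed by welch_test."""
    return welch_test(pairwise_spearman(matrix, stage, min_mean=min_mean))


def pca_embedding(
    log_matrix: LogMatrix,
    gene_subset,
    n_components: int = 2,
    top_k: int = 20,
) -> Embedding:
    """PCA of cells on a gene subset of centered log expression.

    Genes are centered across cells; cells are the observations. Returns
    coordinates, variance-explained fractions, full loadings, and the
    ``top_k`` most positive and most negative loading genes per component.
    ``n_components`` is clipped to the data dimensions with a warning.
    """
    import warnings

    subset = pd.Index(gene_subset).intersection(log_matrix.gene_ids)
    if len(subset) == 0:
        raise InsufficientDataError("gene subset is empty after intersection")
    idx = log_matrix.gene_ids.get_indexer(subset)
    X = log_matrix.values[idx].T  # cells x genes
    max_comp = min(X.shape)
    if n_components > max_comp:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(pca.components_.T, index=subset, columns=comp_names)
    top = {}
    for c in comp_names:
        order = loadings[c].sort_values()
        top[c] = {
            "negative": list(order.index[:top_k]),
            "positive": list(order.index[::-1][:top_k]),
        }
    return Embedding(
        coordinates=pd.DataFrame(coords, index=log_matrix.cell_ids, columns=comp_names),
        variance_fractions=pca.explained_variance_ratio_,
        loadings=loadings,
        top_loadings=top,
        gene_subset=list(subset),
    )
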