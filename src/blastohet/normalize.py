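"""Size-factor normalization and log transform.

Two size-factor sets are computed with the median-of-ratios estimator:
one on ERCC-like spike-ins (capturing sequencing depth only) and one on
endogenous genes (additionally capturing per-cell RNA content). For each
gene with strictly positive counts in every cell, a reference value is
taken as its geometric mean across cells; each cell's factor is the
median over reference genes of count/reference, rescaled so the factors
have geometric mean 1 (the estimator's arbitrary global scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, NormalizationError
from .io import CountMatrix

BASES = ("spikein", "endogenous")


@dataclass
class SizeFactors:
    factors: pd.Series  # per cell, positive, geometric mean 1
    basis: str  # "spikein" | "endogenous"
    reference: pd.Series  # per-gene geometric means used
    fallback: bool = False  # True when the >=95%-nonzero fallback was used


@dataclass
class NormalizedMatrix:
    """Counts divided column-wise by per-cell size factors."""

    values: np.ndarray  # genes x cells, non-negative reals
    genes: pd.DataFrame
    cells: pd.DataFrame
    basis: str
    size_factors: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def endogenous_mask(self) -> np.ndarray:
        return ~self.genes["is_spikein"].to_numpy()

    def subset_cells(self, keep) -> "NormalizedMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cells.index.get_indexer(pd.Index(keep))
        return NormalizedMatrix(
            values=self.values[:, idx],
            genes=self.genes,
            cells=self.cells.iloc[idx],
            basis=self.basis,
            size_factors=self.size_factors.iloc[idx],
        )


@dataclass
class LogMatrix:
    """log10(normalized + 1) expression, the scale of the linear models."""

    values: np.ndarray  # genes x cells, >= 0
    genes: pd.DataFrame
    cells: pd.DataFrame
    norm_means: pd.Series  # per-gene mean of the source normalized matrix

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index


def size_factors(matrix: CountMatrix, basis: str = "endogenous") -> SizeFactors:
    """Median-of-ratios size factors on the chosen gene set.

    Reference genes are those with strictly positive counts in every
    cell. If none exist, genes nonzero in >=95% of cells are used with a
    per-cell median over the available ratios (with a warning); if that
    set is also empty a :class:`NormalizationError` suggests switching
    basis.
    """
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}")
    mask = matrix.spikein_mask() if basis == "spikein" else matrix.endogenous_mask()
    counts = matrix.values[mask, :].astype(float)
    ids = matrix.gene_ids[mask]
    if counts.shape[1] == 0:
        raise NormalizationError("no cells")
    all_pos = (counts > 0).all(axis=1)
    fallback = False
    if all_pos.any():
        ref_counts = counts[all_pos]
        ref_ids = ids[all_pos]
        log_ref = np.log(ref_counts).mean(axis=1)
        s = np.median(ref_counts / np.exp(log_ref)[:, None], axis=0)
    else:
        frac_nonzero = (counts > 0).mean(axis=1)
        near = frac_nonzero >= 0.95
        if not near.any():
            raise NormalizationError(
                f"no {basis} gene has nonzero counts in (nearly) all cells; "
                "switch basis or supply deeper data"
            )
        warnings.warn(
            "no gene is nonzero in every cell; falling back to genes nonzero "
            "in >=95% of cells with per-cell medians over available ratios",
            stacklevel=2,
        )
        fallback = True
        ref_counts = counts[near]
        ref_ids = ids[near]
        with np.errstate(divide="ignore"):
            logc = np.where(ref_counts > 0, np.log(ref_counts), np.nan)
        log_ref = np.nanmean(logc, axis=1)
        ratios = np.where(ref_counts > 0, ref_counts / np.exp(log_ref)[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise NormalizationError("size factors are not all positive and finite")
    # remove the arbitrary global scale
    s = s / np.exp(np.mean(np.log(s)))
    return SizeFactors(
        factors=pd.Series(s, index=matrix.cell_ids, name="size_factor"),
        basis=basis,
        reference=pd.Series(np.exp(log_ref), index=ref_ids, name="reference"),
        fallback=fallback,
    )


def normalize(matrix: CountMatrix, factors: SizeFactors) -> NormalizedMatrix:
    """Divide each cell's counts by its size factor."""
    if not factors.factors.index.equals(matrix.cell_ids):
        raise AlignmentError("size factors were not computed on these cells")
    values = matrix.values / factors.factors.to_numpy()[None, :]
    return NormalizedMatrix(
        values=values,
        genes=matrix.genes,
        cells=matrix.cells,
        basis=factors.basis,
        size_factors=factors.factors,
    )


def log_transform(matrix: NormalizedMatrix) -> LogMatrix:
    """Element-wise log10(x + 1); zeros map to zero exactly."""
    if matrix.values.size and matrix.values.min() < 0:
        raise ValueError("negative values cannot be log-transformed")
    means = matrix.values.mean(axis=1) if matrix.values.size else np.zeros(len(matrix.gene_ids))
    return LogMatrix(
        values=np.log10(matrix.values + 1.0),
        genes=matrix.genes,
        cells=matrix.cells,
        norm_means=pd.Series(means, index=matrix.gene_ids, name="norm_mean"),
    )
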