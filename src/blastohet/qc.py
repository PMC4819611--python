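"""Per-cell quality control.

Three metrics per cell: the fraction of mapped reads assigned to features,
the number of genes exceeding 10 reads per million (RPM), and the fraction
of endogenous reads on mitochondrial genes. A cell is flagged as a quality
outlier when it is worse than the average on all three metrics at once and
at least one metric deviates from the cohort median by more than ``mad_k``
median absolute deviations. A PCA of the z-scored metric table is returned
alongside for visual reporting; the flagging rule itself is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientDataError
from .io import CountMatrix

QC_METRICS = ["frac_mapped", "n_genes_over_10rpm", "frac_mito"]


@dataclass
class QCTable:
    """Per-cell QC metrics.

    ``table`` is indexed by cell id with columns ``total_reads``,
    ``frac_mapped``, ``n_genes_over_10rpm``, ``frac_mito`` and
    ``zero_total`` (warning flag for cells with no endogenous counts).
    ``frac_mapped_assumed`` is True when no mapped-read totals were
    supplied and frac_mapped defaults to 1.
    """

    table: pd.DataFrame
    frac_mapped_assumed: bool


@dataclass
class OutlierReport:
    flagged: set
    pca_coordinates: pd.DataFrame  # cells x PCs of the z-scored metrics
    variance_fractions: np.ndarray
    mad_k: float


def compute_qc_metrics(
    matrix: CountMatrix, mapped_read_totals: pd.Series | None = None
) -> QCTable:
    """Compute the three QC metrics for every cell.

    RPM uses total endogenous counts per cell as the denominator; a gene
    counts toward ``n_genes_over_10rpm`` only if its RPM exceeds 10
    strictly. ``frac_mapped`` is (assigned endogenous+spike reads) /
    ``mapped_read_totals``; when totals are absent it is set to 1 and the
    result flagged accordingly.
    """
    endo = matrix.values[matrix.endogenous_mask(), :].astype(float)
    total_assigned = matrix.values.sum(axis=0).astype(float)
    total_endo = endo.sum(axis=0)
    zero_total = total_endo == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        rpm = endo * 1e6 / total_endo[None, :]
        n_over = (rpm > 10.0).sum(axis=0)
        mito = matrix.values[matrix.mito_mask(), :].sum(axis=0).astype(float)
        frac_mito = np.where(zero_total, 0.0, mito / np.where(zero_total, 1.0, total_endo))
    n_over = np.where(zero_total, 0, n_over)

    assumed = mapped_read_totals is None
    if assumed:
        frac_mapped = np.ones(matrix.n_cells)
    else:
        mapped_read_totals = pd.Series(mapped_read_totals)
        try:
            totals = mapped_read_totals.loc[matrix.cell_ids].to_numpy(float)
        except KeyError as exc:
            raise AlignmentError(f"mapped_read_totals missing cells: {exc}") from exc
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_mapped = np.where(totals > 0, total_assigned / totals, 0.0)
        frac_mapped = np.clip(frac_mapped, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "total_reads": total_assigned.astype(np.int64),
            "frac_mapped": frac_mapped,
            "n_genes_over_10rpm": n_over.astype(np.int64),
            "frac_mito": frac_mito,
            "zero_total": zero_total,
        },
        index=matrix.cell_ids,
    )
    return QCTable(table=table, frac_mapped_assumed=assumed)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def flag_outliers(qc: QCTable, mad_k: float = 3.0) -> OutlierReport:
    """Flag cells that are worse than average on all three metrics.

    "Worse" is low ``frac_mapped``, low ``n_genes_over_10rpm``, high
    ``frac_mito``. A cell is flagged iff it is on the worse side of the
    cohort mean for every metric AND at least one of its metrics lies more
    than ``mad_k`` raw median-absolute-deviations from the cohort median.
    Also returns the PCA of the z-scored metric table (reporting only).
    """
    if mad_k <= 0:
        raise ValueError("mad_k must be positive")
    t = qc.table
    if len(t) < 3:
        raise InsufficientDataError("outlier screen needs at least 3 cells")
    X = t[QC_METRICS].to_numpy(float)
    means = X.mean(axis=0)
    worse = (
        (X[:, 0] < means[0]) & (X[:, 1] < means[1]) & (X[:, 2] > means[2])
    )
    exceed = np.zeros(len(t), dtype=bool)
    for m in range(3):
        col = X[:, m]
        mad = _mad(col)
        if mad > 0:
            exceed |= np.abs(col - np.median(col)) > mad_k * mad
    flagged = set(t.index[worse & exceed])

    # PCA of z-scored metrics, for the report
    sd = X.std(axis=0, ddof=1)
    Z = (X - means) / np.where(sd > 0, sd, 1.0)
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    coords = U * S
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    pca = pd.DataFrame(
        coords, index=t.index, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return OutlierReport(flagged=flagged, pca_coordinates=pca, variance_fractions=frac, mad_k=mad_k)
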