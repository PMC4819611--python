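"""Count-matrix container and on-disk formats.

A dataset is a genes x cells integer matrix plus two annotation tables:
per-gene flags (ERCC-like spike-in, mitochondrial) and per-cell metadata
(embryo of origin, developmental stage, sequencing batch, 2->4-cell
division pattern). On disk the matrix is MatrixMarket coordinate integer
(or a plain numeric TSV) with ``genes.tsv``/``cells.tsv`` sidecars; genes
are rows, cells are columns, following the convention of expression tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import AlignmentError, FormatError

VALID_STAGES = (2, 4, 8, 16, 32)
VALID_DIVISION_PATTERNS = ("ME", "EM", "MM", "EE", "NA")
#: stages at which every sister blastomere of an embryo was captured
COMPLETE_EMBRYO_STAGES = (2, 4, 8)

GENE_COLUMNS = ["gene_id", "is_spikein", "is_mito"]
CELL_COLUMNS = ["cell_id", "embryo", "stage", "batch", "division_pattern"]


@dataclass
class CountMatrix:
    """Integer read counts with gene flags and cell metadata.

    Attributes
    ----------
    values
        ``(n_genes, n_cells)`` array of non-negative integer counts.
    genes
        Frame indexed by unique gene id with boolean columns
        ``is_spikein`` and ``is_mito``.
    cells
        Frame indexed by unique cell id with columns ``embryo`` (str),
        ``stage`` (int, one of 2/4/8/16/32), ``batch`` (str) and
        ``division_pattern`` (one of ME/EM/MM/EE/NA).
    """

    values: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def endogenous_mask(self) -> np.ndarray:
        """Boolean mask of genes that are not spike-ins (includes mito)."""
        return ~self.genes["is_spikein"].to_numpy()

    def spikein_mask(self) -> np.ndarray:
        return self.genes["is_spikein"].to_numpy()

    def mito_mask(self) -> np.ndarray:
        return self.genes["is_mito"].to_numpy()

    def subset_cells(self, keep: np.ndarray | list | pd.Index) -> "CountMatrix":
        """Return a new matrix restricted to the given cell ids or mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cells.index.get_indexer(pd.Index(keep))
            if (idx < 0).any():
                missing = pd.Index(keep)[idx < 0].tolist()
                raise AlignmentError(f"unknown cell ids: {missing[:5]}")
        return CountMatrix(
            values=self.values[:, idx].copy(),
            genes=self.genes.copy(),
            cells=self.cells.iloc[idx].copy(),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise FormatError("count matrix must be 2-dimensional")
        if v.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"matrix shape {v.shape} does not match annotations "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if v.size and (not np.issubdtype(v.dtype, np.integer)):
            if not np.allclose(v, np.round(v)):
                bad = np.argwhere(~np.isclose(v, np.round(v)))[0]
                raise FormatError(
                    f"non-integer count at gene {self.genes.index[bad[0]]!r}, "
                    f"cell {self.cells.index[bad[1]]!r}"
                )
            v = np.round(v).astype(np.int64)
        self.values = v.astype(np.int64, copy=False)
        if v.size and v.min() < 0:
            g, c = np.argwhere(v < 0)[0]
            raise FormatError(
                f"negative count at gene {self.genes.index[g]!r}, "
                f"cell {self.cells.index[c]!r}"
            )
        if self.genes.index.has_duplicates:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise FormatError(f"duplicated gene id {dup!r}")
        if self.cells.index.has_duplicates:
            dup = self.cells.index[self.cells.index.duplicated()][0]
            raise FormatError(f"duplicated cell id {dup!r}")
        for col in ("is_spikein", "is_mito"):
            if col not in self.genes.columns:
                raise FormatError(f"gene table missing column {col!r}")
            self.genes[col] = self.genes[col].astype(bool)
        both = self.genes["is_spikein"] & self.genes["is_mito"]
        if both.any():
            raise FormatError(
                f"gene {both.idxmax()!r} flagged both spike-in and mitochondrial"
            )
        for col in ("embryo", "stage", "batch", "division_pattern"):
            if col not in self.cells.columns:
                raise FormatError(f"cell table missing column {col!r}")
        if len(self.cells):
            stage = self.cells["stage"].astype(int)
            bad_stage = ~stage.isin(VALID_STAGES)
            if bad_stage.any():
                raise FormatError(
                    f"cell {bad_stage.idxmax()!r} has invalid stage "
                    f"{stage[bad_stage].iloc[0]} (expected one of {VALID_STAGES})"
                )
            self.cells["stage"] = stage
            dp = self.cells["division_pattern"].fillna("NA").astype(str)
            bad_dp = ~dp.isin(VALID_DIVISION_PATTERNS)
            if bad_dp.any():
                raise FormatError(
                    f"cell {bad_dp.idxmax()!r} has invalid division pattern "
                    f"{dp[bad_dp].iloc[0]!r}"
                )
            self.cells["division_pattern"] = dp
            complete = stage.isin(COMPLETE_EMBRYO_STAGES)
            emb = self.cells["embryo"].astype(str)
            missing = complete & (emb.isin(("", "nan", "None")) | emb.isna())
            if missing.any():
                raise FormatError(
                    f"cell {missing.idxmax()!r} at a complete-embryo stage "
                    "has no embryo id"
                )
            self.cells["embryo"] = emb
            self.cells["batch"] = self.cells["batch"].astype(str)


def _read_matrix_values(matrix_path: Path) -> np.ndarray:
    suffix = matrix_path.suffix.lower()
    if suffix == ".mtx":
        m = scipy.io.mmread(str(matrix_path))
        return np.asarray(m.todense() if scipy.sparse.issparse(m) else m)
    # plain numeric TSV, genes in rows, no header
    try:
        arr = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse {matrix_path}: {exc}") from exc
    return arr


def read_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a count matrix triplet from disk.

    ``matrix_path`` may be MatrixMarket (``.mtx``) or a headerless numeric
    TSV; the dialect is chosen by extension. The sidecars are
    tab-separated with a header line. All :class:`CountMatrix` invariants
    are enforced; violations raise :class:`FormatError` naming the
    offending record rather than being silently coerced.
    """
    matrix_path, genes_path, cells_path = map(Path, (matrix_path, genes_path, cells_path))
    for p in (matrix_path, genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"file not found: {p}")
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str}, keep_default_na=False)
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise FormatError(f"{genes_path} missing column {col!r}")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise FormatError(f"{cells_path} missing column {col!r}")
    genes = genes.set_index("gene_id")
    cells = cells.set_index("cell_id")
    values = _read_matrix_values(matrix_path)
    if values.size == 0:
        values = values.reshape(len(genes), len(cells))
    if values.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{matrix_path}: matrix is {values.shape}, sidecars describe "
            f"({len(genes)}, {len(cells)})"
        )
    return CountMatrix(values=values, genes=genes, cells=cells)


def write_counts(matrix: CountMatrix, out_prefix) -> dict:
    """Write ``<prefix>.mtx`` + ``<prefix>.genes.tsv`` + ``<prefix>.cells.tsv``.

    Round-trips losslessly through :func:`read_counts`. Returns the paths
    written, keyed ``matrix``/``genes``/``cells``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_prefix.with_suffix(".mtx"),
        "genes": Path(str(out_prefix) + ".genes.tsv"),
        "cells": Path(str(out_prefix) + ".cells.tsv"),
    }
    sparse = scipy.sparse.coo_matrix(matrix.values.astype(np.int64))
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    genes = matrix.genes.reset_index()
    genes.columns = GENE_COLUMNS
    genes.to_csv(paths["genes"], sep="\t", index=False)
    cells = matrix.cells.reset_index()
    cells.columns = CELL_COLUMNS
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths
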