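"""Reading, writing and preprocessing of expression matrices.

The pipeline's universal carrier is :class:`ExpressionMatrix`: a dense
genes x cells matrix with ordered, unique gene and cell identifiers and a
``layer`` tag distinguishing raw counts from library-size log-normalized
values.  Supported on-disk formats are the 10x-style MatrixMarket triplet
(matrix.mtx + genes.tsv + barcodes.tsv) and a dense CSV/TSV with gene IDs
in the first column and cell IDs in the header.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Dense genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Non-negative matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Ordered unique identifiers for rows / columns.
    layer
        ``"counts"`` for raw counts, ``"lognorm"`` for library-size
        normalized log1p values.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.layer not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if np.any(self.values < 0):
            raise ValidationError("expression matrix contains negative entries")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite entries")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValidationError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.cell_ids):
            raise ValidationError(
                f"{self.values.shape[1]} columns but {len(self.cell_ids)} cell ids"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Series(ids)
                dupes = sorted(dupes[dupes.duplicated()].unique())
                raise ValidationError(f"duplicate {name} ids: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )


@dataclass
class GeneGrouping:
    """Partition of retained genes into consecutive rank slices.

    ``group_assignments[g]`` lists gene indices (into the retained matrix)
    of group g; genes are ordered by decreasing highly-variable rank within
    and across groups, and all groups except possibly the last have exactly
    ``group_size`` members.
    """

    group_assignments: list[list[int]]
    group_size: int

    @property
    def r(self) -> int:
        return len(self.group_assignments)


def read_expression(path: str, format: str = "mtx_triplet",
                    genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a counts matrix from disk.

    ``mtx_triplet`` expects ``path`` to be a directory holding
    ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv`` (10x convention,
    genes in rows).  ``dense_csv`` expects a single CSV/TSV file with gene
    IDs in the first column and cell IDs in the header.
    """
    if format == "mtx_triplet":
        mtx = os.path.join(path, "matrix.mtx")
        genes_f = os.path.join(path, "genes.tsv")
        barcodes_f = os.path.join(path, "barcodes.tsv")
        for f in (mtx, genes_f, barcodes_f):
            if not os.path.exists(f):
                raise FileNotFoundError(f"missing sidecar or matrix file: {f}")
        values = np.asarray(mmread(mtx).todense(), dtype=float)
        gene_ids = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    elif format == "dense_csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
    else:
        raise ValueError(f"unknown format {format!r}")
    if not genes_in_rows:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, cell_ids, layer="counts")


def write_expression(X: ExpressionMatrix, path: str,
                     format: str = "mtx_triplet") -> None:
    """Write a matrix so that :func:`read_expression` reads it back bit-exactly."""
    if format == "mtx_triplet":
        os.makedirs(path, exist_ok=True)
        coo = coo_matrix(X.values)
        is_int = np.all(X.values == np.round(X.values))
        field = "integer" if is_int else "real"
        if is_int:
            coo = coo.astype(np.int64)
        mmwrite(os.path.join(path, "matrix.mtx"), coo, field=field)
        pd.Series(X.gene_ids).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False)
        pd.Series(X.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)
    elif format == "dense_csv":
        pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_genes(X: ExpressionMatrix,
                 min_cell_fraction: float = 0.03) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in at least ``min_cell_fraction`` of cells.

    The threshold is inclusive: a gene detected in exactly the threshold
    fraction of cells is retained.  Gene order is preserved.
    """
    if X.layer != "counts":
        raise ValidationError("filter_genes expects a counts-layer matrix")
    frac = np.count_nonzero(X.values, axis=1) / X.n_cells
    keep = np.flatnonzero(frac >= min_cell_fraction)
    if keep.size == 0:
        raise ValidationError(
            "all genes removed by detection filter; lower min_cell_fraction")
    return X.subset_genes(keep)


def log_normalize(X: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each cell to ``scale_factor`` and apply ln(1+x).

    Entry (i, j) becomes ``ln(1 + c_ij * scale_factor / L_j)`` where L_j is
    cell j's total count.  Zeros map exactly to zeros.
    """
    if X.layer != "counts":
        raise ValidationError("log_normalize expects a counts-layer matrix")
    totals = X.values.sum(axis=0)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        names = [X.cell_ids[i] for i in bad[:10]]
        raise ValidationError(f"cells with zero total count: {names}")
    vals = np.log1p(X.values * (scale_factor / totals)[None, :])
    return replace(X, values=vals, layer="lognorm")


def rank_hvgs_vst(X: ExpressionMatrix, loess_span: float = 0.3) -> np.ndarray:
    """Rank genes by decreasing standardized variance (VST procedure).

    Fits a local regression of log10(variance) on log10(mean) across genes
    (span 0.3), standardizes each gene's counts by the predicted standard
    deviation with standardized values clipped at sqrt(n_cells), and ranks
    genes by the variance of the clipped standardized values.  Operates on
    raw counts; deterministic.
    """
    if X.layer != "counts":
        raise ValidationError("rank_hvgs_vst expects a counts-layer matrix")
    if X.n_cells < 2:
        raise ValidationError("need at least 2 cells to rank variable genes")
    vals = X.values
    n = X.n_cells
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    positive = var > 0
    if positive.sum() < 10:
        raise ValidationError("fewer than 10 genes with positive variance")
    std_var = np.zeros(X.n_genes)
    logm = np.log10(mean[positive])
    logv = np.log10(var[positive])
    # locally weighted linear fit of log-variance on log-mean (span 0.3);
    # statsmodels lowess returns fitted values sorted by x, map them back
    order = np.argsort(logm, kind="stable")
    fitted_sorted = sm.nonparametric.lowess(
        logv[order], logm[order], frac=loess_span, return_sorted=False)
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted
    exp_sd = np.sqrt(10.0 ** fitted)
    clip = np.sqrt(n)
    sub = vals[positive, :]
    z = (sub - mean[positive][:, None]) / exp_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    # variance of clipped standardized values around the clipped mean
    std_var[positive] = z.var(axis=1, ddof=1)
    return np.argsort(-std_var, kind="stable")


def group_genes(ranked_genes, group_size: int = 2000) -> GeneGrouping:
    """Slice a ranked gene index list into consecutive groups of ``group_size``.

    The final group holds the remainder and may be smaller.
    """
    ranked = list(map(int, ranked_genes))
    if not ranked:
        raise ValueError("ranked_genes is empty")
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    groups = [ranked[i:i + group_size] for i in range(0, len(ranked), group_size)]
    return GeneGrouping(group_assignments=groups, group_size=group_size)


def preprocess(X: ExpressionMatrix, min_cell_fraction: float = 0.03,
               n_top_genes: int | None = 2000,
               scale_factor: float = 1e4) -> ExpressionMatrix:
    """Standard preprocessing: detection filter, HVG ranking, log-normalize.

    Returns a lognorm-layer matrix whose rows are reordered by decreasing
    highly-variable rank (truncated to ``n_top_genes`` when given), so that
    downstream grouping is a plain consecutive slicing of rows.
    """
    Xf = filter_genes(X, min_cell_fraction)
    ranked = rank_hvgs_vst(Xf)
    if n_top_genes is not None:
        ranked = ranked[:n_top_genes]
    return log_normalize(Xf.subset_genes(ranked), scale_factor)
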