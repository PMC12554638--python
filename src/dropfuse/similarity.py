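"""Cell-cell and gene-gene similarity matrices for a block.

Cell similarity fuses Pearson, Spearman and cosine similarities between
cell expression columns: each metric matrix is row-wise min-max scaled,
symmetrized as (S' + S'^T)/2, and the three are combined by an elementwise
geometric mean.  Gene similarity is the Jaccard index of the genes'
expression support sets after binarizing at > 0.  Both carry a unit
diagonal and live in [0, 1] (the fused cell similarity) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class SimilarityMatrix:
    """Square similarity matrix over cells or genes."""

    values: np.ndarray
    axis: str  # "cell" or "gene"

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _pairwise_correlation(V: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; constant columns give 0."""
    V = V - V.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(V, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    C = (V / safe).T @ (V / safe)
    C[norms == 0, :] = 0.0
    C[:, norms == 0] = 0.0
    return np.clip(C, -1.0, 1.0)


def metric_similarity(M: np.ndarray, metric: str) -> SimilarityMatrix:
    """Cell-cell similarity under one metric, diagonal forced to 1.

    ``M`` is a genes x cells block; cell vectors are its columns.  Constant
    cell vectors have undefined correlation and contribute 0 off-diagonal.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[1] < 2:
        raise ValueError("need at least 2 cells for a similarity matrix")
    if metric == "pearson":
        S = _pairwise_correlation(M)
    elif metric == "spearman":
        R = np.apply_along_axis(rankdata, 0, M)
        S = _pairwise_correlation(R)
    elif metric == "cosine":
        norms = np.linalg.norm(M, axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        S = (M / safe).T @ (M / safe)
        S[norms == 0, :] = 0.0
        S[:, norms == 0] = 0.0
        S = np.clip(S, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, axis="cell")


def rowwise_minmax(S: SimilarityMatrix) -> SimilarityMatrix:
    """Scale each row to [0, 1] by its own min and max.

    The result is generally asymmetric.  A constant row (max == min) maps
    to 0 off-diagonal with the diagonal kept at 1, preserving
    self-similarity without dividing by zero.
    """
    V = S.values
    lo = V.min(axis=1, keepdims=True)
    hi = V.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = (span == 0).ravel()
    out = (V - lo) / np.where(span == 0, 1.0, span)
    if degenerate.any():
        out[degenerate, :] = 0.0
        idx = np.flatnonzero(degenerate)
        out[idx, idx] = 1.0
    return SimilarityMatrix(values=out, axis=S.axis)


def symmetrize(S: SimilarityMatrix) -> SimilarityMatrix:
    """Return (S + S^T) / 2."""
    return SimilarityMatrix(values=0.5 * (S.values + S.values.T), axis=S.axis)


def fuse_cell_similarity(M: np.ndarray) -> SimilarityMatrix:
    """Fused cell-cell similarity of a block.

    Pipeline per metric d in {pearson, spearman, cosine}: similarity ->
    row-wise min-max -> symmetrize; then the elementwise geometric mean of
    the three symmetrized matrices.  Any zero factor annihilates the fused
    entry.
    """
    factors = []
    for metric in ("pearson", "spearman", "cosine"):
        S = metric_similarity(M, metric)
        factors.append(symmetrize(rowwise_minmax(S)).values)
    prod = factors[0] * factors[1] * factors[2]
    fused = np.cbrt(prod)
    return SimilarityMatrix(values=fused, axis="cell")


def gene_jaccard(M: np.ndarray) -> SimilarityMatrix:
    """Jaccard similarity between gene support sets of a block.

    Depends only on the zero pattern: the block is binarized at > 0 and
    SG(i, j) = |supp_i & supp_j| / |supp_i | supp_j| with diagonal 1.  Two
    genes with empty support get similarity 0 off-diagonal.
    """
    M = np.asarray(M)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 genes for a gene similarity matrix")
    B = (M > 0).astype(float)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union == 0, 1.0, union), 0.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, axis="gene")
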