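"""Classification of zeros into technical dropouts and biological zeros.

Within a gene group, each zero entry is judged by the gene's expression
rate R1 in the cell cluster containing it (fraction of that cluster's
cells with value > 0) against the non-zero rates R2 of the cluster block
and of the whole group:

    mark 1 (false zero, impute)  if R1 >= min(R2_block, R2_group)
    mark 0 (true zero, keep)     if 0 < R1 <= min(R2_block, R2_group) / 10

Zeros satisfying neither clause — including genes entirely silent in the
cluster — stay unmarked: they are excluded from training and never
imputed, a deliberate guard against over-imputation.  Marks are computed
for the three best-silhouette clusterings of the group and combined by
strict intersection: the prediction set is the intersection of false-zero
marks, the training set the intersection of true-zero marks united with
all non-zero entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNMARKED = -1


@dataclass
class RateSummary:
    """Expression rates of one gene group under one clustering."""

    R1: np.ndarray        # genes x clusters, per-cluster expression rate
    R2_block: np.ndarray  # per-cluster non-zero fraction of the block
    R2_group: float       # non-zero fraction of the whole group


@dataclass
class MaskSets:
    """Disjoint training / prediction coordinate sets of one gene group."""

    train_mask: np.ndarray    # boolean genes x cells
    predict_mask: np.ndarray  # boolean genes x cells
    per_k_marks: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(self.train_mask & self.predict_mask):
            raise ValueError("training and prediction sets overlap")

    @property
    def train_coords(self) -> set[tuple[int, int]]:
        return set(zip(*np.nonzero(self.train_mask)))

    @property
    def predict_coords(self) -> set[tuple[int, int]]:
        return set(zip(*np.nonzero(self.predict_mask)))

    def to_frame(self, gene_ids, cell_ids):
        """Three-column (gene_id, cell_id, set) table for CSV export."""
        import pandas as pd
        rows = []
        for mask, name in ((self.train_mask, "train"),
                           (self.predict_mask, "predict")):
            gi, cj = np.nonzero(mask)
            rows.append(pd.DataFrame({
                "gene_id": [gene_ids[i] for i in gi],
                "cell_id": [cell_ids[j] for j in cj],
                "set": name}))
        return pd.concat(rows, ignore_index=True)


def expression_rates(G: np.ndarray, labels: np.ndarray) -> RateSummary:
    """Per-gene per-cluster expression rates and block/group non-zero rates."""
    G = np.asarray(G)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != G.shape[1]:
        raise ValueError("one label per cell required")
    k = labels.max() + 1
    nz = G > 0
    R1 = np.empty((G.shape[0], k))
    R2_block = np.empty(k)
    for c in range(k):
        cols = labels == c
        n_c = int(cols.sum())
        if n_c == 0:
            raise ValueError(f"cluster {c} is empty")
        R1[:, c] = nz[:, cols].sum(axis=1) / n_c
        R2_block[c] = nz[:, cols].sum() / (G.shape[0] * n_c)
    return RateSummary(R1=R1, R2_block=R2_block,
                       R2_group=float(nz.sum() / G.size))


def mark_cluster_zeros(G: np.ndarray, labels: np.ndarray,
                       rates: RateSummary | None = None) -> np.ndarray:
    """Mark every zero entry of the group under one clustering.

    Returns an int8 genes x cells matrix: 1 for false zeros, 0 for true
    zeros, -1 for unmarked entries (non-zeros and zeros meeting neither
    clause).  Depends only on the zero pattern and the labels.
    """
    G = np.asarray(G)
    labels = np.asarray(labels, dtype=int)
    if rates is None:
        rates = expression_rates(G, labels)
    thresh = np.minimum(rates.R2_block, rates.R2_group)  # per cluster
    r1 = rates.R1[:, labels]              # genes x cells, rate of own cluster
    t = thresh[labels][None, :]
    marks = np.full(G.shape, UNMARKED, dtype=np.int8)
    is_zero = G == 0
    marks[is_zero & (r1 >= t)] = 1
    marks[is_zero & (r1 > 0) & (r1 <= t / 10.0)] = 0
    return marks


def consensus_sets(per_k_marks: dict[int, np.ndarray],
                   nonzero_mask: np.ndarray) -> MaskSets:
    """Intersect marks across clusterings into training / prediction sets.

    Prediction set: entries marked 1 under every clustering.  Training
    set: entries marked 0 under every clustering, united with all non-zero
    entries.  Intersecting over more clusterings can only shrink the
    prediction set.
    """
    if not per_k_marks:
        raise ValueError("need marks for at least one clustering")
    marks = list(per_k_marks.values())
    predict = np.ones_like(nonzero_mask, dtype=bool)
    true_zero = np.ones_like(nonzero_mask, dtype=bool)
    for m in marks:
        predict &= m == 1
        true_zero &= m == 0
    train = true_zero | nonzero_mask
    return MaskSets(train_mask=train, predict_mask=predict,
                    per_k_marks=dict(per_k_marks))


def mark_group(G: np.ndarray, assignments: dict[int, np.ndarray]) -> MaskSets:
    """Full marking of one gene group given its top-silhouette clusterings.

    ``assignments`` maps each selected cluster count k to per-cell labels;
    rates are recomputed for every k since the blocks differ.
    """
    per_k = {k: mark_cluster_zeros(G, labels)
             for k, labels in assignments.items()}
    return consensus_sets(per_k, np.asarray(G) > 0)
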