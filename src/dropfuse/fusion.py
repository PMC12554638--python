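"""Feature fusion, dropout prediction and pipeline orchestration.

For every gene-group x cell-cluster block, the non-linear latents (Z_g,
Z_c from the dual VGAEs) and linear factors (W, H from NMF) are fused per
entry: the feature vector of coordinate (i, j) is the concatenation of
gene i's latent row, cell j's latent row, gene i's NMF loading and cell
j's NMF coefficient column.  A per-block fully connected network is
trained on the block's training entries (non-zeros plus consensus true
zeros, regression target the log-normalized value) and queried at the
consensus false zeros only.  Predictions are clamped at zero and merged
back; every non-predicted entry stays bit-identical to the input.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neural_network import MLPRegressor

from . import io as dio
from .io import ExpressionMatrix, group_genes, preprocess
from .marking import MaskSets, mark_group
from .nmf import fit_nmf
from .partition import (Block, BlockPartition, partition_matrix, pca_embed,
                        select_k)
from .similarity import fuse_cell_similarity, gene_jaccard
from .vgae import VGAEConfig, train_vgae_pair

logger = logging.getLogger(__name__)

MODES = ("full", "vgae_only", "mf_only")


@dataclass
class FusionConfig:
    """Hyperparameters of the per-block fully connected predictor."""

    hidden_layers: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-3
    epochs: int = 100
    validation_fraction: float = 0.1
    early_stopping_patience: int = 10
    min_train_entries: int = 200
    max_train_entries: int | None = 50000
    seed: int = 0


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end imputation pipeline."""

    min_cell_fraction: float = 0.03
    n_top_genes: int | None = 2000
    scale_factor: float = 1e4
    group_size: int = 2000
    pca_components: int = 50
    k_min: int = 4
    k_max: int = 15
    n_neighbors: int = 15
    nmf_rank: int = 16
    omega: float = 0.01
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    vgae: VGAEConfig = field(default_factory=VGAEConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed,
                       vgae=replace(self.vgae, seed=seed),
                       fusion=replace(self.fusion, seed=seed))


@dataclass
class FeatureBundle:
    """Per-block learned features aligned to block gene/cell order."""

    Z_g: np.ndarray | None
    Z_c: np.ndarray | None
    W: np.ndarray | None
    H: np.ndarray | None


@dataclass
class ImputationResult:
    imputed: ExpressionMatrix
    predicted_mask: np.ndarray  # boolean genes x cells over the output matrix
    run_manifest: dict

    @property
    def predicted_coords(self) -> set[tuple[int, int]]:
        return set(zip(*np.nonzero(self.predicted_mask)))


def assemble_features(bundle: FeatureBundle, coords: np.ndarray) -> np.ndarray:
    """Build the per-entry feature table for block-local coordinates.

    ``coords`` is an (n, 2) array of (gene_row, cell_col) indices local to
    the block.  Row layout: [Z_g[i] | Z_c[j] | W[i, :] | H[:, j]], with
    absent sources (ablation modes) simply omitted.
    """
    coords = np.asarray(coords, dtype=int)
    gi, cj = coords[:, 0], coords[:, 1]
    parts = []
    if bundle.Z_g is not None:
        if gi.size and (gi.max() >= bundle.Z_g.shape[0]
                        or cj.max() >= bundle.Z_c.shape[0]):
            raise IndexError("coordinate outside block feature range")
        parts += [bundle.Z_g[gi], bundle.Z_c[cj]]
    if bundle.W is not None:
        if gi.size and (gi.max() >= bundle.W.shape[0]
                        or cj.max() >= bundle.H.shape[1]):
            raise IndexError("coordinate outside block feature range")
        parts += [bundle.W[gi], bundle.H[:, cj].T]
    if not parts:
        raise ValueError("feature bundle is empty")
    return np.concatenate(parts, axis=1)


class ConstantPredictor:
    """Degenerate predictor for (near-)constant training targets.

    Early stopping on R-squared is meaningless when the target has no
    variance, so a constant fit is returned directly.
    """

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.full(features.shape[0], self.value)


def train_fusion(features: np.ndarray, targets: np.ndarray,
                 config: FusionConfig):
    """Train the per-block MLP regressor; None when data are insufficient."""
    n = features.shape[0]
    if n < config.min_train_entries:
        logger.warning(
            "block has only %d training entries (< %d); falling back to "
            "no imputation", n, config.min_train_entries)
        return None
    if np.ptp(targets) < 1e-12 * max(1.0, abs(float(targets[0]))):
        return ConstantPredictor(targets[0])
    rng = np.random.default_rng(config.seed)
    if config.max_train_entries is not None and n > config.max_train_entries:
        keep = rng.choice(n, size=config.max_train_entries, replace=False)
        features, targets = features[keep], targets[keep]
        n = config.max_train_entries
    use_es = n >= 50
    model = MLPRegressor(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation="relu", solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        early_stopping=use_es,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.early_stopping_patience,
        random_state=int(rng.integers(2**31 - 1)))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(features, targets)
    return model


def _block_seed(seed: int, g: int, c: int) -> int:
    return int((seed + 7919 * (g + 1) + 104729 * (c + 1)) % (2**31 - 1))


def _learn_block_features(block: Block, mode: str,
                          config: PipelineConfig) -> FeatureBundle | None:
    """Run VGAE and/or NMF on one block; None when the block is degenerate."""
    vals = block.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        logger.warning("block (%d, %d) too small for feature learning: %s",
                       block.group, block.cluster, vals.shape)
        return None
    seed = _block_seed(config.seed, block.group, block.cluster)
    Z_g = Z_c = W = H = None
    if mode in ("full", "vgae_only"):
        SG = gene_jaccard(vals)
        SC = fuse_cell_similarity(vals)
        vcfg = replace(config.vgae, seed=seed)
        latents = train_vgae_pair(SG.values, SC.values, vals, vcfg)
        Z_g, Z_c = latents.Z_g, latents.Z_c
    if mode in ("full", "mf_only"):
        rank = min(config.nmf_rank, min(vals.shape))
        factors = fit_nmf(vals, rank=rank, omega=config.omega,
                          max_iter=config.nmf_max_iter, tol=config.nmf_tol,
                          seed=seed)
        W, H = factors.W, factors.H
    return FeatureBundle(Z_g=Z_g, Z_c=Z_c, W=W, H=H)


def predict_and_merge(Xp: ExpressionMatrix, partition: BlockPartition,
                      group_masks: list[MaskSets], bundles: dict,
                      predictors: dict, group_rows: list[np.ndarray],
                      manifest: dict) -> ImputationResult:
    """Insert per-block predictions at the consensus false zeros.

    Every coordinate outside the prediction set keeps its input value
    bit-identically; predictions are clamped at zero in lognorm space.
    """
    imputed = Xp.values.copy()
    predicted = np.zeros_like(imputed, dtype=bool)
    for (g, c), block in partition.blocks.items():
        model = predictors.get((g, c))
        bundle = bundles.get((g, c))
        if model is None or bundle is None:
            continue
        rows = group_rows[g]
        local = group_masks[g].predict_mask[np.ix_(
            block.gene_idx - rows[0], block.cell_idx)]
        coords = np.argwhere(local)
        if coords.size == 0:
            continue
        feats = assemble_features(bundle, coords)
        preds = np.maximum(model.predict(feats), 0.0)
        gi = block.gene_idx[coords[:, 0]]
        cj = block.cell_idx[coords[:, 1]]
        if predicted[gi, cj].any():
            raise ValueError("blocks claim overlapping coordinates")
        imputed[gi, cj] = preds
        predicted[gi, cj] = True
    out = replace(Xp, values=imputed)
    return ImputationResult(imputed=out, predicted_mask=predicted,
                            run_manifest=manifest)


def run_pipeline(X: ExpressionMatrix, config: PipelineConfig | None = None,
                 mode: str = "full") -> ImputationResult:
    """End-to-end imputation.

    Counts input is preprocessed (detection filter, HVG ranking and
    truncation, log-normalization); a lognorm input is taken as already
    preprocessed with rows in decreasing HVG rank.  Stages: gene grouping
    -> per-group spectral clustering with silhouette k-selection -> block
    partition by the top group's best clustering -> per-group consensus
    zero marking -> per-block feature learning (VGAE and/or NMF per
    ``mode``) -> per-block fused prediction of false zeros.
    """
    if config is None:
        config = PipelineConfig()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    t0 = time.time()
    if X.layer == "counts":
        Xp = preprocess(X, config.min_cell_fraction, config.n_top_genes,
                        config.scale_factor)
    else:
        Xp = X
    grouping = group_genes(list(range(Xp.n_genes)), config.group_size)
    group_rows = [np.asarray(g, dtype=int) for g in grouping.group_assignments]

    selections = []
    for g, rows in enumerate(group_rows):
        G = Xp.values[rows, :]
        E = pca_embed(G, config.pca_components, seed=config.seed)
        sel = select_k(E, range(config.k_min, config.k_max + 1),
                       seed=config.seed, n_neighbors=config.n_neighbors)
        selections.append(sel)
        logger.info("group %d: best k=%d (silhouette %.3f), top3=%s",
                    g, sel.best_k, sel.scores[sel.best_k], sel.top3_k)

    clusters = selections[0].assignments[selections[0].best_k]
    partition = partition_matrix(Xp, grouping, clusters)

    group_masks = []
    for g, rows in enumerate(group_rows):
        sel = selections[g]
        assignments = {k: sel.assignments[k].labels for k in sel.top3_k}
        group_masks.append(mark_group(Xp.values[rows, :], assignments))

    bundles, predictors, block_info = {}, {}, {}
    for (g, c), block in sorted(partition.blocks.items()):
        bundle = _learn_block_features(block, mode, config)
        bundles[(g, c)] = bundle
        if bundle is None:
            continue
        rows = group_rows[g]
        local_train = group_masks[g].train_mask[np.ix_(
            block.gene_idx - rows[0], block.cell_idx)]
        coords = np.argwhere(local_train)
        targets = block.values[coords[:, 0], coords[:, 1]]
        feats = assemble_features(bundle, coords) if coords.size else \
            np.empty((0, 1))
        fcfg = replace(config.fusion,
                       seed=_block_seed(config.seed, block.group,
                                        block.cluster))
        predictors[(g, c)] = train_fusion(feats, targets, fcfg)
        block_info[f"{g},{c}"] = {
            "shape": list(block.values.shape),
            "n_train": int(coords.shape[0]),
            "n_features": int(feats.shape[1]) if coords.size else 0,
            "fallback": predictors[(g, c)] is None,
        }

    manifest = {
        "mode": mode,
        "seed": config.seed,
        "n_genes": Xp.n_genes,
        "n_cells": Xp.n_cells,
        "r_groups": grouping.r,
        "best_k": int(clusters.k),
        "top3_k_per_group": [list(s.top3_k) for s in selections],
        "config": {
            "group_size": config.group_size,
            "pca_components": config.pca_components,
            "k_range": [config.k_min, config.k_max],
            "n_neighbors": config.n_neighbors,
            "nmf_rank": config.nmf_rank, "omega": config.omega,
            "vgae": vars(config.vgae),
            "fusion": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config.fusion).items()},
        },
        "blocks": block_info,
        "evaluation_scale": "lognorm",
    }
    result = predict_and_merge(Xp, partition, group_masks, bundles,
                               predictors, group_rows, manifest)
    result.run_manifest["runtime_s"] = round(time.time() - t0, 2)
    n_pred = int(result.predicted_mask.sum())
    logger.info("imputed %d entries in %.1fs (mode=%s)",
                n_pred, result.run_manifest["runtime_s"], mode)
    return result
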