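"""Dual variational graph autoencoders for non-linear feature learning.

Two VGAEs are trained jointly per block: a gene-side encoder over the gene
Jaccard similarity graph with the block's log-expression rows as node
features, and a cell-side encoder over the fused cell similarity graph
with the transposed block as features.  Each encoder is a two-layer GCN —
a shared hidden layer followed by parallel mu and log-sigma heads:

    mu        = S~ . ReLU(S~ A W0) . Wmu
    log sigma = S~ . ReLU(S~ A W0) . Wsig

with S~ = D^{-1/2} S D^{-1/2}.  Latents are sampled by reparameterization
(z = mu + eps * sigma) during training and taken at z = mu for downstream
features.  The shared inner-product decoder A~ = Z_g Z_c^T reconstructs
the block, trained against the loss

    L = lambda * L_mse + (1 - lambda) * L_cos  (+ beta * KL, beta = 0)

where L_mse is the mean squared entry error and L_cos the mean over rows
of one minus the cosine between original and reconstructed row.  All
gradients are analytic; optimization is Adam.  Everything is seeded and
bit-reproducible at a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VGAEConfig:
    hidden_dim: int = 64
    latent_dim: int = 16
    lambda_weight: float = 0.5
    kl_weight: float = 0.0
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.hidden_dim <= 0 or self.latent_dim <= 0:
            raise ValueError("dims must be positive")


@dataclass
class EncoderParams:
    """Weights of one two-layer GCN encoder."""

    W0: np.ndarray   # features -> hidden
    Wmu: np.ndarray  # hidden -> latent (mean head)
    Wsig: np.ndarray  # hidden -> latent (log-sigma head)


@dataclass
class LatentFactors:
    """Evaluation-mode latents (z = mu) with the underlying heads."""

    Z_g: np.ndarray
    Z_c: np.ndarray
    mu_g: np.ndarray
    logsig_g: np.ndarray
    mu_c: np.ndarray
    logsig_c: np.ndarray
    loss_history: list[dict] = field(default_factory=list)

    def history_frame(self):
        """Training log (epoch, l_mse, l_cos, loss) for CSV export."""
        import pandas as pd
        return pd.DataFrame(self.loss_history)


def normalize_similarity(S: np.ndarray) -> np.ndarray:
    """Symmetric graph normalization S~ = D^{-1/2} S D^{-1/2}.

    Zero diagonal entries receive a unit self-loop first, so every row sum
    is strictly positive.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    S = S.copy()
    diag = np.diag_indices_from(S)
    zero_diag = S[diag] == 0
    S[diag] = np.where(zero_diag, 1.0, S[diag])
    d = S.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return S * inv_sqrt[:, None] * inv_sqrt[None, :]


def encode(S_tilde: np.ndarray, A: np.ndarray,
           params: EncoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass of the two-layer GCN encoder (deterministic)."""
    if A.shape[0] != S_tilde.shape[0]:
        raise ValueError(
            f"feature rows ({A.shape[0]}) must match graph nodes "
            f"({S_tilde.shape[0]})")
    if A.shape[1] != params.W0.shape[0]:
        raise ValueError(
            f"feature dim ({A.shape[1]}) must match W0 rows "
            f"({params.W0.shape[0]})")
    hidden = np.maximum(S_tilde @ A @ params.W0, 0.0)
    smoothed = S_tilde @ hidden
    return smoothed @ params.Wmu, smoothed @ params.Wsig


def reparameterize(mu: np.ndarray, logsig: np.ndarray,
                   eps: np.ndarray | None = None,
                   seed: int | None = None) -> np.ndarray:
    """z = mu + eps * sigma with eps ~ N(0, 1); eps = None means z = mu."""
    if mu.shape != logsig.shape:
        raise ValueError("mu and log sigma shapes differ")
    if eps is None:
        if seed is None:
            return mu.copy()
        eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return mu + eps * np.exp(logsig)


def decode(Z_g: np.ndarray, Z_c: np.ndarray) -> np.ndarray:
    """Inner-product decoder: genes x cells reconstruction Z_g Z_c^T."""
    if Z_g.shape[1] != Z_c.shape[1]:
        raise ValueError(
            f"latent dims differ: {Z_g.shape[1]} vs {Z_c.shape[1]}")
    return Z_g @ Z_c.T


def _cosine_loss_and_grad(A: np.ndarray, At: np.ndarray):
    """Row-wise 1 - cos term: value and gradient w.r.t. the reconstruction."""
    m = A.shape[0]
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(At, axis=1)
    ok = (na > 0) & (nb > 0)
    cos = np.zeros(m)
    dots = np.einsum("ij,ij->i", A, At)
    cos[ok] = dots[ok] / (na[ok] * nb[ok])
    loss = float(np.mean(1.0 - cos))  # zero-norm rows contribute 1
    grad = np.zeros_like(At)
    grad[ok] = -(A[ok] / (na[ok] * nb[ok])[:, None]
                 - (cos[ok] / nb[ok] ** 2)[:, None] * At[ok]) / m
    return loss, grad


def vgae_loss(A: np.ndarray, At: np.ndarray, lambda_weight: float,
              beta: float = 0.0, kl_terms=None) -> float:
    """Reconstruction loss lambda*L_mse + (1-lambda)*L_cos (+ beta*KL).

    ``kl_terms`` is an optional list of (mu, logsig) pairs entering the KL
    penalty; ignored when beta is 0.
    """
    if A.shape != At.shape:
        raise ValueError("original and reconstruction shapes differ")
    l_mse = float(np.mean((A - At) ** 2))
    l_cos, _ = _cosine_loss_and_grad(A, At)
    total = lambda_weight * l_mse + (1.0 - lambda_weight) * l_cos
    if beta > 0 and kl_terms:
        kl = 0.0
        for mu, logsig in kl_terms:
            kl += 0.5 * np.mean(
                np.sum(np.exp(2 * logsig) + mu ** 2 - 1.0 - 2 * logsig, axis=1))
        total += beta * kl
    return total


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _EncoderState:
    """One GCN encoder side with cached forward intermediates."""

    def __init__(self, S_tilde, A, hidden_dim, latent_dim, rng):
        self.S = S_tilde
        self.P = S_tilde @ A  # constant across epochs
        f = A.shape[1]
        self.params = EncoderParams(
            W0=_glorot(rng, f, hidden_dim),
            Wmu=_glorot(rng, hidden_dim, latent_dim),
            Wsig=_glorot(rng, hidden_dim, latent_dim))

    def forward(self):
        self.pre = self.P @ self.params.W0
        self.hidden = np.maximum(self.pre, 0.0)
        self.smoothed = self.S @ self.hidden
        self.mu = self.smoothed @ self.params.Wmu
        self.logsig = self.smoothed @ self.params.Wsig
        return self.mu, self.logsig

    def backward(self, dmu, dlogsig):
        dWmu = self.smoothed.T @ dmu
        dWsig = self.smoothed.T @ dlogsig
        dsmoothed = dmu @ self.params.Wmu.T + dlogsig @ self.params.Wsig.T
        dhidden = self.S.T @ dsmoothed
        dpre = dhidden * (self.pre > 0)
        dW0 = self.P.T @ dpre
        return [dW0, dWmu, dWsig]

    def weights(self):
        return [self.params.W0, self.params.Wmu, self.params.Wsig]


def train_vgae_pair(SG: np.ndarray, SC: np.ndarray, logM: np.ndarray,
                    config: VGAEConfig) -> LatentFactors:
    """Jointly train the gene- and cell-side VGAEs of one block.

    The gene encoder runs on the normalized gene similarity graph with the
    block's log-expression as node features; the cell encoder runs on the
    normalized cell similarity graph with the transposed block.  Both feed
    the shared inner-product decoder, whose reconstruction of the block is
    scored by :func:`vgae_loss`.  Returns evaluation-mode latents (z = mu)
    and a per-epoch loss trace.
    """
    logM = np.asarray(logM, dtype=float)
    n_g, n_c = logM.shape
    if SG.shape != (n_g, n_g):
        raise ValueError(f"SG must be {n_g}x{n_g}, got {SG.shape}")
    if SC.shape != (n_c, n_c):
        raise ValueError(f"SC must be {n_c}x{n_c}, got {SC.shape}")
    rng = np.random.default_rng(config.seed)
    Sg = normalize_similarity(SG)
    Sc = normalize_similarity(SC)
    gene = _EncoderState(Sg, logM, config.hidden_dim, config.latent_dim, rng)
    cell = _EncoderState(Sc, logM.T, config.hidden_dim, config.latent_dim, rng)
    opt = _Adam(gene.weights() + cell.weights(), config.learning_rate)
    lam, beta = config.lambda_weight, config.kl_weight
    N = logM.size
    history: list[dict] = []
    for epoch in range(config.epochs):
        mu_g, ls_g = gene.forward()
        mu_c, ls_c = cell.forward()
        eps_g = rng.standard_normal(mu_g.shape)
        eps_c = rng.standard_normal(mu_c.shape)
        sig_g, sig_c = np.exp(ls_g), np.exp(ls_c)
        z_g = mu_g + eps_g * sig_g
        z_c = mu_c + eps_c * sig_c
        At = z_g @ z_c.T
        l_mse = float(np.mean((logM - At) ** 2))
        l_cos, dAt_cos = _cosine_loss_and_grad(logM, At)
        loss = lam * l_mse + (1 - lam) * l_cos
        dAt = lam * 2.0 * (At - logM) / N + (1 - lam) * dAt_cos
        dz_g = dAt @ z_c
        dz_c = dAt.T @ z_g
        dmu_g, dls_g = dz_g, dz_g * eps_g * sig_g
        dmu_c, dls_c = dz_c, dz_c * eps_c * sig_c
        if beta > 0:
            loss += beta * 0.5 * (
                float(np.mean(np.sum(sig_g**2 + mu_g**2 - 1 - 2*ls_g, axis=1)))
                + float(np.mean(np.sum(sig_c**2 + mu_c**2 - 1 - 2*ls_c, axis=1))))
            dmu_g = dmu_g + beta * mu_g / n_g
            dls_g = dls_g + beta * (sig_g ** 2 - 1.0) / n_g
            dmu_c = dmu_c + beta * mu_c / n_c
            dls_c = dls_c + beta * (sig_c ** 2 - 1.0) / n_c
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite VGAE loss at epoch {epoch} "
                f"(lambda={lam}, lr={config.learning_rate})")
        history.append({"epoch": epoch, "l_mse": l_mse, "l_cos": l_cos,
                        "loss": loss})
        grads = gene.backward(dmu_g, dls_g) + cell.backward(dmu_c, dls_c)
        opt.step(grads)
    mu_g, ls_g = gene.forward()
    mu_c, ls_c = cell.forward()
    return LatentFactors(Z_g=mu_g, Z_c=mu_c, mu_g=mu_g, logsig_g=ls_g,
                         mu_c=mu_c, logsig_c=ls_c, loss_history=history)
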