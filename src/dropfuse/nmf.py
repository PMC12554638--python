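"""L2-regularized non-negative matrix factorization by multiplicative updates.

A block's log-expression matrix X (m x n) is factored as X ~ W H with
W (m x rank) holding linear gene features and H (rank x n) linear cell
features, minimizing

    (1/2) ||X - W H||_F^2 + (w1/2) ||W||_F^2 + (w2/2) ||H||_F^2

with w1 = omega * m and w2 = omega * n.  The Lee-Seung-style multiplicative
rules

    W <- W * (X H^T) / (W H H^T + w1 W)
    H <- H * (W^T X) / (W^T W H + w2 H)

preserve non-negativity and decrease the objective monotonically (they are
Majorization-Minimization steps).  W is updated first; H uses the fresh W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FLOOR = 1e-12  # denominator floor; keeps updates finite without sign flips

OMEGA_GRID = (0.001, 0.01, 0.1, 0.25)  # candidate regularization strengths


@dataclass
class NMFFactors:
    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0


def nmf_objective(X: np.ndarray, W: np.ndarray, H: np.ndarray,
                  omega: float) -> float:
    """Regularized Frobenius objective with w1 = omega*m, w2 = omega*n."""
    if np.any(X < 0) or np.any(W < 0) or np.any(H < 0):
        raise ValueError("NMF inputs must be non-negative")
    m, n = X.shape
    resid = X - W @ H
    return float(
        0.5 * np.sum(resid ** 2)
        + 0.5 * omega * m * np.sum(W ** 2)
        + 0.5 * omega * n * np.sum(H ** 2))


def nmf_update_step(X: np.ndarray, W: np.ndarray, H: np.ndarray,
                    omega1: float, omega2: float):
    """One multiplicative update: W first, then H using the updated W."""
    num_w = X @ H.T
    den_w = W @ (H @ H.T) + omega1 * W
    W_new = W * num_w / np.maximum(den_w, _FLOOR)
    num_h = W_new.T @ X
    den_h = (W_new.T @ W_new) @ H + omega2 * H
    H_new = H * num_h / np.maximum(den_h, _FLOOR)
    if not (np.all(np.isfinite(W_new)) and np.all(np.isfinite(H_new))):
        raise FloatingPointError("non-finite factor in multiplicative update")
    return W_new, H_new


def fit_nmf(X: np.ndarray, rank: int, omega: float = 0.01,
            max_iter: int = 2000, tol: float = 1e-6,
            seed: int = 0) -> NMFFactors:
    """Fit NMF on a non-negative matrix.

    Initialization is seeded uniform(0, 1] scaled by sqrt(mean(X)/rank).
    Iteration stops when the relative objective change between consecutive
    iterations drops below ``tol`` or ``max_iter`` is reached.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    m, n = X.shape
    if rank > min(m, n):
        raise ValueError(f"rank {rank} exceeds min(m, n) = {min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _FLOOR) / rank)
    W = (1.0 - rng.random((m, rank))) * scale  # uniform on (0, 1], scaled
    H = (1.0 - rng.random((rank, n))) * scale
    omega1, omega2 = omega * m, omega * n
    trace = [nmf_objective(X, W, H, omega)]
    it = 0
    for it in range(1, max_iter + 1):
        W, H = nmf_update_step(X, W, H, omega1, omega2)
        obj = nmf_objective(X, W, H, omega)
        prev = trace[-1]
        trace.append(obj)
        if prev > 0 and abs(prev - obj) / prev < tol:
            break
    return NMFFactors(W=W, H=H, objective_trace=trace, iterations_run=it)
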