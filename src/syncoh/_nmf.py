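"""Best-of-restarts nonnegative matrix factorization (Frobenius objective).

Thin wrapper around scikit-learn's multiplicative-update solver; restarts use
independent uniform-random nonnegative initializations and the restart with
the highest explained variation is retained.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import non_negative_factorization
from sklearn.exceptions import ConvergenceWarning

__all__ = ["nmf_best_of_restarts", "explained_r2"]


def explained_r2(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """R^2 = 1 - SSE/SST with SST taken about the column-mean vector."""
    sse = float(np.sum((X - W @ H) ** 2))
    sst = float(np.sum((X - X.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0.0:
        raise ValueError("SST is zero: input has no variation about its mean")
    return 1.0 - sse / sst


def nmf_best_of_restarts(X: np.ndarray, rank: int, restarts: int = 10,
                         rng: np.random.Generator | None = None,
                         max_iter: int = 1000, tol: float = 1e-6):
    """Factorize ``X ~= W @ H`` keeping the restart with the highest R^2.

    Returns ``(W, H, r2, restart_r2s)``.
    """
    X = np.asarray(X, float)
    if np.any(X < 0):
        raise ValueError("NMF input must be nonnegative")
    if not np.any(X > 0):
        raise ValueError("NMF input is identically zero")
    if not 1 <= rank <= min(X.shape):
        raise ValueError(f"rank {rank} out of range for shape {X.shape}")
    if rng is None:
        rng = np.random.default_rng()
    best = None
    restart_r2s = []
    for _ in range(max(1, restarts)):
        seed = int(rng.integers(2 ** 31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W, H, _ = non_negative_factorization(
                X, n_components=rank, init="random", solver="mu",
                beta_loss="frobenius", tol=tol, max_iter=max_iter,
                random_state=seed)
        r2 = explained_r2(X, W, H)
        restart_r2s.append(r2)
        if best is None or r2 > best[2]:
            best = (W, H, r2)
    W, H, r2 = best
    return W, H, r2, restart_r2s
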