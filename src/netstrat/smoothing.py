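"""Network propagation of binary alteration profiles.

A sample's 0/1 gene vector is diffused over the interaction network by
random walk with restart,

    F_{t+1} = alpha * F_t @ W + (1 - alpha) * F0,

whose fixed point is F = (1 - alpha) * F0 @ (I - alpha W)^{-1}.  The
restart weight ``alpha`` controls how far each alteration's influence
spreads; the smoothed profiles are then quantile-normalized across samples
so every patient carries an identical value distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def normalize_adjacency(
    net: nx.Graph, node_order: list[str] | None = None, mode: str = "row_stochastic"
) -> tuple[np.ndarray, list[str]]:
    """Degree-normalized adjacency for the propagation recursion.

    ``row_stochastic`` divides each row of the weighted adjacency by its row
    sum (zero-degree rows stay all-zero); ``symmetric`` forms
    D^{-1/2} A D^{-1/2}.  Returns the matrix and the node order used.
    """
    if node_order is None:
        node_order = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=node_order, weight="weight")
    if (A < 0).any():
        raise ValueError("negative edge weights are not allowed")
    deg = A.sum(axis=1)
    if mode == "row_stochastic":
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(deg[:, None] > 0, A / deg[:, None], 0.0)
    elif mode == "symmetric":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        W = d[:, None] * A * d[None, :]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return W, list(node_order)


@dataclass
class SmoothedProfile:
    """Samples x genes propagation scores with the run's diagnostics."""

    values: pd.DataFrame
    alpha: float
    iterations_used: int
    residual: float
    converged: bool
    quantile_normalized: bool = False


def propagate(
    F0: pd.DataFrame,
    W: np.ndarray,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SmoothedProfile:
    """Iterate the restart recursion until the profile stops moving.

    Stops when ``max|F_{t+1} - F_t| < tol`` or at ``max_iter`` (then a
    warning is raised and the residual flagged, not a hard error).  With a
    (sub-)stochastic W and ``alpha < 1`` the iteration is a contraction, so
    the residual shrinks geometrically.  ``alpha = 0`` returns F0 itself.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    if F0.shape[1] != W.shape[0]:
        raise ValueError("F0 columns must align with W's node order")
    F = F0.to_numpy(dtype=float)
    base = (1.0 - alpha) * F
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        F_next = alpha * (F @ W) + base
        residual = float(np.abs(F_next - F).max())
        F = F_next
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"propagation did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} >= tol {tol:.3g})",
            RuntimeWarning,
        )
    return SmoothedProfile(
        values=pd.DataFrame(F, index=F0.index, columns=F0.columns),
        alpha=alpha,
        iterations_used=iterations,
        residual=residual,
        converged=converged,
    )


def propagate_exact(F0: pd.DataFrame, W: np.ndarray, alpha: float) -> pd.DataFrame:
    """Closed-form fixed point (1 - alpha) * F0 @ (I - alpha W)^{-1}."""
    n = W.shape[0]
    kernel = np.linalg.solve((np.eye(n) - alpha * W).T, F0.to_numpy(dtype=float).T).T
    return pd.DataFrame((1.0 - alpha) * kernel, index=F0.index, columns=F0.columns)


def propagation_kernel(W: np.ndarray, alpha: float) -> np.ndarray:
    """(I - alpha W)^{-1}; row g is gene g's diffusion profile."""
    return np.linalg.inv(np.eye(W.shape[0]) - alpha * W)


def quantile_normalize(profile: SmoothedProfile) -> SmoothedProfile:
    """Map every sample's values rank-wise onto the mean order statistics.

    The reference distribution is the across-sample mean of each sorted
    position; ties within a sample share the mean of the reference values at
    their would-be positions.  Afterwards all rows have the identical sorted
    value multiset.
    """
    X = profile.values.to_numpy(dtype=float)
    n_samples, n_genes = X.shape
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n_samples):
        order = np.argsort(X[i], kind="mergesort")
        row = np.empty(n_genes)
        row[order] = reference
        # ties share the mean reference value of their positions
        sorted_vals = X[i][order]
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or sorted_vals[end] != sorted_vals[start]:
                if end - start > 1:
                    row[order[start:end]] = reference[start:end].mean()
                start = end
        out[i] = row
    return SmoothedProfile(
        values=pd.DataFrame(out, index=profile.values.index, columns=profile.values.columns),
        alpha=profile.alpha,
        iterations_used=profile.iterations_used,
        residual=profile.residual,
        converged=profile.converged,
        quantile_normalized=True,
    )


def smooth_profiles(
    F0: pd.DataFrame,
    net: nx.Graph,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 100,
    norm_mode: str = "row_stochastic",
    quantile_norm: bool = True,
) -> SmoothedProfile:
    """Full smoothing stage: normalize, propagate, optionally quantile-normalize."""
    W, order = normalize_adjacency(net, node_order=list(F0.columns), mode=norm_mode)
    profile = propagate(F0[order], W, alpha=alpha, tol=tol, max_iter=max_iter)
    if quantile_norm:
        profile = quantile_normalize(profile)
    log.info(
        "smoothed %d samples over %d genes (alpha=%.2f, %d iterations, residual %.2g)",
        F0.shape[0], F0.shape[1], alpha, profile.iterations_used, profile.residual,
    )
    return profile
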