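"""Graph-regularized NMF with consensus resampling.

The smoothed profile (genes x samples after transposition) is factorized as
F ~ W H with W, H >= 0 and a graph-Laplacian penalty lambda * tr(W' L W)
that encourages gene bases smooth over the interaction network.  Cluster
assignments come from the argmax of H; robustness comes from consensus over
subsampled refits, summarized in a samples x samples co-clustering
frequency matrix that is cut by average-linkage hierarchical clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .smoothing import SmoothedProfile, normalize_adjacency, propagation_kernel

log = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


def build_knn_laplacian(
    net: nx.Graph,
    node_order: list[str],
    alpha: float = 0.7,
    knn_k: int = 11,
) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian of the kNN graph of the propagation kernel.

    For each gene, the ``knn_k`` other genes with the largest influence
    kernel (I - alpha W)^{-1} entries are kept as neighbours; the kept
    weighted adjacency is symmetrized by elementwise maximum.  Returns
    ``(L, K)`` with L = D_K - K.
    """
    n = len(node_order)
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be < number of genes ({n})")
    W, _ = normalize_adjacency(net, node_order=node_order, mode="row_stochastic")
    kernel = propagation_kernel(W, alpha)
    np.fill_diagonal(kernel, -np.inf)
    K = np.zeros((n, n))
    for i in range(n):
        nbrs = np.argpartition(kernel[i], -knn_k)[-knn_k:]
        K[i, nbrs] = kernel[i, nbrs]
    K = np.maximum(K, K.T)
    K[K == -np.inf] = 0.0
    L = np.diag(K.sum(axis=1)) - K
    return L, K


def _nndsvd_init(
    Fg: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization with random fill of zeros."""
    try:
        U, S, Vt = np.linalg.svd(Fg, full_matrices=False)
    except np.linalg.LinAlgError:        # pragma: no cover - SVD failure fallback
        scale = np.sqrt(max(Fg.mean(), _EPS) / k)
        return (
            scale * rng.uniform(size=(Fg.shape[0], k)),
            scale * rng.uniform(size=(k, Fg.shape[1])),
        )
    W = np.zeros((Fg.shape[0], k))
    H = np.zeros((k, Fg.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * up / n_up
                H[j, :] = np.sqrt(S[j] * sigma) * vp / n_vp
        else:
            sigma = n_un * n_vn
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * un / n_un
                H[j, :] = np.sqrt(S[j] * sigma) * vn / n_vn
    mean_scale = np.sqrt(max(Fg.mean(), _EPS) / k)
    fill = rng.uniform(0.0, mean_scale / 100.0, size=W.shape)
    W = np.where(W > 0, W, fill)
    fill = rng.uniform(0.0, mean_scale / 100.0, size=H.shape)
    H = np.where(H > 0, H, fill)
    return W, H


@dataclass
class NetNMFModel:
    """Fitted graph-regularized NMF factors and fit diagnostics."""

    W: pd.DataFrame                   # genes x k basis
    H: pd.DataFrame                   # k x samples coefficients
    k: int
    lam: float
    objective_trace: np.ndarray
    n_iter_used: int
    converged: bool


def netnmf_fit(
    F,
    k: int,
    L: np.ndarray | None = None,
    lam: float = 1.0,
    seed: int = 0,
    n_iter: int = 1000,
    tol: float = 1e-6,
    init: str = "nndsvd",
) -> NetNMFModel:
    """Multiplicative-update fit of ||F' - W H||_F^2 + lam * tr(W' L W).

    With L = D_K - K the updates

        W <- W * (Fg H' + lam K W) / (W H H' + lam D_K W)
        H <- H * (W' Fg) / (W' W H)

    never increase the objective; denominators are floored at machine
    epsilon.  ``F`` is a samples x genes frame (or SmoothedProfile); the
    factorization acts on its transpose Fg (genes x samples).

    ``init``: ``nndsvd`` (deterministic non-negative double SVD, zeros
    filled with seed-controlled small uniforms — the default for
    clustering) or ``random`` (seeded uniform — preferable for exact
    low-rank recovery, where NNDSVD's zero pattern can lock a stationary
    point).  Iteration also stops once the objective reaches the
    numerically-exact-fit floor 1e-15 * ||Fg||_F^2.
    """
    values = F.values if isinstance(F, SmoothedProfile) else F
    if isinstance(values, pd.DataFrame):
        gene_ids = list(values.columns)
        sample_ids = list(values.index)
        Fg = values.to_numpy(dtype=float).T
    else:
        Fg = np.asarray(values, dtype=float).T
        gene_ids = [f"g{i}" for i in range(Fg.shape[0])]
        sample_ids = [f"s{i}" for i in range(Fg.shape[1])]
    if (Fg < 0).any():
        raise ValueError("input profile must be non-negative")
    if k < 2:
        raise ValueError("k must be >= 2")

    use_graph = L is not None and lam > 0
    if use_graph:
        DK = np.diag(np.diag(L))
        K = DK - L

    rng = np.random.default_rng(seed)
    if init == "nndsvd":
        W, H = _nndsvd_init(Fg, k, rng)
    elif init == "random":
        scale = np.sqrt(max(Fg.mean(), _EPS) / k)
        W = scale * rng.uniform(size=(Fg.shape[0], k))
        H = scale * rng.uniform(size=(k, Fg.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")

    def objective(W, H):
        resid = Fg - W @ H
        obj = float(np.sum(resid * resid))
        if use_graph:
            obj += lam * float(np.sum(W * (L @ W)))
        return obj

    trace = [objective(W, H)]
    floor = 1e-15 * float(np.sum(Fg * Fg))
    converged = False
    it = 0
    for it in range(1, n_iter + 1):
        numer = Fg @ H.T
        denom = W @ (H @ H.T)
        if use_graph:
            numer += lam * (K @ W)
            denom += lam * (DK @ W)
        W = W * numer / np.maximum(denom, _EPS)
        H = H * (W.T @ Fg) / np.maximum((W.T @ W) @ H, _EPS)
        obj = objective(W, H)
        trace.append(obj)
        prev = trace[-2]
        if obj <= floor or (prev > 0 and (prev - obj) / prev < tol):
            converged = True
            break

    return NetNMFModel(
        W=pd.DataFrame(W, index=gene_ids, columns=range(1, k + 1)),
        H=pd.DataFrame(H, index=range(1, k + 1), columns=sample_ids),
        k=k,
        lam=lam if use_graph else 0.0,
        objective_trace=np.asarray(trace),
        n_iter_used=it,
        converged=converged,
    )


def assign_clusters(model: NetNMFModel) -> pd.Series:
    """Hard assignment: argmax coefficient per sample, ties to the lowest index."""
    H = model.H.to_numpy()
    if (H.max(axis=0) == 0).any():
        warnings.warn("all-zero coefficient column; assigning subgroup 1", RuntimeWarning)
    labels = H.argmax(axis=0) + 1
    return pd.Series(labels, index=model.H.columns, name="subgroup")


@dataclass
class ConsensusResult:
    """Co-clustering frequencies over resampled refits plus the final cut."""

    consensus: pd.DataFrame            # samples x samples, in [0, 1]
    co_cluster_counts: pd.DataFrame
    co_sample_counts: pd.DataFrame
    assignment: pd.Series              # sample -> subgroup in 1..k
    k: int


def consensus_cluster(
    F,
    k: int,
    L: np.ndarray | None = None,
    lam: float = 1.0,
    n_runs: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_iter: int = 1000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Consensus clustering of subsampled graph-regularized NMF runs.

    Each run subsamples ``ceil(subsample_frac * n)`` samples without
    replacement, refits with a fresh derived seed, and records pairwise
    co-membership.  The consensus matrix is the co-cluster / co-sample
    ratio (0 where a pair was never co-sampled, with a warning); the final
    assignment cuts average-linkage hierarchical clustering of
    1 - consensus into k groups.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must lie in (0, 1]")
    values = F.values if isinstance(F, SmoothedProfile) else F
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    n = values.shape[0]
    sample_ids = list(values.index)
    n_sub = int(np.ceil(subsample_frac * n))

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_runs):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        run_seed = int(rng.integers(0, 2**31 - 1))
        model = netnmf_fit(
            values.iloc[idx], k, L=L, lam=lam, seed=run_seed, n_iter=n_iter, tol=tol
        )
        labels = assign_clusters(model).to_numpy()
        co_sample[np.ix_(idx, idx)] += 1
        for c in np.unique(labels):
            members = idx[labels == c]
            co_cluster[np.ix_(members, members)] += 1

    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs never co-sampled in {n_runs} runs; "
            "their consensus entries are set to 0",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")

    idx = pd.Index(sample_ids, name="sample_id")
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=idx, columns=sample_ids),
        co_cluster_counts=pd.DataFrame(co_cluster, index=idx, columns=sample_ids),
        co_sample_counts=pd.DataFrame(co_sample, index=idx, columns=sample_ids),
        assignment=pd.Series(labels, index=idx, name="subgroup"),
        k=k,
    )


def stratify_range(
    F,
    k_values=range(3, 16),
    L: np.ndarray | None = None,
    lam: float = 1.0,
    n_runs: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[dict[int, ConsensusResult], pd.DataFrame]:
    """Consensus stratification for every k, plus the samples x k landscape table."""
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_range must be non-empty")
    results: dict[int, ConsensusResult] = {}
    for j, k in enumerate(k_values):
        results[k] = consensus_cluster(
            F, k, L=L, lam=lam, n_runs=n_runs, subsample_frac=subsample_frac,
            seed=seed + j, n_iter=n_iter, tol=tol,
        )
        log.info("consensus stratification at k=%d done", k)
    landscape = pd.DataFrame(
        {f"k={k}": results[k].assignment for k in k_values}
    )
    landscape.index.name = "sample_id"
    return results, landscape
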