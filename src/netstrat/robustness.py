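"""Subsampling stability of a consensus stratification.

Repeatedly subsample the cohort, rerun the full consensus clustering on the
reduced smoothed matrix, and score agreement with the reference partition
restricted to the subsample — adjusted Rand index as the primary metric and
Hungarian best-match label accuracy as the secondary one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .clustering import consensus_cluster
from .smoothing import SmoothedProfile

log = logging.getLogger(__name__)


def best_match_accuracy(labels_a, labels_b) -> float:
    """Fraction agreeing under the Hungarian-optimal label matching."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    table = pd.crosstab(a, b).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(a))


def robustness_check(
    F,
    reference: pd.Series,
    k: int = 9,
    frac: float = 0.8,
    reps: int = 20,
    seed: int = 0,
    L: np.ndarray | None = None,
    lam: float = 1.0,
    n_runs: int = 100,
    subsample_frac: float = 0.8,
    n_iter: int = 1000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Reclassify random subsamples and score consistency with the reference.

    Each rep draws ``ceil(frac * n)`` samples without replacement, reruns
    :func:`consensus_cluster` at ``k`` on the reduced matrix, and records
    ARI and best-match accuracy against the reference restricted to the
    subsample.  A rep whose reclassification leaves some subgroup empty is
    recorded (flag column), not fatal.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    values = F.values if isinstance(F, SmoothedProfile) else F
    if not set(values.index) <= set(reference.index):
        raise ValueError("reference must cover all samples")
    n = values.shape[0]
    n_sub = int(np.ceil(frac * n))
    rng = np.random.default_rng(seed)

    rows = []
    for rep in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = values.iloc[idx]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        result = consensus_cluster(
            sub, k, L=L, lam=lam, n_runs=n_runs, subsample_frac=subsample_frac,
            seed=rep_seed, n_iter=n_iter, tol=tol,
        )
        ref = reference.loc[sub.index]
        ari = adjusted_rand_score(ref.to_numpy(), result.assignment.to_numpy())
        acc = best_match_accuracy(ref, result.assignment)
        n_groups = result.assignment.nunique()
        rows.append(
            {
                "rep": rep,
                "frac": frac,
                "n_subsample": n_sub,
                "ari": ari,
                "accuracy": acc,
                "n_groups": n_groups,
                "flag": "empty_subgroup" if n_groups < k else "",
            }
        )
        log.info("robustness rep %d: ARI %.3f, accuracy %.3f", rep, ari, acc)
    return pd.DataFrame(rows)
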