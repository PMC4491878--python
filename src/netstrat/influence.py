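"""Differentially influenced genes and their induced subnetwork modules.

For each subgroup the smoothed propagation scores are contrasted against
all remaining samples with a SAM-style moderated statistic
d = (mean_in - mean_out) / (s + s0), with FDR q-values from label
permutations.  Genes passing the selection rule (d > 15, q < 0.05 by
default) are mapped back onto the interaction network as connected
modules, and their expression changes are tested by Wilcoxon rank-sum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .smoothing import SmoothedProfile
from .subgroup_stats import bh_adjust

log = logging.getLogger(__name__)


def _as_frame(F) -> pd.DataFrame:
    values = F.values if isinstance(F, SmoothedProfile) else F
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    return values


def choose_s0(s: np.ndarray, diff: np.ndarray) -> float:
    """Exchangeability constant s0 per the original SAM recipe.

    Candidate values are percentiles of the gene-wise standard errors; the
    winner minimizes the coefficient of variation of the d-spread (median
    absolute deviation) across s-quantile bins.  For small gene counts
    (< 100) the 5th percentile of s is used directly.
    """
    s = np.asarray(s, dtype=float)
    diff = np.asarray(diff, dtype=float)
    if s.size < 100:
        return float(np.percentile(s, 5))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = min(100, max(10, s.size // 20))
    quantiles = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = []
        for b in range(n_bins):
            vals = d[bins == b]
            if vals.size >= 2:
                mads.append(stats.median_abs_deviation(vals, scale="normal"))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def sam_statistic(
    F, in_group, s0: float | None = None, s0_mode: str = "auto"
) -> pd.DataFrame:
    """Per-gene SAM d-scores of an in-group vs all remaining samples.

    d_g = (mean_in - mean_out) / (s_g + s0) with the pooled standard error
    s_g = sqrt((1/n_in + 1/n_out) * SS_within / (n_in + n_out - 2)).  With
    s0 = 0 this is exactly the two-sample t statistic.  ``s0_mode``:
    ``auto`` (SAM recipe via :func:`choose_s0`), ``percentile5``, or
    ``zero``.  A gene constant in both groups with s + s0 = 0 gets d = 0,
    flagged.
    """
    values = _as_frame(F)
    mask = _in_mask(values, in_group)
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError("both groups need >= 2 samples")
    X = values.to_numpy(dtype=float)
    x_in, x_out = X[mask], X[~mask]
    m_in, m_out = x_in.mean(axis=0), x_out.mean(axis=0)
    ss = ((x_in - m_in) ** 2).sum(axis=0) + ((x_out - m_out) ** 2).sum(axis=0)
    s = np.sqrt((1.0 / n_in + 1.0 / n_out) * ss / (n_in + n_out - 2))
    diff = m_in - m_out

    if s0 is None:
        if s0_mode == "zero":
            s0 = 0.0
        elif s0_mode == "percentile5":
            s0 = float(np.percentile(s, 5))
        elif s0_mode == "auto":
            s0 = choose_s0(s, diff)
        else:
            raise ValueError(f"unknown s0_mode {s0_mode!r}")

    denom = s + s0
    flagged = denom == 0
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} genes constant in both groups with s0 = 0; d set to 0",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(flagged, 0.0, diff / np.where(flagged, 1.0, denom))
    return pd.DataFrame(
        {
            "d_score": d,
            "mean_in": m_in,
            "mean_out": m_out,
            "pooled_se": s,
            "s0": s0,
            "flag": np.where(flagged, "constant_gene", ""),
        },
        index=pd.Index(values.columns, name="gene"),
    )


def _in_mask(values: pd.DataFrame, in_group) -> np.ndarray:
    in_group = list(in_group) if not isinstance(in_group, np.ndarray) else in_group
    if isinstance(in_group, np.ndarray) and in_group.dtype == bool:
        return in_group
    if all(isinstance(x, (bool, np.bool_)) for x in in_group) and len(in_group) == len(values.index):
        return np.asarray(in_group, dtype=bool)
    members = set(in_group)
    return np.asarray([s in members for s in values.index], dtype=bool)


def _perm_masks(n: int, n_in: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Label arrangements: exhaustive when feasible, else seeded draws."""
    total = comb(n, n_in)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_in)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_in, replace=False)] = True
    return masks, False


def _d_for_mask(X: np.ndarray, mask: np.ndarray, s0: float) -> np.ndarray:
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    x_in, x_out = X[mask], X[~mask]
    m_in, m_out = x_in.mean(axis=0), x_out.mean(axis=0)
    ss = ((x_in - m_in) ** 2).sum(axis=0) + ((x_out - m_out) ** 2).sum(axis=0)
    s = np.sqrt((1.0 / n_in + 1.0 / n_out) * ss / (n_in + n_out - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom == 0, 0.0, (m_in - m_out) / np.where(denom == 0, 1.0, denom))


def sam_permutation_fdr(
    F, in_group, n_perm: int = 1000, seed: int = 0, s0_mode: str = "auto"
) -> pd.DataFrame:
    """SAM permutation FDR q-values for every gene.

    Group labels are permuted (exhaustively whenever the number of distinct
    arrangements is <= ``n_perm``, the same shuffles applied to all genes);
    for each gene's threshold t = |d_g| the expected false count is the
    median over permutations of #{|d*| >= t}, and
    q = median_count / #{|d| >= t}, capped at 1 and made monotone
    non-increasing in |d|.  s0 is fixed from the observed labeling and
    shared across permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = _as_frame(F)
    mask = _in_mask(values, in_group)
    observed = sam_statistic(values, mask, s0_mode=s0_mode)
    s0 = float(observed["s0"].iloc[0])
    X = values.to_numpy(dtype=float)
    n, n_in = len(mask), int(mask.sum())

    masks, exhaustive = _perm_masks(n, n_in, n_perm, seed)
    if len(masks) < 20:
        warnings.warn(
            f"only {len(masks)} distinct label arrangements; q resolution is limited",
            RuntimeWarning,
        )
    D = np.vstack([_d_for_mask(X, m, s0) for m in masks])        # perms x genes

    abs_d = np.abs(observed["d_score"].to_numpy())
    abs_D_sorted = np.sort(np.abs(D), axis=1)
    n_genes = abs_d.size
    # for each gene threshold: per-permutation exceedance counts, then the median
    counts = n_genes - np.vstack(
        [np.searchsorted(row, abs_d, side="left") for row in abs_D_sorted]
    )
    median_false = np.median(counts, axis=0)
    order_desc = np.argsort(-abs_d, kind="mergesort")
    ranks = np.empty(n_genes, dtype=int)
    ranks[order_desc] = np.arange(1, n_genes + 1)
    # ties share the deepest rank (count of |d| >= threshold)
    n_called = np.array([(abs_d >= t).sum() for t in abs_d])
    q = np.minimum(median_false / n_called, 1.0)
    # monotone non-increasing in |d|: running min from the least significant up
    q_sorted = q[order_desc]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_mono = np.empty(n_genes)
    q_mono[order_desc] = q_sorted

    out = observed.copy()
    out["q_value"] = q_mono
    out.attrs["exhaustive"] = exhaustive
    out.attrs["n_permutations"] = len(masks)
    return out


def select_significant(
    sam: pd.DataFrame, score_min: float = 15.0, q_max: float = 0.05,
    two_sided: bool = False,
) -> list[str]:
    """Genes with d > score_min and q < q_max (positive tail by default).

    The literal positive reading selects genes influenced *in* the
    subgroup; ``two_sided=True`` selects on |d| instead.
    """
    score = sam["d_score"].abs() if two_sided else sam["d_score"]
    keep = (score > score_min) & (sam["q_value"] < q_max)
    return list(sam.index[keep])


@dataclass
class SubnetworkModule:
    """One connected component of the selected genes' induced subgraph."""

    component_id: int
    graph: nx.Graph                    # node attrs: node_score, expression_flag
    node_scores: pd.Series

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def extract_subnetworks(
    genes, net: nx.Graph, F, in_group, expression_flags: dict[str, bool] | None = None
) -> list[SubnetworkModule]:
    """Induced subgraph of the selected genes, split into connected components.

    Node scores are the mean smoothed value over the in-group samples;
    ``expression_flags`` (gene -> significant expression change) are carried
    as node attributes for export.  Genes absent from the network are
    dropped with a warning; an empty gene set yields an empty list.
    """
    genes = list(genes)
    values = _as_frame(F)
    mask = _in_mask(values, in_group)
    missing = [g for g in genes if g not in net.nodes]
    if missing:
        warnings.warn(f"{len(missing)} selected genes absent from network; dropped",
                      RuntimeWarning)
    kept = [g for g in genes if g in net.nodes]
    if not kept:
        return []
    induced = net.subgraph(kept)
    in_values = values.loc[values.index[mask]]
    modules = []
    flags = expression_flags or {}
    for cid, comp in enumerate(
        sorted(nx.connected_components(induced), key=lambda c: (-len(c), sorted(c)[0]))
    ):
        sub = nx.Graph(induced.subgraph(comp))
        scores = in_values[sorted(comp)].mean(axis=0)
        for node in sub.nodes:
            sub.nodes[node]["node_score"] = float(scores[node])
            sub.nodes[node]["expression_flag"] = bool(flags.get(node, False))
        modules.append(
            SubnetworkModule(component_id=cid, graph=sub, node_scores=scores)
        )
    return modules


def gene_set_overlap(sets: dict | list) -> pd.DataFrame:
    """k x k pairwise intersection counts; the diagonal holds set sizes."""
    if isinstance(sets, dict):
        keys, values = list(sets.keys()), [set(v) for v in sets.values()]
    else:
        keys, values = list(range(1, len(sets) + 1)), [set(v) for v in sets]
    counts = [[len(a & b) for b in values] for a in values]
    return pd.DataFrame(counts, index=keys, columns=keys)


def wilcoxon_expression(
    expr: pd.DataFrame, assignment: pd.Series, subgroup, genes
) -> pd.DataFrame:
    """Wilcoxon rank-sum expression contrast for a subgroup's gene set.

    Two-sided test of subgroup samples vs all remaining samples per gene:
    exact enumeration when both groups have <= 10 samples and no ties,
    tie-corrected normal approximation otherwise.  BH correction across the
    tested genes of this subgroup.  Genes absent from the expression matrix
    are skipped with a warning.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        warnings.warn(
            f"{len(missing)} genes absent from expression matrix; skipped", RuntimeWarning
        )
    genes = [g for g in genes if g in expr.index]
    samples = expr.columns.intersection(assignment.index)
    mask = assignment.loc[samples] == subgroup
    in_cols, out_cols = samples[mask], samples[~mask]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError("both groups need >= 2 samples")

    rows = []
    for gene in genes:
        x = expr.loc[gene, in_cols].to_numpy(dtype=float)
        y = expr.loc[gene, out_cols].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if len(x) <= 10 and len(y) <= 10 and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        rows.append({"gene": gene, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "method": method})
    out = pd.DataFrame(rows).set_index("gene")
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def influence_analysis(
    F,
    assignment: pd.Series,
    net: nx.Graph,
    expression: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    score_min: float = 15.0,
    q_max: float = 0.05,
    s0_mode: str = "auto",
) -> dict:
    """Full influence stage for every subgroup of an assignment.

    Returns per-subgroup SAM tables, selected gene sets, subnetwork
    modules, expression contrasts (when an expression matrix is given), and
    the pairwise gene-set overlap matrix.
    """
    values = _as_frame(F)
    results: dict = {"sam": {}, "gene_sets": {}, "modules": {}, "expression": {}}
    for j, subgroup in enumerate(sorted(assignment.unique())):
        in_group = assignment.index[assignment == subgroup]
        sam = sam_permutation_fdr(
            values, in_group, n_perm=n_perm, seed=seed + j, s0_mode=s0_mode
        )
        selected = select_significant(sam, score_min=score_min, q_max=q_max)
        flags: dict[str, bool] = {}
        if expression is not None and selected:
            wtab = wilcoxon_expression(expression, assignment, subgroup, selected)
            results["expression"][subgroup] = wtab
            flags = (wtab["q_value"] < 0.05).to_dict()
        results["sam"][subgroup] = sam
        results["gene_sets"][subgroup] = selected
        results["modules"][subgroup] = extract_subnetworks(
            selected, net, values, in_group, expression_flags=flags
        )
        log.info("subgroup %s: %d significant genes, %d modules",
                 subgroup, len(selected), len(results["modules"][subgroup]))
    results["overlap"] = gene_set_overlap(results["gene_sets"])
    return results
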