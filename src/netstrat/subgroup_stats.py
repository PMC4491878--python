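"""Subgroup characterization: enrichment, survival and stage/grade association.

Cancer-type enrichment per subgroup uses Pearson's chi-squared on 2x2
tables with Benjamini-Hochberg correction across all (subgroup, type)
pairs; survival comparisons use Kaplan-Meier curves with the two-group
log-rank test; ordinal stage/grade distributions are compared by an exact
(or Monte-Carlo) Fisher test on r x c tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Floor applied to displayed p-values (visualization convention).
DISPLAY_P_FLOOR = 1e-10


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def enrichment_test(assignment: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Chi-squared enrichment of every label (cancer type/subtype) in every subgroup.

    For each (subgroup, label) pair a 2x2 table {in/out of subgroup} x
    {is/is-not label} is tested by Pearson's chi-squared without continuity
    correction; q-values are BH-adjusted across all pairs of the partition.
    ``display_p`` floors p at 1e-10 for visualization; the exact p is kept.
    A label absent from the cohort (zero margin) records p = 1 with a flag.
    """
    common = assignment.index.intersection(labels.index)
    if len(common) != len(assignment) or len(common) != len(labels):
        raise ValueError("assignment and labels must cover the same samples")
    assignment = assignment.loc[common]
    labels = labels.loc[common]
    n = len(common)

    rows = []
    for subgroup in sorted(assignment.unique()):
        in_mask = assignment == subgroup
        for label in sorted(labels.dropna().unique()):
            is_label = labels == label
            a = int((in_mask & is_label).sum())
            b = int((in_mask & ~is_label).sum())
            c = int((~in_mask & is_label).sum())
            d = int((~in_mask & ~is_label).sum())
            table = np.array([[a, b], [c, d]])
            flag = ""
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                chi2, p = 0.0, 1.0
                flag = "degenerate_margin"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "subgroup": subgroup,
                    "label": label,
                    "count_in_subgroup": a,
                    "subgroup_size": a + b,
                    "label_total": a + c,
                    "n": n,
                    "chi2_stat": float(chi2),
                    "p_value": float(p),
                    "flag": flag,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["display_p"] = out["p_value"].clip(lower=DISPLAY_P_FLOOR)
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time: at-risk count, events,
    censorings in the preceding interval, and the survival estimate.  The
    curve starts at S(0) = 1; censored times reduce the risk set but never
    drop the curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")

    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = [{"time": 0.0, "n_at_risk": len(times), "n_events": 0, "survival": 1.0}]
    surv = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float, str]:
    """Two-group log-rank test via the O/E/V tabulation.

    At each distinct pooled event time the observed minus hypergeometric-
    expected events in group a are accumulated with their variance;
    stat = (sum O - sum E)^2 / sum V, p from the upper tail of chi2(1).
    Zero total variance (no comparable event times) yields p = 1 flagged.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(((ta == t) & (ea == 1)).sum())
        db = int(((tb == t) & (eb == 1)).sum())
        d = da + db
        if n == 0 or d == 0:
            continue
        o_minus_e += da - d * na / n
        if n > 1:
            variance += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0, "zero_variance"
    stat = o_minus_e**2 / variance
    return float(stat), float(stats.chi2.sf(stat, df=1)), ""


def _table_logprob(table: np.ndarray, lg_margins: float) -> float:
    return lg_margins - sum(lgamma(x + 1) for x in table.ravel())


def _enumerate_tables(row_margins, col_margins, cap):
    """Yield all contingency tables with the given margins (None if > cap)."""
    r, c = len(row_margins), len(col_margins)
    tables = []

    def fill(row_idx, col_rem, acc):
        if len(tables) > cap:
            return False
        if row_idx == r - 1:
            last = np.asarray(col_rem)
            if (last >= 0).all() and last.sum() == row_margins[-1]:
                tables.append(np.vstack(acc + [last]))
            return True
        target = row_margins[row_idx]
        row = np.zeros(c, dtype=int)

        def fill_cell(j, rem):
            if len(tables) > cap:
                return False
            if j == c - 1:
                row[j] = rem
                if 0 <= rem <= col_rem[j]:
                    new_rem = [col_rem[t] - row[t] for t in range(c)]
                    if not fill(row_idx + 1, new_rem, acc + [row.copy()]):
                        return False
                return True
            hi = min(rem, col_rem[j])
            for v in range(hi + 1):
                row[j] = v
                if not fill_cell(j + 1, rem - v):
                    return False
            return True

        return fill_cell(0, target)

    ok = fill(0, list(col_margins), [])
    if not ok or len(tables) > cap:
        return None
    return tables


def fisher_exact_rxc(
    table,
    max_tables: int = 1_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Exact conditional Fisher test on an r x c table.

    The p-value is the total probability, under fixed margins, of tables at
    most as probable as the observed one — by full enumeration when the
    table count stays within ``max_tables``, else by Patefield Monte-Carlo
    sampling with the given seed.  Returns ``(p, mc_standard_error)`` with
    the standard error ``None`` for the exact path.  All-zero rows/columns
    are removed first; an empty margin yields p = 1.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, None

    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = table.sum()
    lg_margins = (
        sum(lgamma(x + 1) for x in row_m)
        + sum(lgamma(x + 1) for x in col_m)
        - lgamma(n + 1)
    )
    logp_obs = _table_logprob(table, lg_margins)
    tol = 1e-9 * abs(logp_obs) + 1e-12

    tables = _enumerate_tables(list(row_m), list(col_m), max_tables)
    if tables is not None:
        total = 0.0
        for t in tables:
            lp = _table_logprob(t, lg_margins)
            if lp <= logp_obs + tol:
                total += np.exp(lp)
        return float(min(total, 1.0)), None

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_m, col_m, seed=rng)
    draws = sampler.rvs(n_mc, method="patefield")
    lps = lg_margins - np.vectorize(lambda x: lgamma(x + 1))(draws).sum(axis=(1, 2))
    hits = (lps <= logp_obs + tol).mean()
    se = float(np.sqrt(hits * (1 - hits) / n_mc))
    return float(hits), se


@dataclass
class SurvivalComparison:
    """A two-group survival contrast within one cancer type."""

    cancer_type: str
    group_a: list[str]
    group_b: list[str]
    km_a: pd.DataFrame
    km_b: pd.DataFrame
    logrank_stat: float
    p_value: float
    flag: str


def compare_survival(
    clinical: pd.DataFrame,
    assignment: pd.Series,
    subgroup,
    cancer_type: str,
) -> SurvivalComparison:
    """Enriched-subgroup vs rest survival within one cancer type.

    Samples of ``cancer_type`` assigned to ``subgroup`` are compared against
    the remaining samples of the same type.  Samples missing survival time
    or the event indicator are excluded from this comparison only.
    """
    common = clinical.index.intersection(assignment.index)
    sub = clinical.loc[common]
    sub = sub[sub["cancer_type"] == cancer_type]
    sub = sub.dropna(subset=["survival_time", "event_indicator"])
    in_mask = assignment.loc[sub.index] == subgroup
    a, b = sub[in_mask], sub[~in_mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"empty survival group for subgroup {subgroup} within {cancer_type}"
        )
    stat, p, flag = logrank_test(
        a["survival_time"], a["event_indicator"], b["survival_time"], b["event_indicator"]
    )
    return SurvivalComparison(
        cancer_type=cancer_type,
        group_a=list(a.index),
        group_b=list(b.index),
        km_a=km_estimate(a["survival_time"], a["event_indicator"]),
        km_b=km_estimate(b["survival_time"], b["event_indicator"]),
        logrank_stat=stat,
        p_value=p,
        flag=flag,
    )


def stage_association(
    clinical: pd.DataFrame,
    assignment: pd.Series,
    subgroup,
    cancer_type: str,
    feature: str = "stage",
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float | None]:
    """Fisher test of a stage/grade distribution: subgroup vs rest within a type.

    Returns the categories x {in, out} contingency table and the Fisher
    p-value (with Monte-Carlo standard error when sampling was used).
    Samples missing the feature are excluded from this comparison only.
    """
    common = clinical.index.intersection(assignment.index)
    sub = clinical.loc[common]
    sub = sub[sub["cancer_type"] == cancer_type].dropna(subset=[feature])
    in_mask = assignment.loc[sub.index] == subgroup
    table = pd.crosstab(sub[feature], in_mask.map({True: "in_subgroup", False: "rest"}))
    for col in ("in_subgroup", "rest"):
        if col not in table.columns:
            table[col] = 0
    table = table[["in_subgroup", "rest"]]
    p, se = fisher_exact_rxc(table.to_numpy(), seed=seed)
    return table, p, se


def survival_scan(
    clinical: pd.DataFrame, assignment: pd.Series, adjust: bool = True
) -> pd.DataFrame:
    """Log-rank scan of every (subgroup, cancer type) pair with both groups non-empty.

    Emits raw p-values and, optionally, BH q-values across the scan.
    """
    rows = []
    for subgroup in sorted(assignment.unique()):
        for cancer_type in sorted(clinical["cancer_type"].dropna().unique()):
            try:
                cmp = compare_survival(clinical, assignment, subgroup, cancer_type)
            except ValueError:
                continue
            rows.append(
                {
                    "subgroup": subgroup,
                    "cancer_type": cancer_type,
                    "n_in": len(cmp.group_a),
                    "n_rest": len(cmp.group_b),
                    "logrank_stat": cmp.logrank_stat,
                    "p_value": cmp.p_value,
                    "flag": cmp.flag,
                }
            )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
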