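from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netstrat as ns


def frame(X, samples=None, genes=None):
    X = np.asarray(X, dtype=float)
    samples = samples or [f"s{i}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, index=samples, columns=genes)


class TestSamStatistic:
    def test_equal_group_means_give_zero(self):
        X = frame([[1.0, 5.0], [3.0, 1.0], [1.0, 5.0], [3.0, 1.0]])
        sam = ns.sam_statistic(X, ["s0", "s1"], s0=0.5)
        assert np.allclose(sam.d_score, 0.0)

    def test_s0_zero_reduces_to_t_statistic(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(size=(12, 30)))
        in_group = list(X.index[:5])
        sam = ns.sam_statistic(X, in_group, s0=0.0)
        t_ref, _ = stats.ttest_ind(X.iloc[:5], X.iloc[5:], equal_var=True)
        assert np.allclose(sam.d_score, t_ref, atol=1e-12)

    def test_scale_invariance_at_s0_zero(self):
        rng = np.random.default_rng(1)
        X = frame(rng.normal(size=(10, 8)))
        in_group = list(X.index[:4])
        d1 = ns.sam_statistic(X, in_group, s0=0.0).d_score
        d2 = ns.sam_statistic(2.0 * X, in_group, s0=0.0).d_score
        assert np.allclose(d1, d2, atol=1e-12)

    def test_constant_gene_with_zero_s0_flagged(self):
        X = frame([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        with pytest.warns(RuntimeWarning, match="constant"):
            sam = ns.sam_statistic(X, ["s0", "s1"], s0=0.0)
        assert sam.d_score.iloc[0] == 0.0
        assert sam.flag.iloc[0] == "constant_gene"

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(2)
        X = frame(rng.normal(size=(14, 20)))
        X.iloc[:7, :5] += 2.0
        sam = ns.sam_statistic(X, list(X.index[:7]), s0_mode="percentile5")
        diff = sam.mean_in - sam.mean_out
        nonzero = sam.d_score != 0
        assert (np.sign(sam.d_score[nonzero]) == np.sign(diff[nonzero])).all()


def brute_force_sam_q(X: pd.DataFrame, in_samples: list[str], s0: float):
    """Independent q-value oracle: plain loops over all label arrangements."""
    n = X.shape[0]
    n_in = len(in_samples)
    samples = list(X.index)

    def d_stat(in_set):
        x_in = X.loc[list(in_set)].to_numpy()
        x_out = X.loc[[s for s in samples if s not in in_set]].to_numpy()
        m_in, m_out = x_in.mean(axis=0), x_out.mean(axis=0)
        ss = ((x_in - m_in) ** 2).sum(axis=0) + ((x_out - m_out) ** 2).sum(axis=0)
        s = np.sqrt((1 / len(x_in) + 1 / len(x_out)) * ss / (n - 2))
        return (m_in - m_out) / (s + s0)

    d_obs = d_stat(set(in_samples))
    all_d = [d_stat(set(c)) for c in combinations(samples, n_in)]
    genes = list(X.columns)
    q = np.empty(len(genes))
    for j, g in enumerate(genes):
        t = abs(d_obs[j])
        counts = [sum(1 for v in dperm if abs(v) >= t) for dperm in all_d]
        called = sum(1 for v in d_obs if abs(v) >= t)
        q[j] = min(np.median(counts) / called, 1.0)
    # monotone non-increasing in |d|
    order = np.argsort(-np.abs(d_obs), kind="mergesort")
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q_sorted
    return d_obs, out


class TestSamPermutationFdr:
    def test_exhaustive_enumeration_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = frame(rng.normal(size=(8, 15)))
        X.iloc[:4, :4] += 1.5
        in_samples = list(X.index[:4])
        sam = ns.sam_permutation_fdr(X, in_samples, n_perm=100, seed=0,
                                     s0_mode="percentile5")
        assert sam.attrs["exhaustive"]
        assert sam.attrs["n_permutations"] == 70
        s0 = float(sam.s0.iloc[0])
        d_ref, q_ref = brute_force_sam_q(X, in_samples, s0)
        assert np.allclose(sam.d_score, d_ref, atol=1e-12)
        assert np.allclose(sam.q_value, q_ref, atol=1e-12)

    def test_q_values_monotone_in_abs_d(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(size=(16, 40)))
        X.iloc[:8, :6] += 1.0
        sam = ns.sam_permutation_fdr(X, list(X.index[:8]), n_perm=200, seed=1,
                                     s0_mode="percentile5")
        ordered = sam.sort_values("d_score", key=np.abs, ascending=False)
        assert (np.diff(ordered.q_value) >= -1e-12).all()

    def test_null_calibration_over_replicate_cohorts(self):
        """Labels independent of data: q < 0.05 fraction near or below nominal."""
        rng = np.random.default_rng(5)
        flagged = total = 0
        for _ in range(100):
            X = frame(rng.normal(size=(20, 50)))
            in_samples = list(rng.choice(X.index, size=10, replace=False))
            sam = ns.sam_permutation_fdr(X, in_samples, n_perm=100,
                                         seed=int(rng.integers(2**31)),
                                         s0_mode="percentile5")
            flagged += (sam.q_value < 0.05).sum()
            total += len(sam)
        rate = flagged / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se

    def test_tiny_groups_warn_about_resolution(self):
        X = frame(np.random.default_rng(6).normal(size=(5, 6)))
        with pytest.warns(RuntimeWarning, match="arrangements"):
            ns.sam_permutation_fdr(X, list(X.index[:2]), n_perm=50, seed=0,
                                   s0_mode="percentile5")


class TestSelectSignificant:
    def test_selection_rule(self):
        sam = pd.DataFrame(
            {"d_score": [16.0, 16.0, -20.0, 14.0], "q_value": [0.01, 0.2, 0.001, 0.01]},
            index=["a", "b", "c", "d"],
        )
        assert ns.select_significant(sam) == ["a"]
        # symmetric mode admits the strongly negative gene too
        assert ns.select_significant(sam, two_sided=True) == ["a", "c"]


class TestSubnetworks:
    def test_triangle_becomes_single_module(self):
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        F = frame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], genes=["a", "b", "c"])
        modules = ns.extract_subnetworks(["a", "b", "c"], net, F, ["s0"])
        assert len(modules) == 1
        assert modules[0].graph.number_of_edges() == 3

    def test_disconnected_genes_become_singletons(self):
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "x", 1), ("b", "y", 1)])
        F = frame([[1.0, 0.5, 0.2, 0.1]], genes=["a", "b", "x", "y"])
        modules = ns.extract_subnetworks(["a", "b"], net, F, ["s0"])
        assert len(modules) == 2
        assert all(m.graph.number_of_nodes() == 1 for m in modules)

    def test_node_scores_are_in_group_column_means(self):
        rng = np.random.default_rng(7)
        F = frame(rng.random((6, 4)), genes=["a", "b", "c", "d"])
        net = nx.Graph()
        net.add_weighted_edges_from([("a", "b", 1), ("c", "d", 1)])
        in_group = list(F.index[:3])
        modules = ns.extract_subnetworks(["a", "b", "c", "d"], net, F, in_group)
        expected = F.loc[in_group].mean(axis=0)
        for module in modules:
            for node in module.nodes:
                assert module.graph.nodes[node]["node_score"] == pytest.approx(
                    expected[node], rel=1e-12
                )

    def test_empty_gene_set_and_missing_genes(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=1.0)
        F = frame([[1.0, 2.0]], genes=["a", "b"])
        assert ns.extract_subnetworks([], net, F, ["s0"]) == []
        with pytest.warns(RuntimeWarning, match="absent"):
            modules = ns.extract_subnetworks(["a", "zz"], net, F, ["s0"])
        assert [m.nodes for m in modules] == [["a"]]


class TestGeneSetOverlap:
    def test_disjoint_identical_and_random_sets(self):
        rng = np.random.default_rng(8)
        disjoint = {1: {"a", "b"}, 2: {"c"}, 3: {"d", "e"}}
        m = ns.gene_set_overlap(disjoint)
        assert (m.to_numpy()[~np.eye(3, dtype=bool)] == 0).all()
        assert list(np.diag(m)) == [2, 1, 2]

        identical = {1: {"a", "b", "c"}, 2: {"a", "b", "c"}}
        assert (ns.gene_set_overlap(identical).to_numpy() == 3).all()

        sets = {g: set(rng.choice(list("abcdefghij"), size=5, replace=False))
                for g in range(4)}
        m = ns.gene_set_overlap(sets)
        for i in sets:
            for j in sets:
                assert m.loc[i, j] == len(sets[i] & sets[j])


class TestWilcoxonExpression:
    def _expr(self, X, genes):
        return pd.DataFrame(np.asarray(X, dtype=float), index=genes,
                            columns=[f"s{i}" for i in range(np.shape(X)[1])])

    def test_identical_distributions_p_one(self):
        expr = self._expr([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["g"])
        assignment = pd.Series([1, 1, 1, 2, 2, 2], index=expr.columns)
        out = ns.wilcoxon_expression(expr, assignment, 1, ["g"])
        assert out.loc["g", "p_value"] == pytest.approx(1.0)

    def test_complete_separation_exact_enumeration(self):
        """{1,2,3} vs {4,5,6}: two-sided exact p = 2/20 = 0.1."""
        expr = self._expr([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], ["g"])
        assignment = pd.Series([1, 1, 1, 2, 2, 2], index=expr.columns)
        out = ns.wilcoxon_expression(expr, assignment, 1, ["g"])
        assert out.loc["g", "method"] == "exact"
        assert out.loc["g", "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_monotone_transform_leaves_p_unchanged(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 30))
        expr = self._expr(X, ["g1", "g2", "g3"])
        assignment = pd.Series([1] * 15 + [2] * 15, index=expr.columns)
        p1 = ns.wilcoxon_expression(expr, assignment, 1, ["g1", "g2", "g3"])["p_value"]
        p2 = ns.wilcoxon_expression(np.exp(expr), assignment, 1,
                                    ["g1", "g2", "g3"])["p_value"]
        assert np.allclose(p1, p2, atol=1e-12)

    def test_absent_gene_skipped_with_warning(self):
        expr = self._expr(np.random.default_rng(10).normal(size=(1, 8)), ["g"])
        assignment = pd.Series([1] * 4 + [2] * 4, index=expr.columns)
        with pytest.warns(RuntimeWarning, match="absent"):
            out = ns.wilcoxon_expression(expr, assignment, 1, ["g", "nope"])
        assert list(out.index) == ["g"]


class TestModuleRecovery:
    def test_planted_modules_recovered_with_little_overlap(self):
        """Per-subgroup selected genes recover planted modules; overlaps stay tiny.

        The absolute selection cut (d > 15) is scale-dependent: d grows like
        sqrt of the harmonic group size, and the threshold belongs to a
        several-thousand-sample cohort.  The check therefore runs at 150
        samples per subgroup (900 total), the smallest cohort of comparable
        statistical scale.
        """
        cohort = ns.generate_cohort(ns.SimConfig(seed=0, samples_per_subgroup=150))
        aligned, net, _ = ns.align_to_network(cohort.gene_matrix, cohort.network)
        profile = ns.smooth_profiles(aligned, net)
        results = ns.influence_analysis(
            profile, cohort.truth, net,
            expression=cohort.expression,
            n_perm=200, seed=5, s0_mode="percentile5",
        )
        recovered = []
        for g in sorted(cohort.truth.unique()):
            module = set(cohort.module_genes[g - 1])
            selected = set(results["gene_sets"][g])
            recovered.append(len(selected & module) / len(module))
        assert np.mean(recovered) >= 0.8
        overlap = results["overlap"].to_numpy()
        off_diag = overlap[~np.eye(len(overlap), dtype=bool)]
        assert off_diag.mean() < 0.05 * np.diag(overlap).mean()
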