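"""Signed co-expression network: correlation, adjacency, TOM, clustering,
eigengenes, module-trait statistics, temporal classes."""

import numpy as np
import pandas as pd
import pytest

from lncstage import (
    PipelineConfig,
    average_linkage,
    classify_temporal_modules,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    pearson_matrix,
    pick_soft_threshold,
    signed_adjacency,
    tom_similarity,
    tree_cut_modules,
)
from lncstage.modules import GREY, kme_cleanup, student_t_pvalue
from lncstage.simulate import generate_expression, planted_membership

from conftest import small_design, toy_expression


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop brute-force topological overlap; the independent oracle."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def naive_upgma(d: np.ndarray):
    """Independent UPGMA re-derivation; returns sorted merge heights.

    Uses the defining UPGMA property that the distance between two clusters
    is the unweighted mean of all original pairwise distances between their
    members, recomputed from scratch at every step.
    """
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


class TestPearson:
    def test_diagonal_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=21)
        vals = np.exp2(np.vstack([base, 10 - base])) - 1
        expr = toy_expression(vals)
        cor = pearson_matrix(expr)
        assert cor.iloc[0, 0] == 1.0
        assert cor.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_ratio_oracle(self):
        rng = np.random.default_rng(33)
        vals = rng.uniform(0, 20, size=(10, 21))
        expr = toy_expression(vals)
        cor = pearson_matrix(expr).to_numpy()
        x = np.log2(vals + 1)
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        vals = np.ones((2, 21))
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_matrix(toy_expression(vals))


class TestSignedAdjacency:
    @pytest.mark.parametrize("r,beta,expected", [(1.0, 6, 1.0), (-1.0, 6, 0.0), (0.0, 2, 0.25)])
    def test_closed_forms(self, r, beta, expected):
        cor = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        a = signed_adjacency(cor, beta)
        assert a.iloc[0, 1] == pytest.approx(expected)
        assert a.iloc[0, 0] == 1.0

    def test_non_integer_beta_rejected(self):
        cor = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            signed_adjacency(cor, 0)


class TestTOM:
    def test_two_feature_closed_form(self):
        for a12 in (0.0, 0.3, 0.9):
            a = pd.DataFrame([[1.0, a12], [a12, 1.0]])
            tom = tom_similarity(a)
            assert tom.iloc[0, 1] == pytest.approx(a12, abs=1e-15)

    def test_zero_adjacency_zero_tom(self):
        a = pd.DataFrame(np.eye(5))
        tom = tom_similarity(a)
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(44)
        a = random_adjacency(rng, 8)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom_oracle(a), atol=1e-12)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(45)
        for n in (3, 6, 10):
            a = random_adjacency(rng, n)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.all(tom >= 0) and np.all(tom <= 1)
            assert np.allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame(a))


class TestAverageLinkage:
    def test_identical_features_merge_at_zero(self):
        d = pd.DataFrame([[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]])
        merges = average_linkage(d)
        assert merges[0, 2] == 0.0

    def test_three_point_hand_computation(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.8], [0.1, 0.0, 0.9], [0.8, 0.9, 0.0]]
        )
        merges = average_linkage(d)
        assert merges[0, 2] == pytest.approx(0.1)
        assert merges[1, 2] == pytest.approx(0.85)  # (0.8 + 0.9) / 2

    def test_matches_independent_upgma(self):
        rng = np.random.default_rng(55)
        m = rng.uniform(0.1, 1.0, size=(15, 15))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        merges = average_linkage(pd.DataFrame(d))
        assert np.allclose(sorted(merges[:, 2]), naive_upgma(d), atol=1e-10)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(56)
        m = rng.uniform(0, 1, size=(12, 12))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        merges = average_linkage(pd.DataFrame(d))
        assert np.all(np.diff(merges[:, 2]) >= -1e-12)


class TestTreeCut:
    def _block_dissimilarity(self, sizes, within=0.05, between=0.95):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d)

    def test_two_planted_blocks_found(self):
        d = self._block_dissimilarity([30, 30])
        merges = average_linkage(d)
        labels = tree_cut_modules(merges, [f"f{i}" for i in range(60)], min_module_size=20)
        assert len(set(labels) - {GREY}) == 2
        assert (labels != GREY).all()
        assert labels.iloc[:30].nunique() == 1 and labels.iloc[30:].nunique() == 1

    def test_all_dissimilar_all_grey(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.8, 1.0, size=(15, 15))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        merges = average_linkage(pd.DataFrame(d))
        labels = tree_cut_modules(merges, [f"f{i}" for i in range(15)], min_module_size=20)
        assert (labels == GREY).all()

    def test_sizes_non_increasing_across_label_order(self):
        d = self._block_dissimilarity([40, 25, 30])
        merges = average_linkage(d)
        labels = tree_cut_modules(merges, [f"f{i}" for i in range(95)], min_module_size=20)
        sizes = labels[labels != GREY].value_counts()
        assert list(sizes.index) == ["turquoise", "blue", "brown"]
        assert sizes["turquoise"] == 40 and sizes["blue"] == 30 and sizes["brown"] == 25

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            tree_cut_modules(np.empty((0, 4)), [], min_module_size=1)


class TestEigengene:
    def test_identical_rows_rank_one(self):
        rng = np.random.default_rng(12)
        profile = rng.normal(4, 1, size=21)
        vals = np.exp2(np.tile(profile, (5, 1))) - 1
        expr = toy_expression(np.maximum(vals, 0))
        eg = module_eigengene(expr, expr.feature_ids)
        assert eg.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        expected = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eg.values.to_numpy()), np.abs(expected), atol=1e-8)

    def test_orientation_positive_with_mean_profile(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            vals = np.random.default_rng(seed).uniform(0, 30, size=(10, 21))
            expr = toy_expression(vals)
            eg = module_eigengene(expr, expr.feature_ids)
            x = np.log2(vals + 1)
            z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(eg.values, z.mean(0))[0, 1] > 0

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(77)
        vals = rng.uniform(0, 30, size=(10, 21))
        expr = toy_expression(vals)
        eg = module_eigengene(expr, expr.feature_ids).values.to_numpy()
        x = np.log2(vals + 1)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        v = power_iteration_eigengene(z)
        assert min(np.linalg.norm(eg - v), np.linalg.norm(eg + v)) < 1e-8

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(78)
        vals = rng.uniform(0, 30, size=(8, 21))
        expr = toy_expression(vals)
        eg1 = module_eigengene(expr, expr.feature_ids).values.to_numpy()
        eg2 = module_eigengene(expr, list(reversed(expr.feature_ids))).values.to_numpy()
        assert np.allclose(eg1, eg2, atol=1e-8)

    def test_constant_row_rejected(self):
        vals = np.vstack([np.ones(21), np.arange(21.0)])
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(toy_expression(vals), ["f0", "f1"])


def power_iteration_eigengene(z: np.ndarray, iters: int = 5000) -> np.ndarray:
    """Dominant right singular vector via power iteration on z^T z."""
    m = z.T @ z
    rng = np.random.default_rng(1)
    v = rng.normal(size=m.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(iters):
        v = m @ v
        v /= np.linalg.norm(v)
    return v


class TestModuleTrait:
    def test_published_f45_pair(self):
        # r = 0.64 over 21 samples prints as p = 0.002
        assert round(student_t_pvalue(0.64, 21), 3) == 0.002

    def test_published_f90_bound(self):
        assert student_t_pvalue(0.98, 21) <= 2e-14

    def test_r_zero(self):
        assert student_t_pvalue(0.0, 21) == 1.0

    def test_perfect_correlation_p_zero(self):
        assert student_t_pvalue(1.0, 21) == 0.0

    def test_p_strictly_decreasing_in_abs_r(self):
        ps = [student_t_pvalue(r, 21) for r in np.linspace(0.0, 0.99, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_stage_indicator_correlations(self):
        d = small_design(seed=1)
        expr = generate_expression(d)
        mem = planted_membership(d)
        members = [f for f, lab in mem.items() if lab == "early"]
        eg = module_eigengene(expr, members)
        stats_df = module_trait_correlation(eg.values, expr.sample_meta)
        sig = set(stats_df.loc[stats_df["significant"], "stage"])
        assert sig == {"F45", "F65"}
        # t/p consistency with the closed form
        for row in stats_df.itertuples():
            assert row.p_value == pytest.approx(student_t_pvalue(row.r, 21), abs=1e-12)
            assert row.df == 19


class TestTemporalClassification:
    @pytest.mark.parametrize(
        "sig,expected",
        [
            ({"F45", "F65", "F90"}, "early"),
            ({"F45", "F65"}, "early"),
            ({"F135", "B1", "B90"}, "late"),
            ({"F90"}, "stage_specific"),
            (set(), "none"),
            ({"F45", "B90"}, "mixed"),
        ],
    )
    def test_rules(self, sig, expected):
        df = pd.DataFrame(
            {
                "stage": list("ABCDEFG"),
                "significant": [False] * 7,
            }
        )
        df["stage"] = ["F45", "F65", "F90", "F120", "F135", "B1", "B90"]
        df["significant"] = df["stage"].isin(sig)
        assert classify_temporal_modules({"m": df})["m"] == expected


class TestSoftThreshold:
    def test_fit_table_has_all_powers(self):
        rng = np.random.default_rng(99)
        vals = rng.uniform(0, 20, size=(40, 21))
        cor = pearson_matrix(toy_expression(vals))
        beta, table = pick_soft_threshold(cor, powers=range(1, 13))
        assert len(table) == 12
        assert 1 <= beta <= 12

    def test_selection_rule_consistent_with_fit_table(self):
        for seed in (0, 1, 2):
            d = small_design(seed=seed)
            expr = generate_expression(d)
            mem = planted_membership(d)
            feats = [f for f, lab in mem.items() if lab != "background"]
            cor = pearson_matrix(expr, feats)
            beta, table = pick_soft_threshold(cor)
            reaching = table[table["signed_r2"] >= 0.8]
            if not reaching.empty:
                assert beta == int(reaching["power"].iloc[0])
            else:
                assert beta == int(table.loc[table["signed_r2"].idxmax(), "power"])


class TestEndToEndModules:
    def test_planted_modules_recovered_small(self):
        d = small_design(seed=9)
        expr = generate_expression(d)
        mem = planted_membership(d)
        planted = [f for f, lab in mem.items() if lab != "background" and f.startswith("LNC")]
        res = detect_modules(expr, planted, PipelineConfig(min_module_size=15))
        labels = res["labels"]
        assert len(set(labels) - {GREY}) == 2
        early = [f for f in planted if mem[f] == "early"]
        assert labels.loc[early].nunique() == 1
        classes = set(res["temporal_classes"].values())
        assert classes == {"early", "late"}

    def test_kme_cleanup_removes_weak_members(self):
        d = small_design(seed=11)
        expr = generate_expression(d)
        mem = planted_membership(d)
        early = [f for f, lab in mem.items() if lab == "early"]
        background = [f for f, lab in mem.items() if lab == "background"][:10]
        labels = pd.Series(
            "turquoise", index=pd.Index(early + background, name="feature_id")
        )
        cleaned = kme_cleanup(expr, labels, kme_min=0.7, min_module_size=15)
        assert (cleaned.loc[early] != GREY).all()
        assert (cleaned.loc[background] == GREY).all()
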