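import math

import numpy as np
import pandas as pd
import pytest

from triadnet import coexpression_network as cx, expression_io as eio


def expr(rows: dict) -> eio.ExpressionMatrix:
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return eio.ExpressionMatrix(df)


class TestAdjacency:
    def test_power_of_absolute_correlation(self):
        # genes with Pearson correlation exactly 0.5
        X = expr({"g1": [1, 2, 3], "g2": [1, 3, 2]})
        assert np.corrcoef(X.values.values)[0, 1] == pytest.approx(0.5)
        A2 = cx.adjacency(X, 2)
        assert A2.loc["g1", "g2"] == pytest.approx(0.25)
        A1 = cx.adjacency(X, 1)
        assert A1.loc["g1", "g2"] == pytest.approx(0.5)

    def test_perfect_pair_is_one_for_any_power(self):
        X = expr({"g1": [1, 2, 3], "g2": [2, 4, 6]})
        for beta in (1, 6, 20):
            assert cx.adjacency(X, beta).loc["g1", "g2"] == pytest.approx(1.0)

    def test_zero_variance_gene_warned_and_zeroed(self):
        X = expr({"g1": [1, 2, 3], "g2": [5, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            A = cx.adjacency(X, 2)
        assert A.loc["g1", "g2"] == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        X = expr({f"g{i}": rng.random(8) for i in range(12)})
        for beta in (1, 3, 20):
            A = cx.adjacency(X, beta).values
            assert np.abs(A - A.T).max() < 1e-12
            assert A.min() >= 0 and A.max() <= 1


class TestSoftThreshold:
    def test_exact_power_law_scores_high(self):
        # degree sequence with frequency proportional to 1/k
        ks = np.concatenate([np.full(1200 // k, float(k)) for k in range(1, 11)])
        assert cx.scale_free_fit(ks) >= 0.99

    def test_single_beta_grid_selected(self, toy_expression):
        X, _ = toy_expression
        rep = cx.pick_soft_threshold(X, grid=[7], r2_goal=0.85)
        assert rep.selected == 7

    def test_mean_connectivity_decreases_in_beta(self):
        rng = np.random.default_rng(1)
        X = expr({f"g{i}": rng.random(10) for i in range(30)})
        rep = cx.pick_soft_threshold(X, grid=range(1, 11), r2_goal=0.85)
        mk = rep.table["mean_k"].values
        assert (np.diff(mk) < 0).all()


class TestTom:
    def test_no_shared_neighbors_no_adjacency(self):
        A = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        W = cx.tom(A)
        assert W.values[np.triu_indices(3, 1)].max() == 0.0

    def test_complete_graph_has_full_overlap(self):
        A = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        W = cx.tom(A)
        assert W.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_three_gene_case(self):
        # a12 = a13 = 0.5, a23 = 0
        A = pd.DataFrame(
            [[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1]], index=list("abc"), columns=list("abc")
        )
        # w23 = (l23 + a23)/(min(k2,k3) + 1 - a23); l23 = a21*a13 = 0.25; k2 = k3 = 0.5
        expected = (0.25 + 0.0) / (0.5 + 1.0 - 0.0)
        W = cx.tom(A)
        assert W.loc["b", "c"] == pytest.approx(expected)
        # w12: l12 = a13*a32 = 0; (0 + 0.5)/(min(1,0.5) + 1 - 0.5) = 0.5
        assert W.loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(2)
        M = rng.random((15, 15))
        A = pd.DataFrame((M + M.T) / 2, index=range(15), columns=range(15))
        np.fill_diagonal(A.values, 1.0)
        W = cx.tom(A).values
        assert np.abs(W - W.T).max() < 1e-12
        assert W.min() >= 0 and W.max() <= 1


class TestModuleDetection:
    def test_block_diagonal_recovers_two_modules(self):
        n = 30
        blocks = np.zeros((2 * n, 2 * n))
        blocks[:n, :n] = 0.8
        blocks[n:, n:] = 0.8
        np.fill_diagonal(blocks, 1.0)
        genes = [f"g{i}" for i in range(2 * n)]
        W = cx.tom(pd.DataFrame(blocks, index=genes, columns=genes))
        assign = cx.detect_modules(W, min_module_size=10, cut_height=0.5)
        assert assign.nunique() == 2
        assert assign.iloc[:n].nunique() == 1 and assign.iloc[n:].nunique() == 1

    def test_min_size_above_n_leaves_all_unassigned(self):
        rng = np.random.default_rng(0)
        M = rng.random((10, 10))
        A = pd.DataFrame((M + M.T) / 2, index=range(10), columns=range(10))
        assign = cx.detect_modules(cx.tom(A), min_module_size=50)
        assert (assign == cx.UNASSIGNED).all()


class TestEigengenesAndMerge:
    def test_identical_gene_module_explains_all_variance(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0])
        X = expr({f"g{i}": prof for i in range(4)})
        assign = pd.Series("M1", index=X.gene_ids)
        mes, varex = cx.module_eigengenes(X, assign)
        assert varex["M1"] == pytest.approx(1.0)
        z = (prof - prof.mean()) / prof.std()
        r = np.corrcoef(mes["M1"], z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign aligned with the module mean profile

    def test_sign_alignment_is_stable(self):
        rng = np.random.default_rng(3)
        X = expr({f"g{i}": rng.random(6) for i in range(5)})
        assign = pd.Series("M1", index=X.gene_ids)
        mes, _ = cx.module_eigengenes(X, assign)
        mean_prof = X.values.mean(axis=0)
        assert np.corrcoef(mes["M1"], mean_prof)[0, 1] >= 0

    def test_split_module_remerges(self):
        rng = np.random.default_rng(4)
        base = rng.random(8)
        X = expr({f"g{i}": base + rng.normal(0, 0.01, 8) for i in range(20)})
        assign = pd.Series(["M1"] * 10 + ["M2"] * 10, index=X.gene_ids)
        merged = cx.merge_modules(assign, X, threshold=0.9)
        assert merged.nunique() == 1

    def test_anticorrelated_modules_never_merge(self):
        rng = np.random.default_rng(5)
        base = rng.random(8)
        X = expr(
            {f"a{i}": base + rng.normal(0, 0.01, 8) for i in range(5)}
            | {f"b{i}": (1 - base) + rng.normal(0, 0.01, 8) for i in range(5)}
        )
        assign = pd.Series(["M1"] * 5 + ["M2"] * 5, index=X.gene_ids)
        merged = cx.merge_modules(assign, X, threshold=0.9)
        assert merged.nunique() == 2

    def test_correlated_triple_converges_to_one_module(self):
        # three modules built from latent profiles with pairwise correlation > 0.9
        rng = np.random.default_rng(6)
        z = rng.standard_normal(12)
        latents = [z + rng.normal(0, 0.25, 12) for _ in range(3)]
        rows = {}
        for m, lat in enumerate(latents):
            for i in range(6):
                rows[f"m{m}g{i}"] = 10 + lat + rng.normal(0, 0.05, 12)
        X = expr(rows)
        assign = pd.Series(
            [f"M{m + 1}" for m in range(3) for _ in range(6)], index=X.gene_ids
        )
        merged = cx.merge_modules(assign, X, threshold=0.9)
        assert merged.nunique() == 1


class TestGeneSignificance:
    def test_tissue_restricted_gene_has_high_gs(self, toy_expression):
        X, meta = toy_expression
        vals = X.values.copy()
        vals.loc["g1"] = [10.0, 0.0, 10.0, 0.0]  # expressed only in lung
        gs = cx.gene_significance(eio.ExpressionMatrix(vals), meta, "lung")
        assert gs["g1"] == pytest.approx(1.0)

    def test_constant_gene_scores_zero(self, toy_expression):
        X, meta = toy_expression
        vals = X.values.copy()
        vals.loc["g1"] = 7.0
        gs = cx.gene_significance(eio.ExpressionMatrix(vals), meta, "lung")
        assert gs["g1"] == 0.0


class TestNetworkConcepts:
    def test_complete_graph_limits(self):
        n = 5
        A = pd.DataFrame(np.ones((n, n)), index=range(n), columns=range(n))
        c = cx.network_concepts(A)
        assert c.density == pytest.approx(1.0)
        assert c.mean_cluster_coef == pytest.approx(1.0)
        assert c.centralization == pytest.approx(0.0)
        assert c.heterogeneity == pytest.approx(0.0)

    def test_unweighted_star_hand_values(self):
        n = 5
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 1.0
        c = cx.network_concepts(pd.DataFrame(A, index=range(n), columns=range(n)))
        # k = (4,1,1,1,1): density 8/20; CL = (5/3)(1 - 0.4); HG = sd/mean
        assert c.density == pytest.approx(0.4)
        assert c.mean_cluster_coef == pytest.approx(0.0)
        assert c.centralization == pytest.approx(1.0)
        k = np.array([4, 1, 1, 1, 1])
        assert c.heterogeneity == pytest.approx(np.sqrt(k.var()) / k.mean())

    def test_matches_brute_force_on_random_unweighted_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            M = (rng.random((n, n)) < 0.5).astype(float)
            M = np.triu(M, 1)
            M = M + M.T
            got = cx.network_concepts(pd.DataFrame(M, index=range(n), columns=range(n)))
            exp = brute_concepts(M)
            for key in ("density", "mean_cluster_coef", "centralization", "heterogeneity"):
                assert getattr(got, key) == pytest.approx(exp[key], abs=1e-12)

    def test_too_small_module_rejected(self):
        A = pd.DataFrame(np.ones((2, 2)), index=range(2), columns=range(2))
        with pytest.raises(ValueError):
            cx.network_concepts(A)


def brute_concepts(M: np.ndarray) -> dict:
    """Direct-formula oracle with explicit loops (independent of the impl)."""
    n = M.shape[0]
    M = M.copy().astype(float)
    np.fill_diagonal(M, 0.0)
    k = [sum(M[i, j] for j in range(n) if j != i) for i in range(n)]
    density = sum(M[i, j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    ccs = []
    for i in range(n):
        num = sum(
            M[i, j] * M[j, u] * M[u, i]
            for j in range(n)
            for u in range(n)
            if j != i and u != i and u != j
        )
        den = k[i] ** 2 - sum(M[i, j] ** 2 for j in range(n) if j != i)
        ccs.append(num / den if den > 0 else 0.0)
    mean_k = sum(k) / n
    var_k = sum((x - mean_k) ** 2 for x in k) / n
    return {
        "density": density,
        "mean_cluster_coef": sum(ccs) / n,
        "centralization": (n / (n - 2)) * (max(k) / (n - 1) - density),
        "heterogeneity": math.sqrt(var_k) / mean_k if mean_k > 0 else 0.0,
    }


class TestKeyModulesAndHubs:
    def _fixture(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(18)]
        tissues = ["lung", "liver", "heart"] * 6
        meta = eio.SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "condition": ["A"] * 18,
                    "tissue": tissues,
                    "replicate": list(range(1, 7)) * 3,
                }
            )
        )
        indicator = (np.array(tissues) == "lung").astype(float)
        mes = pd.DataFrame(
            {
                "M1": indicator + rng.normal(0, 0.05, 18),  # strong lung association
                "M2": rng.normal(0, 1, 18),
            },
            index=samples,
        )
        stats = pd.DataFrame(
            {
                "module": ["M1"] * 10 + ["M2"] * 10,
                "GS_lung": [0.9] * 10 + [0.2] * 10,
                "GS_liver": [0.1] * 20,
                "GS_heart": [0.1] * 20,
                "kWithin": np.arange(20, 0, -1, dtype=float),
                "MM": [0.97] * 20,
                "kTotal": np.arange(20, 0, -1, dtype=float) + 1,
            },
            index=[f"g{i}" for i in range(20)],
        )
        return mes, meta, stats

    def test_key_requires_both_criteria(self):
        mes, meta, stats = self._fixture()
        keys = cx.key_modules(mes, meta, stats)
        key_pairs = set(map(tuple, keys.loc[keys.is_key, ["module", "tissue"]].values))
        assert key_pairs == {("M1", "lung")}
        m1lung = keys[(keys.module == "M1") & (keys.tissue == "lung")].iloc[0]
        assert m1lung["p"] < m1lung["bonferroni_threshold"]
        # M2 fails criterion 1 regardless of GS; M1/liver fails both
        assert keys["bonferroni_threshold"].nunique() == 1
        assert keys["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 6)

    def test_high_gs_alone_is_not_key(self):
        mes, meta, stats = self._fixture()
        stats = stats.copy()
        stats.loc[stats.module == "M2", "GS_lung"] = 0.95
        keys = cx.key_modules(mes, meta, stats)
        m2 = keys[(keys.module == "M2") & (keys.tissue == "lung")].iloc[0]
        assert m2["median_GS"] > 0.8 and not m2["is_key"]

    def test_hub_criteria_with_inclusive_boundaries(self):
        stats = pd.DataFrame(
            {
                "module": ["M1"] * 10,
                "GS_lung": [0.9, 0.79, 0.9, 0.8] + [0.9] * 6,
                "MM": [0.96, 0.97, 0.94, 0.95] + [0.96] * 6,
                "kWithin": [10.0, 9.0, 8.0, 7.0] + list(np.arange(6.0, 0.0, -1)),
                "kTotal": [11.0] * 10,
            },
            index=[f"g{i}" for i in range(10)],
        )
        hubs = cx.hub_genes(stats, {"M1": "lung"})
        # top-20% rank cutoff = ceil(0.2*10) = 2: only g0 passes all three
        assert hubs["M1"] == ["g0"]
        # widen the rank window so the boundary gene (rank 4, GS .8, MM .95) is in
        hubs = cx.hub_genes(stats, {"M1": "lung"}, top_k_fraction=0.4)
        assert hubs["M1"] == ["g0", "g3"]
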