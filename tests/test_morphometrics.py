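import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dunnartdelim import morphometrics as mm
from dunnartdelim.synthetic_data import MorphoSimConfig, simulate_morphotable


def make_table(values, groups=None, columns=None, ids=None):
    values = np.asarray(values, float)
    n, p = values.shape
    ids = ids or [f"i{k}" for k in range(n)]
    columns = columns or [f"v{k}" for k in range(p)]
    groups = groups or ["G"] * n
    df = pd.DataFrame(values, index=ids, columns=columns)
    return mm.MorphoTable(df, pd.Series(groups, index=ids))


class TestFilterMissing:
    def test_complete_table_unchanged(self):
        t = make_table(np.ones((4, 3)))
        out, log = mm.filter_missing(t)
        assert out.data.shape == (4, 3) and log == []

    def test_variable_then_individual_order(self):
        """A 16%-missing individual (over surviving variables) is removed by
        the 15% rule after a >20%-missing variable is dropped first."""
        X = np.ones((10, 6))
        X[:3, 0] = np.nan  # variable v0: 30% missing -> dropped
        # individual i0: missing 1 of remaining 5 variables = 20% > 15%
        X[0, 1] = np.nan
        t = make_table(X)
        out, log = mm.filter_missing(t)
        kinds = {(e["kind"], e["name"]) for e in log}
        assert ("variable", "v0") in kinds
        assert ("individual", "i0") in kinds
        assert "v0" not in out.data.columns and "i0" not in out.data.index

    def test_hand_enumerated_survivors(self):
        X = np.ones((10, 6))
        X[0:3, 0] = np.nan  # 30% -> drop v0
        X[0:2, 1] = np.nan  # 20% -> keep v1 (not > 20%)
        X[4, 2] = np.nan  # i4 misses 1/5 of surviving = 20% -> drop
        t = make_table(X)
        out, _ = mm.filter_missing(t)
        assert list(out.data.columns) == ["v1", "v2", "v3", "v4", "v5"]
        # i0, i1 (miss v1) and i4 (miss v2) each exceed 15% over 5 variables
        assert sorted(out.data.index) == sorted(
            [f"i{k}" for k in range(10) if k not in (0, 1, 4)]
        )

    def test_sixteen_percent_individual_removed(self):
        # 25 variables; individual missing 4 -> 16% > 15%
        X = np.ones((6, 25))
        X[0, :4] = np.nan
        t = make_table(X)
        out, log = mm.filter_missing(t)
        entry = [e for e in log if e["kind"] == "individual"][0]
        assert entry["name"] == "i0"
        assert entry["fraction"] == pytest.approx(0.16)
        assert "i0" not in out.data.index


class TestPruneCorrelated:
    def test_duplicate_column_removed_anchor_kept(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 2, 20)
        t = make_table(np.column_stack([x, x, rng.uniform(1, 2, 20)]))
        out, log = mm.prune_correlated(t)
        assert list(out.data.columns) == ["v0", "v2"]
        assert log[0]["name"] == "v1" and log[0]["anchor"] == "v0"

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.uniform(1, 2, (30, 2)))
        out, log = mm.prune_correlated(t)
        assert out.data.shape[1] == 2 and log == []

    @staticmethod
    def _prune_oracle(df, thresh):
        """Independent re-implementation of the stated pruning rule:
        repeatedly drop the non-anchor of the largest-|r| pair."""
        import itertools

        cols = list(df.columns)
        while len(cols) > 1:
            best = None
            for a, b in itertools.combinations(cols, 2):
                r = abs(df[a].corr(df[b]))
                if r > thresh and (best is None or r > best[0]):
                    best = (r, a, b)
            if best is None:
                break
            _, a, b = best
            na, nb = df[a].isna().sum(), df[b].isna().sum()
            if na < nb or (na == nb and list(df.columns).index(a)
                           < list(df.columns).index(b)):
                cols.remove(b)
            else:
                cols.remove(a)
        return cols

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_chain_fixtures_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(10, 20, 200)
        y = x * np.exp(rng.normal(0, 0.075, 200))
        z = y * np.exp(rng.normal(0, 0.075, 200))
        w = rng.uniform(10, 20, 200)  # independent control column
        df = pd.DataFrame({"x": x, "y": y, "z": z, "w": w})
        t = make_table(df.to_numpy(), columns=list(df.columns))
        out, _ = mm.prune_correlated(t, r_thresh=0.90)
        assert list(out.data.columns) == self._prune_oracle(t.data, 0.90)
        assert "w" in out.data.columns


class TestPMMImpute:
    def test_no_missing_identity(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.uniform(1, 2, (10, 3)))
        out = mm.pmm_impute(t, seed=42)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_donor_property_and_range(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(5, 10, (30, 4))
        mask = rng.random((30, 4)) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        t = make_table(Xm)
        out = mm.pmm_impute(t, seed=0)
        for j, col in enumerate(t.data.columns):
            observed = set(t.data[col].dropna())
            for i in np.flatnonzero(mask[:, j]):
                v = out.data.iloc[i, j]
                assert v in observed  # imputed value is an observed donor value
                assert min(observed) <= v <= max(observed)

    def test_mvn_rmse_below_column_sd(self):
        """MCAR-deleted cells from correlated data are recovered with RMSE
        below the column SD (PMM exploits the correlation)."""
        rng = np.random.default_rng(5)
        rmses, sds = [], []
        for seed in range(5):
            z = rng.normal(size=(60, 1))
            X = np.exp(0.05 * (z + 0.3 * rng.normal(size=(60, 4)))) * 10
            mask = rng.random(X.shape) < 0.12
            Xm = X.copy()
            Xm[mask] = np.nan
            t = make_table(Xm)
            out = mm.pmm_impute(t, seed=seed, iterations=20)
            err = (out.data.to_numpy() - X)[mask]
            rmses.append(np.sqrt((err**2).mean()))
            sds.append(np.nanstd(Xm, ddof=1, axis=0).mean())
        assert np.mean(rmses) < np.mean(sds)

    def test_too_few_complete_cases(self):
        X = np.ones((6, 2))
        X[:4, 0] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            mm.pmm_impute(make_table(X), donors=5)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(1, 2, (20, 3))
        X[rng.random((20, 3)) < 0.1] = np.nan
        t = make_table(X)
        a = mm.pmm_impute(t, seed=7).data
        b = mm.pmm_impute(t, seed=7).data
        pd.testing.assert_frame_equal(a, b)


class TestUnivariateTests:
    def test_identical_groups_f_zero(self):
        vals = np.tile(np.linspace(1, 2, 8)[:, None], (2, 1))
        t = make_table(vals, groups=["A"] * 8 + ["B"] * 8)
        res = mm.univariate_tests(t)[0]
        assert res.test == "anova"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_unequal_variance_routes_to_kruskal(self):
        rng = np.random.default_rng(8)
        a = 10 + rng.normal(0, 0.1, 25)
        b = 10 + rng.normal(0, 1.0, 25)  # 10x the SD: Bartlett rejects
        t = make_table(np.concatenate([a, b])[:, None], groups=["A"] * 25 + ["B"] * 25)
        res = mm.univariate_tests(t)[0]
        assert res.bartlett_pvalue < 0.05
        assert res.test == "kruskal_wallis"
        assert res.tukey_pvalues == {}

    def test_three_group_fixture_matches_closed_forms(self):
        """ANOVA F and Kruskal-Wallis H recomputed from their textbook
        formulas; Tukey p-values cross-checked against statsmodels."""
        rng = np.random.default_rng(9)
        groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        y = np.concatenate(
            [10 + rng.normal(0, 1, 10), 11 + rng.normal(0, 1, 10),
             12.5 + rng.normal(0, 1, 10)]
        )
        t = make_table(y[:, None], groups=groups)
        res = mm.univariate_tests(t)[0]
        samples = [y[:10], y[10:20], y[20:]]
        if res.test == "anova":
            gm_all = y.mean()
            ssb = sum(len(s) * (s.mean() - gm_all) ** 2 for s in samples)
            ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
            f_hand = (ssb / 2) / (ssw / 27)
            assert res.statistic == pytest.approx(f_hand, rel=1e-9)
            sm = pytest.importorskip("statsmodels.stats.multicomp")
            tk = sm.pairwise_tukeyhsd(y, np.array(groups))
            for (pair, p_ours), p_sm in zip(
                sorted(res.tukey_pvalues.items()), tk.pvalues
            ):
                assert p_ours == pytest.approx(p_sm, abs=1e-4)
        else:  # pragma: no cover - fixture built to pass Bartlett
            pytest.fail("expected the ANOVA path")

    def test_degenerate_group_flagged(self):
        X = np.ones((3, 1)) * np.arange(1, 4)[:, None]
        t = make_table(X, groups=["A", "A", "B"])
        res = mm.univariate_tests(t)[0]
        assert res.test == "na"


class TestSizeShape:
    def test_hand_arithmetic(self):
        t = make_table([[4.0, 9.0]])
        ss = mm.size_and_shape(t)
        assert ss.gm.iloc[0] == pytest.approx(6.0)
        np.testing.assert_allclose(
            ss.shape.iloc[0], [math.log(2 / 3), math.log(3 / 2)]
        )

    def test_equal_variables_zero_shape(self):
        t = make_table([[3.0, 3.0, 3.0]])
        ss = mm.size_and_shape(t)
        np.testing.assert_allclose(ss.shape.iloc[0], 0.0, atol=1e-12)

    @given(
        st.lists(st.floats(0.5, 50), min_size=2, max_size=6),
        st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_sum_zero_and_scale_invariance(self, row, c):
        t = make_table([row])
        ss = mm.size_and_shape(t)
        assert abs(ss.shape.iloc[0].sum()) < 1e-10
        t2 = make_table([[c * v for v in row]])
        ss2 = mm.size_and_shape(t2)
        np.testing.assert_allclose(ss2.shape.iloc[0], ss.shape.iloc[0], atol=1e-8)
        assert ss2.gm.iloc[0] == pytest.approx(c * ss.gm.iloc[0], rel=1e-8)


class TestPCA:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.uniform(1, 2, (20, 5)))
        res = mm.pca_correlation(t.data)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_fractions) <= 1e-12).all()

    def test_rank_one_data(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(1, 2, 15)
        t = make_table(np.column_stack([f, 2 * f, 0.5 * f]))
        res = mm.pca_correlation(t.data)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(rng.uniform(1, 2, (25, 4)))
        res = mm.pca_correlation(data)
        Z = (data - data.mean()) / data.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_eigenvalues_match_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(13)
        data = pd.DataFrame(rng.uniform(1, 2, (30, 5)))
        res = mm.pca_correlation(data)
        Z = (data - data.mean()) / data.std(ddof=1)
        ref = sk.PCA().fit(Z)
        np.testing.assert_allclose(
            res.variance_fractions, ref.explained_variance_ratio_, atol=1e-8
        )

    def test_constant_variable_named(self):
        t = make_table([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="v0"):
            mm.pca_correlation(t.data)


class TestUPGMA:
    def test_three_point_hand_heights(self):
        vals = np.array([[0, 2, 4], [2, 0, 4.5], [4, 4.5, 0]], float)
        from dunnartdelim.distances import DistanceMatrix

        m = DistanceMatrix(("a", "b", "c"), vals, "euclidean")
        tree = mm.upgma_cluster(m)
        # a,b merge at height 1; c joins at mean(4, 4.5)/2 = 2.125
        from dunnartdelim.treebuild import patristic_distances

        p = patristic_distances(tree)
        assert p.get("a", "b") == pytest.approx(2.0)
        assert p.get("a", "c") == pytest.approx(4.25)
        assert p.get("b", "c") == pytest.approx(4.25)

    def test_ultrametric_input_recovered(self):
        from dunnartdelim.distances import DistanceMatrix
        from dunnartdelim.treebuild import patristic_distances

        vals = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0]], float
        )
        m = DistanceMatrix(("a", "b", "c", "d"), vals, "euclidean")
        p = patristic_distances(mm.upgma_cluster(m))
        np.testing.assert_allclose(p.submatrix(list(m.labels)).values, vals, atol=1e-9)

    def test_duplicates_merge_at_zero(self):
        t = make_table([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        tree = mm.upgma_cluster(mm.euclidean_matrix(t.data))
        from dunnartdelim.treebuild import patristic_distances

        assert patristic_distances(tree).get("i0", "i1") == 0.0


class TestKNN:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 0.2, (10, 3)) + 10
        b = rng.normal(0, 0.2, (10, 3)) + 20
        t = make_table(np.vstack([a, b]), groups=["A"] * 10 + ["B"] * 10)
        res = mm.knn_classify_loo(t.data, t.groups, k=1)
        assert res.overall_percent == 100.0
        assert (res.per_group.percent_correct == 100.0).all()

    def test_five_point_fixture_k1(self):
        # i4 (group B) is closest to the A cluster: 4/5 correct at k=1
        X = np.array([[1.0], [1.1], [1.25], [5.0], [1.45]])
        t = make_table(X, groups=["A", "A", "A", "B", "B"])
        res = mm.knn_classify_loo(t.data, t.groups, k=1, standardize=False)
        assert res.overall_percent == pytest.approx(80.0)

    def test_twin_property(self):
        rng = np.random.default_rng(15)
        X = rng.uniform(1, 2, (8, 2))
        t = make_table(
            np.vstack([X, X]),
            groups=(["A"] * 4 + ["B"] * 4) * 2,
            ids=[f"i{k}" for k in range(16)],
        )
        res = mm.knn_classify_loo(t.data, t.groups, k=1)
        assert res.overall_percent == 100.0

    def test_auto_k_reported_and_odd(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(2, 1, (12, 2))])
        t = make_table(X + 10, groups=["A"] * 12 + ["B"] * 12)
        res = mm.knn_classify_loo(t.data, t.groups, k="auto")
        assert res.k % 2 == 1 and 1 <= res.k <= 15

    def test_k_too_large(self):
        t = make_table(np.ones((3, 1)) * np.arange(1, 4)[:, None],
                       groups=["A", "A", "B"])
        with pytest.raises(ValueError):
            mm.knn_classify_loo(t.data, t.groups, k=3)


class TestDescriptives:
    def test_single_value_sd_flagged(self):
        t = make_table([[1.0], [2.0]], groups=["A", "B"])
        out = mm.descriptive_stats(t)
        assert out.loc[out.group == "A", "sd"].isna().all()
        assert out.loc[out.group == "A", "mean"].iloc[0] == 1.0

    def test_hand_computation(self):
        t = make_table([[1.0], [3.0], [5.0]], groups=["A", "A", "A"])
        row = mm.descriptive_stats(t).iloc[0]
        assert row["mean"] == 3.0 and row["sd"] == pytest.approx(2.0)
        assert row["min"] == 1.0 and row["max"] == 5.0 and row["n"] == 3


class TestPipelineProperties:
    def test_size_signal_vs_shape_signal(self):
        """Groups differing only by size: size ANOVA rejects while
        shape-space classification drops toward chance; the pipeline's
        size correction separates the two signals."""
        cfg = MorphoSimConfig(
            groups=[("g1", 20, 1.0), ("g2", 20, 1.2)],
            variable_base_means=[20, 10, 5, 8, 3],
            cv_noise=0.03,
            cv_size=0.03,
            seed=21,
        )
        table, _ = simulate_morphotable(cfg)
        ss = mm.size_and_shape(table)
        size_t = mm.MorphoTable(ss.gm.to_frame("gm"), table.groups)
        assert mm.univariate_tests(size_t)[0].pvalue < 1e-6
        res_shape = mm.knn_classify_loo(ss.shape, table.groups, k=5)
        assert res_shape.overall_percent < 75.0  # near-chance, size removed
        res_raw = mm.knn_classify_loo(table.data, table.groups, k=5)
        assert res_raw.overall_percent > 90.0

    def test_driver_enforces_order_and_runs(self, fixture_paths):
        table = mm.MorphoTable.read_csv(fixture_paths["morpho"])
        res = mm.morpho_pipeline(table, seed=3)
        assert res.imputed.is_complete()
        # clones injected by the generator must fall to the pruning step
        pruned_names = {e["name"] for e in res.prune_log} | set(res.pruned.data.columns)
        assert any("clone" in e["name"] for e in res.prune_log) or not any(
            "clone" in c for c in res.pruned.data.columns
        )
        assert res.pca_raw.variance_fractions[0] > 0.3  # size dominates PC1
        assert res.size_tests.pvalue < 0.01  # small group differs in size
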