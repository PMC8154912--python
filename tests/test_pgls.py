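import dendropy
import numpy as np
import pandas as pd
import pytest

from codefidelity.pgls import (
    PREDICTORS,
    RESPONSES,
    ComparativeDataset,
    PGLSRegression,
    brownian_covariance,
    model_summary_table,
    pgls_fit,
    results_long_table,
    run_full_analysis,
    standardized_fit,
)
from codefidelity.synthetic import simulate_tree


def tree_from_newick(s: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=s, schema="newick")
    t.is_rooted = True
    return t


def star_tree(n: int, bl: float = 1.0) -> dendropy.Tree:
    s = "(" + ",".join(f"t{i}:{bl}" for i in range(n)) + ");"
    return tree_from_newick(s)


def random_dataset(n: int, seed: int) -> tuple[ComparativeDataset, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n, 1.0, seed=seed)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    df = pd.DataFrame(
        rng.normal(size=(n, 8)),
        index=pd.Index(taxa, name="taxon_id"),
        columns=[*RESPONSES, *PREDICTORS],
    )
    return ComparativeDataset(tree=tree, traits=df.reset_index()), df


class TestBrownianCovariance:
    def test_star_tree_is_scaled_identity(self):
        V, labels = brownian_covariance(star_tree(4, bl=2.5))
        np.testing.assert_allclose(V, 2.5 * np.eye(4), atol=1e-15)
        assert labels == ["t0", "t1", "t2", "t3"]

    def test_cherry_shares_divergence_depth(self):
        tree = tree_from_newick("((A:2,B:2):3,C:5);")
        V, labels = brownian_covariance(tree, ["A", "B", "C"])
        assert V[0, 1] == pytest.approx(3.0)   # depth of the (A,B) ancestor
        assert V[0, 0] == pytest.approx(5.0)
        assert V[2, 2] == pytest.approx(5.0)
        assert V[0, 2] == 0.0

    def test_ultrametric_tree_has_constant_diagonal(self):
        tree = simulate_tree(16, 1.0, seed=3)
        V, _ = brownian_covariance(tree)
        np.testing.assert_allclose(np.diag(V), V[0, 0], rtol=1e-12)

    def test_polytomy_accepted(self):
        tree = tree_from_newick("((A:1,B:1,C:1):1,D:2);")
        V, _ = brownian_covariance(tree, ["A", "B", "C", "D"])
        assert V[0, 1] == V[0, 2] == V[1, 2] == pytest.approx(1.0)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            brownian_covariance(tree_from_newick("((A:1,B:-1):1,C:2);"))

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            brownian_covariance(tree_from_newick("(A:1,B:1);"))

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(3):
            V, _ = brownian_covariance(simulate_tree(32, 1.0, seed=seed))
            eig = np.linalg.eigvalsh(V)
            assert eig.min() > -1e-10


class TestPGLSRegression:
    def test_star_phylogeny_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n, p = 40, 3
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        V = 1.7 * np.eye(n)
        gls = PGLSRegression().fit(X, y, V=V)
        ols = PGLSRegression().fit(X, y, V=None)
        np.testing.assert_allclose(gls.params_, ols.params_, atol=1e-10)
        np.testing.assert_allclose(gls.bse_, ols.bse_, atol=1e-10)
        np.testing.assert_allclose(gls.tvalues_, ols.tvalues_, atol=1e-10)
        assert gls.rsquared_ == pytest.approx(ols.rsquared_, abs=1e-10)
        assert gls.fvalue_ == pytest.approx(ols.fvalue_, abs=1e-8)

    def test_matches_cholesky_whitened_ols_on_random_trees(self):
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(64, 1.0, seed=seed)
            V, _ = brownian_covariance(tree)
            X = rng.normal(size=(64, 4))
            y = rng.normal(size=64)
            est = PGLSRegression().fit(X, y, V=V)
            L = np.linalg.cholesky(V)
            Xd = np.column_stack([np.ones(64), X])
            Xw = np.linalg.solve(L, Xd)
            yw = np.linalg.solve(L, y)
            beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            np.testing.assert_allclose(est.params_, beta, atol=1e-10)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        tree = simulate_tree(32, 1.0, seed=5)
        V, _ = brownian_covariance(tree)
        X = rng.normal(size=(32, 4))
        y = rng.normal(size=32)
        est = PGLSRegression().fit(X, y, V=V)
        ref = sm.GLS(y, sm.add_constant(X), sigma=V).fit()
        np.testing.assert_allclose(est.params_, ref.params, atol=1e-10)
        np.testing.assert_allclose(est.bse_, ref.bse, atol=1e-10)
        np.testing.assert_allclose(est.tvalues_, ref.tvalues, atol=1e-8)
        np.testing.assert_allclose(est.pvalues_, ref.pvalues, atol=1e-10)

    def test_perfect_fit_gives_r2_one(self):
        rng = np.random.default_rng(7)
        tree = simulate_tree(16, 1.0, seed=7)
        V, _ = brownian_covariance(tree)
        X = rng.normal(size=(16, 2))
        y = 1.0 + X @ np.array([2.0, -3.0])
        est = PGLSRegression().fit(X, y, V=V)
        assert est.rsquared_ == pytest.approx(1.0, abs=1e-10)
        assert est.ssr_ == pytest.approx(0.0, abs=1e-18)

    def test_branch_length_scale_invariance(self):
        rng = np.random.default_rng(11)
        tree = simulate_tree(24, 1.0, seed=11)
        V, _ = brownian_covariance(tree)
        X = rng.normal(size=(24, 3))
        y = rng.normal(size=24)
        a = PGLSRegression().fit(X, y, V=V)
        b = PGLSRegression().fit(X, y, V=37.0 * V)
        np.testing.assert_allclose(a.params_, b.params_, atol=1e-10)
        np.testing.assert_allclose(a.tvalues_, b.tvalues_, atol=1e-8)
        assert a.rsquared_ == pytest.approx(b.rsquared_, abs=1e-12)
        assert a.fvalue_ == pytest.approx(b.fvalue_, rel=1e-10)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(np.linalg.LinAlgError):
            PGLSRegression().fit(X, rng.normal(size=20))

    def test_jitter_handles_duplicate_tips(self):
        # zero-length cherry -> duplicated rows in V; one jitter round fixes it
        tree = tree_from_newick("((A:0,B:0):2,(C:1,D:1):1);")
        V, _ = brownian_covariance(tree, ["A", "B", "C", "D"])
        assert np.linalg.matrix_rank(V) < 4
        rng = np.random.default_rng(0)
        est = PGLSRegression().fit(rng.normal(size=(4, 1)), rng.normal(size=4), V=V)
        assert np.isfinite(est.params_).all()

    def test_predict_is_linear(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        est = PGLSRegression().fit(X, y)
        np.testing.assert_allclose(est.predict(X), est.intercept_ + X @ est.coef_)


class TestComparativeAnalysis:
    def test_dataset_requires_bijection(self):
        tree = simulate_tree(8, 1.0, seed=0)
        taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        df = pd.DataFrame(np.ones((7, 8)), index=taxa[:7],
                          columns=[*RESPONSES, *PREDICTORS])
        df.index.name = "taxon_id"
        with pytest.raises(ValueError, match="bijection"):
            ComparativeDataset(tree=tree, traits=df.reset_index())

    def test_full_analysis_shapes(self):
        ds, _ = random_dataset(64, seed=21)
        results = run_full_analysis(ds)
        assert set(results) == set(RESPONSES)
        for r in results.values():
            assert r.df1 == 4
            assert r.df2 == 64 - 5
            assert 0.0 <= r.rsquared <= 1.0
            assert r.terms == ("intercept", *PREDICTORS)

    def test_results_independent_of_response_ordering(self):
        ds, _ = random_dataset(16, seed=2)
        a = run_full_analysis(ds, responses=RESPONSES)
        b = run_full_analysis(ds, responses=tuple(reversed(RESPONSES)))
        for r in RESPONSES:
            np.testing.assert_allclose(a[r].params, b[r].params, atol=1e-14)

    def test_standardized_betas_affine_invariant_and_sign_matching(self):
        ds, df = random_dataset(32, seed=4)
        std = standardized_fit(ds, "D_hyd")
        # rescale temperature to tenths of a degree: betas unchanged
        df2 = df.copy()
        df2["temperature"] = df2["temperature"] * 10 + 3
        ds2 = ComparativeDataset(tree=ds.tree, traits=df2.reset_index())
        std2 = standardized_fit(ds2, "D_hyd")
        for k in std:
            assert std[k] == pytest.approx(std2[k], rel=1e-8)
        raw = pgls_fit(ds, "D_hyd")
        for k in std:
            assert np.sign(std[k]) == np.sign(raw.coef(k))

    def test_standardized_fit_rejects_zero_variance(self):
        ds, df = random_dataset(16, seed=6)
        df["ph"] = 7.0
        ds2 = ComparativeDataset(tree=ds.tree, traits=df.reset_index())
        with pytest.raises(ValueError, match="zero-variance"):
            standardized_fit(ds2, "D_hyd")

    def test_output_tables(self):
        ds, _ = random_dataset(16, seed=9)
        results = run_full_analysis(ds)
        long = results_long_table(results)
        assert len(long) == 4 * 5  # 4 responses x (intercept + 4 predictors)
        summary = model_summary_table(results)
        assert list(summary["response"]) == list(RESPONSES)
        assert (summary["df1"] == 4).all() and (summary["n"] == 16).all()
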