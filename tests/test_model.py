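"""Penalized drug-response models and the tissue-weighted evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmark import model
from panmark.dataio import ConfigError


def _xy(n=50, p=10, seed=0, beta=None, noise=0.3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=pd.Index([f"c{i}" for i in range(n)]),
        columns=[f"g{j}" for j in range(p)],
    )
    if beta is None:
        beta = np.zeros(p)
        beta[0] = 1.0
    y = pd.Series(X.to_numpy() @ beta + rng.normal(scale=noise, size=n), index=X.index)
    return X, y


class TestWeightedPearson:
    def test_single_tissue_identity(self):
        assert model.weighted_pearson([("t", 10, 0.5)]) == pytest.approx(0.5, abs=1e-12)

    def test_equal_correlations_pass_through(self):
        pairs = [("a", 5, 0.3), ("b", 9, 0.3), ("c", 20, 0.3)]
        assert model.weighted_pearson(pairs) == pytest.approx(0.3, abs=1e-12)

    def test_two_tissue_hand_value(self):
        # tanh((2*0 + 4*arctanh(0.8)) / 6)
        expected = np.tanh(4 * np.arctanh(0.8) / 6)
        assert model.weighted_pearson([("a", 3, 0.0), ("b", 5, 0.8)]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.62454, abs=5e-5)

    def test_small_tissues_excluded(self):
        assert np.isnan(model.weighted_pearson([("a", 2, 0.9)]))
        assert model.weighted_pearson([("a", 2, 0.9), ("b", 4, 0.1)]) == pytest.approx(0.1)

    def test_extreme_correlations_clamped(self):
        out = model.weighted_pearson([("a", 5, 1.0), ("b", 5, 1.0)])
        assert 0.999 < out <= 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_monotone_in_each_correlation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        ns = rng.integers(3, 30, size=k)
        ps = rng.uniform(-0.95, 0.95, size=k)
        base = model.weighted_pearson(list(zip(range(k), ns, ps)))
        j = int(rng.integers(0, k))
        bumped = ps.copy()
        bumped[j] = min(0.99, bumped[j] + 0.1)
        after = model.weighted_pearson(list(zip(range(k), ns, bumped)))
        assert after >= base - 1e-12
        assert -1 <= base <= 1


class TestFitDrugModelRun:
    def test_vanishing_penalty_matches_ols(self):
        X, y = _xy(n=50, p=10, seed=1)
        spec = model.ModelSpec(folds=5, repeats=1, penalty_grid=[1e-10], seed=0)
        res = model.fit_drug_model_run(X, y, spec, run_seed=0)
        xs, _, _ = model._standardize(X.to_numpy(), True)
        beta, *_ = np.linalg.lstsq(xs, y.to_numpy() - y.mean(), rcond=None)
        assert np.abs(res.coef.to_numpy() - beta).max() < 1e-6

    def test_constant_response_degenerates(self):
        X, y = _xy(n=20, p=5, seed=2)
        y[:] = 0.7
        res = model.fit_drug_model_run(X, y, model.ModelSpec(folds=5, repeats=1), 0)
        assert res.degenerate
        assert (res.coef == 0).all()
        assert np.allclose(res.oof, 0.7)

    def test_too_few_samples_errors(self):
        X, y = _xy(n=4, p=3)
        with pytest.raises(model.ModelError):
            model.fit_drug_model_run(X, y, model.ModelSpec(folds=5, repeats=1), 0)

    def test_run_seed_determinism(self):
        X, y = _xy(n=40, p=30, seed=3)
        spec = model.ModelSpec(folds=5, repeats=1, seed=0)
        r1 = model.fit_drug_model_run(X, y, spec, 123)
        r2 = model.fit_drug_model_run(X, y, spec, 123)
        pd.testing.assert_series_equal(r1.coef, r2.coef)
        pd.testing.assert_series_equal(r1.oof, r2.oof)

    def test_planted_predictor_gets_largest_coefficient(self):
        beta = np.zeros(40)
        beta[7] = 2.0
        X, y = _xy(n=80, p=40, seed=4, beta=beta, noise=0.5)
        spec = model.ModelSpec(folds=5, repeats=1, seed=0)
        res = model.fit_drug_model_run(X, y, spec, 0)
        assert res.coef.abs().idxmax() == "g7"
        # univariate correlation screen agrees on the top gene
        corr = X.apply(lambda c: abs(np.corrcoef(c, y)[0, 1]))
        assert corr.idxmax() == "g7"

    def test_ridge_path_matches_sklearn(self):
        from sklearn.linear_model import Ridge

        X, y = _xy(n=30, p=50, seed=5)
        xs, _, _ = model._standardize(X.to_numpy(), True)
        yc = y.to_numpy() - y.mean()
        for lam in (0.5, 10.0, 300.0):
            ours = model.ridge_path(xs, yc, np.array([lam]))[:, 0]
            ref = Ridge(alpha=lam, fit_intercept=False).fit(xs, yc).coef_
            assert np.abs(ours - ref).max() < 1e-8

    def test_lasso_mode_selects_sparse_model(self):
        beta = np.zeros(30)
        beta[3] = 1.5
        X, y = _xy(n=60, p=30, seed=6, beta=beta, noise=0.2)
        spec = model.ModelSpec(
            alpha=1.0, folds=5, repeats=1, penalty_grid=np.logspace(-3, 0, 7), seed=0
        )
        res = model.fit_drug_model_run(X, y, spec, 0)
        assert res.coef.abs().idxmax() == "g3"
        assert (res.coef == 0).sum() > 10


class TestPerformance:
    def test_perfect_and_reversed_predictions(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"c{i}" for i in range(30)])
        y = pd.Series(rng.normal(size=30), index=idx)
        tissues = pd.Series(np.repeat(["A", "B", "C"], 10), index=idx)
        p, pw = model.run_performance(y, y.copy(), tissues)
        assert p == pytest.approx(1.0)
        assert pw == pytest.approx(1.0, abs=1e-9)
        p_neg, _ = model.run_performance(y, -y, tissues)
        assert p_neg == pytest.approx(-1.0)

    def test_two_tissue_toy_matches_manual_formula(self):
        idx = pd.Index([f"c{i}" for i in range(11)])
        y = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.9, 0.8, 0.7, 0.6, 0.5], index=idx)
        yhat = pd.Series([0.2, 0.1, 0.35, 0.5, 0.4, 0.65, 0.5, 0.6, 0.8, 0.65, 0.7], index=idx)
        tissues = pd.Series(["A"] * 6 + ["B"] * 5, index=idx)
        r_a = np.corrcoef(y[:6], yhat[:6])[0, 1]
        r_b = np.corrcoef(y[6:], yhat[6:])[0, 1]
        manual = np.tanh((5 * np.arctanh(r_a) + 4 * np.arctanh(r_b)) / 9)
        _, pw = model.run_performance(y, yhat, tissues)
        assert pw == pytest.approx(manual, abs=1e-12)

    def test_undefined_tissues_are_excluded(self):
        idx = pd.Index([f"c{i}" for i in range(8)])
        y = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.5, 0.5, 0.5], index=idx)
        yhat = pd.Series([0.15, 0.25, 0.28, 0.41, 0.1, 0.2, 0.3, 0.4], index=idx)
        tissues = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
        pt = model.per_tissue_correlations(y, yhat, tissues)
        assert list(pt["tissue"]) == ["A"]  # tissue B has constant observations


class TestRepeatedModels:
    def test_equal_seeds_give_identical_runs(self, small_dataset):
        ds = small_dataset
        spec = model.ModelSpec(folds=3, repeats=1, penalty_grid=[1.0, 10.0], seed=5)
        drug = sorted(ds.response["drug_id"].unique())[0]
        y = ds.drug_response(drug)
        X = ds.expression.loc[y.index]
        r = model.run_drug_model(X, y, ds.tissue_map(), spec, [11, 11], drug, "raw")
        pd.testing.assert_series_equal(r.coef.iloc[0], r.coef.iloc[1], check_names=False)
        assert r.performance["pearson"].iloc[0] == r.performance["pearson"].iloc[1]

    def test_summary_covers_all_drugs(self, small_dataset):
        spec = model.ModelSpec(folds=3, repeats=2, penalty_grid=[1.0, 100.0], seed=5)
        res = model.run_repeated_models(small_dataset, "zscore", spec)
        perf = model.summarize_performance(res)
        assert set(perf["drug_id"]) == set(small_dataset.response["drug_id"])
        assert perf["weighted_pearson"].between(-1, 1).all()
        assert (perf["n_tissues"] >= 1).all()

    def test_tissue_labels_modality_is_one_hot(self, small_dataset):
        mat = model.prepare_modality(small_dataset, "tissue_labels")
        assert mat.shape[1] == small_dataset.samples["cancer_type"].nunique()
        assert set(np.unique(mat.to_numpy())) == {0.0, 1.0}

    def test_unknown_modality_rejected(self, small_dataset):
        with pytest.raises(ConfigError):
            model.prepare_modality(small_dataset, "pca")
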