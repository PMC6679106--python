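import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmaftir.chemometrics import (
    ConfusionCounts,
    CVResult,
    PLSDA,
    covariance_ellipse,
    cross_validate,
    pca_fit,
    plsda_fit,
    plsda_predict,
    select_optimal_lv,
    sensitivity_specificity,
)
from plasmaftir.cohort import generate_cohort
from plasmaftir.preprocess import preprocess_dataset

from conftest import two_group_config


def pca_eigh_oracle(X):
    """Explained variances via direct covariance eigendecomposition."""
    Xc = X - X.mean(axis=0)
    evals = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
    return 100.0 * evals / evals.sum()


class TestPCA:
    def test_collinear_units_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 12)
        X = np.outer(t, np.array([1.0, -2.0, 0.5, 3.0]))
        res = pca_fit(X, n_components=3)
        assert res.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 12)) @ rng.normal(size=(12, 12))
        res = pca_fit(X, n_components=11)
        oracle = pca_eigh_oracle(X)[:11]
        assert np.allclose(res.explained_variance_pct, oracle, atol=1e-8)
        assert np.all(np.diff(res.explained_variance_pct) <= 1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        res = pca_fit(rng.normal(size=(20, 15)), n_components=8)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(8), atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        res = pca_fit(X, n_components=6)
        recon = res.scores @ res.loadings
        assert np.allclose(recon, X - X.mean(axis=0), atol=1e-10)

    def test_component_bound_enforced(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_fit(np.random.default_rng(3).normal(size=(5, 10)), n_components=5)

    def test_dataset_units_are_patient_means(self, small_cohort):
        mv, _, _ = preprocess_dataset(small_cohort)
        res = pca_fit(mv, n_components=5)
        n_patients = mv.metadata["patient_id"].nunique()
        assert res.scores.shape == (n_patients, 5)


class TestCovarianceEllipse:
    def test_identity_covariance_radius(self):
        # large sample with identity covariance: both semi-axes near
        # sqrt(chi2_{2,0.95}) = 2.4477
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((200_000, 2))
        ell = covariance_ellipse(pts, 0.95)
        assert np.allclose(ell.axes, 2.4477, atol=0.02)

    def test_exact_radius_from_constructed_covariance(self):
        # three points with sample covariance diag(1, 0): major axis
        # sqrt(5.991), minor axis exactly 0
        pts = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        ell = covariance_ellipse(pts)
        assert ell.axes[0] == pytest.approx(np.sqrt(stats.chi2.ppf(0.95, 2) * 1.0))
        assert ell.axes[1] == 0.0

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(5)
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.6], [0.6, 1.0]], size=100_000)
        ell = covariance_ellipse(pts, 0.95)
        assert ell.contains(pts).mean() == pytest.approx(0.95, abs=0.01)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            covariance_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestConfusion:
    def test_sensitivity_specificity_closed_form(self):
        assert sensitivity_specificity(ConfusionCounts(9, 1, 8, 2)) == (90.0, 80.0)
        assert sensitivity_specificity(ConfusionCounts(5, 0, 7, 0)) == (100.0, 100.0)
        assert sensitivity_specificity(ConfusionCounts(0, 3, 2, 1))[0] == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_specificity(ConfusionCounts(0, 0, 5, 5))
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_from_labels(self):
        y = np.array([1, 1, 0, 0, 1], dtype=bool)
        yhat = np.array([1, 0, 0, 1, 1], dtype=bool)
        c = ConfusionCounts.from_labels(y, yhat)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 1, 1)


class TestPLSDA:
    def test_one_lv_univariate_matches_ols(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = (x > 0).astype(float)
        X = np.column_stack([x])
        fit = plsda_fit(X, y, n_lv=1)
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        ols_pred = beta * xc + y.mean()
        scores, _ = plsda_predict(fit, X)
        assert np.allclose(scores, ols_pred, atol=1e-8)

    def test_full_rank_matches_minimum_norm_least_squares(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 25))
            p = int(rng.integers(3, 9))
            X = rng.normal(size=(n, p))
            y = rng.integers(0, 2, size=n).astype(float)
            if y.all() or not y.any():
                y[0] = 1 - y[0]
            rank = np.linalg.matrix_rank(X - X.mean(axis=0))
            fit = plsda_fit(X, y, n_lv=rank)
            Xc = X - X.mean(axis=0)
            ls = Xc @ (np.linalg.pinv(Xc) @ (y - y.mean())) + y.mean()
            scores, _ = fit.predict(X)
            assert np.allclose(scores, ls, atol=1e-6 * max(1, np.abs(ls).max()))

    def test_label_swap_affine_equivariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        y = rng.integers(0, 2, size=30).astype(float)
        y[:2] = [0, 1]
        s1, _ = plsda_fit(X, y, 3).predict(X)
        s2, _ = plsda_fit(X, 1 - y, 3).predict(X)
        assert np.allclose(s2, 1 - s1, atol=1e-8)

    def test_training_mean_predicts_class_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 6))
        y = np.array([0, 1] * 10, dtype=float)
        fit = plsda_fit(X, y, 2)
        score, _ = fit.predict(X.mean(axis=0))
        assert score[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_separable_training_data_reproduced(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 5))
        X[:15, 0] += 10.0
        y = np.array([0.0] * 15 + [1.0] * 15)
        fit = plsda_fit(X, 1 - y, 2)  # positive class is the shifted half
        _, labels = fit.predict(X)
        assert np.array_equal(labels, (1 - y).astype(bool))

    def test_threshold_labels(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 4))
        y = np.array([0, 1] * 5, dtype=float)
        fit = plsda_fit(X, y, 1)
        fake_scores = np.array([0.2, 0.7])
        assert np.array_equal(fake_scores >= fit.decision_threshold, [False, True])

    def test_single_class_rejected(self):
        X = np.random.default_rng(12).normal(size=(8, 4))
        with pytest.raises(ValueError):
            PLSDA(X, np.zeros(8))

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        fit = plsda_fit(rng.normal(size=(12, 6)), np.array([0, 1] * 6, float), 2)
        with pytest.raises(ValueError, match="grid mismatch"):
            fit.predict(rng.normal(size=(3, 5)))

    def test_nested_coefficients_match_smaller_fits(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 12))
        y = rng.integers(0, 2, size=25).astype(float)
        y[:2] = [0, 1]
        big = plsda_fit(X, y, 6)
        for k in (1, 3, 5):
            small = plsda_fit(X, y, k)
            coef, intercept = big.coefficients_for(k)
            assert np.allclose(coef, small.regression_coefficients, atol=1e-10)
            assert intercept == pytest.approx(small.intercept, abs=1e-10)


@pytest.fixture(scope="module")
def separable_cv():
    cfg = two_group_config(
        n_a=8, n_b=8, replicates=4,
        effect={"amide I": 0.85, "CH2 asym lipids 2930": 1.3}, seed=21,
    )
    mv, _, _ = preprocess_dataset(generate_cohort(cfg))
    return cross_validate(mv, "g0", "g1", m_max=6, rounds=8, seed=5)


class TestCrossValidate:
    def test_table_shape_and_metadata(self, separable_cv):
        r = separable_cv
        assert list(r.table["lv"]) == list(range(1, 7))
        assert r.rounds == 8
        assert r.train_fraction == 0.9
        assert set(r.table.columns) >= {
            "lv", "sensitivity_mean", "sensitivity_sd",
            "specificity_mean", "specificity_sd",
        }
        assert ((r.table["sensitivity_mean"] >= 0) & (r.table["sensitivity_mean"] <= 100)).all()

    def test_patient_disjoint_stratified_splits(self, separable_cv):
        r = separable_cv
        assert len(r.splits) == r.rounds
        for split in r.splits:
            val, train = set(split["validation"]), set(split["train"])
            assert not val & train
            assert len(val) + len(train) == 16
            # stratified: one held-out patient per group (10% of 8 -> 1)
            for g in ("g0", "g1"):
                assert sum(p.startswith(g) for p in split["validation"]) == 1

    def test_strong_effect_is_recovered(self, separable_cv):
        best = separable_cv.table["balanced_accuracy"].max()
        assert best >= 90.0

    def test_deterministic_given_seed(self, separable_cv):
        cfg = two_group_config(
            n_a=8, n_b=8, replicates=4,
            effect={"amide I": 0.85, "CH2 asym lipids 2930": 1.3}, seed=21,
        )
        mv, _, _ = preprocess_dataset(generate_cohort(cfg))
        again = cross_validate(mv, "g0", "g1", m_max=6, rounds=8, seed=5)
        pd.testing.assert_frame_equal(again.table, separable_cv.table)

    def test_lv_bound_enforced(self, small_cohort):
        mv, _, _ = preprocess_dataset(small_cohort)
        with pytest.raises(ValueError, match="m_max"):
            cross_validate(mv, "g0", "g1", m_max=5000, rounds=2, seed=0)

    def test_single_patient_group_rejected(self, small_cohort):
        mv, _, _ = preprocess_dataset(small_cohort)
        keep = mv.metadata["patient_id"].isin(
            ["g0_P000", "g1_P000", "g1_P001"]
        ).to_numpy()
        with pytest.raises(ValueError, match="two patients"):
            cross_validate(mv.select(keep), "g0", "g1", m_max=2, rounds=2, seed=0)


class TestSelectOptimalLV:
    def _result(self, sens, spec):
        m = len(sens)
        table = pd.DataFrame({
            "lv": np.arange(1, m + 1),
            "sensitivity_mean": np.asarray(sens, float),
            "sensitivity_sd": np.zeros(m),
            "specificity_mean": np.asarray(spec, float),
            "specificity_sd": np.zeros(m),
        })
        table["balanced_accuracy"] = (table["sensitivity_mean"]
                                      + table["specificity_mean"]) / 2
        return CVResult(table, rounds=1, train_fraction=0.9, seed=0,
                        group_a="a", group_b="b")

    def test_peak_then_decline(self):
        sens = list(range(50, 61)) + [55, 52]  # peak at the 11th entry
        r = self._result(sens, sens)
        assert select_optimal_lv(r) == 11

    def test_all_equal_returns_one(self):
        r = self._result([70] * 8, [70] * 8)
        assert select_optimal_lv(r) == 1

    def test_tie_broken_to_smaller(self):
        sens = [50, 50, 50, 50, 50, 50, 50, 50, 50, 90, 50, 50, 90, 50]
        r = self._result(sens, sens)
        assert select_optimal_lv(r) == 10
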