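"""Fit, external-validation and cross-validation statistics."""

import numpy as np
import pandas as pd
import pytest

from pacqsar import QsarDataset, external_stats, fit_mlr, fit_stats, loo_cv
from pacqsar.modelbuild import design_matrix
from pacqsar.synthetic import SyntheticSpec, generate_regression


def textbook_external(y_train, o, p):
    """Independent reimplementation of the four external metrics."""
    e2 = np.sum((o - p) ** 2)
    q2f1 = 1 - e2 / np.sum((o - np.mean(y_train)) ** 2)
    q2f2 = 1 - e2 / np.sum((o - np.mean(o)) ** 2)
    q2f3 = 1 - (e2 / len(o)) / (np.sum((y_train - np.mean(y_train)) ** 2) / len(y_train))
    so2 = np.var(o)
    sp2 = np.var(p)
    sop = np.mean((o - o.mean()) * (p - p.mean()))
    ccc = 2 * sop / (so2 + sp2 + (o.mean() - p.mean()) ** 2)
    return q2f1, q2f2, q2f3, ccc


class TestFitStats:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = fit_stats(y, y)
        assert rep.r2 == rep.q2 == 1.0
        assert rep.rmse == rep.bias == rep.mae == rep.mpe == rep.mne == 0.0

    def test_symmetric_unit_residuals(self):
        rep = fit_stats(np.array([1.0, -1.0]), np.array([0.0, 0.0]))
        assert rep.rmse == 1.0 and rep.bias == 0.0 and rep.mae == 1.0
        assert rep.mpe == 1.0 and rep.mne == -1.0

    def test_mae_le_rmse_and_mpe_mne_signs(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=50)
        pred = y + rng.normal(0, 0.5, 50)
        rep = fit_stats(y, pred)
        assert rep.mae <= rep.rmse + 1e-12
        assert rep.mpe >= 0.0 >= rep.mne

    def test_ols_in_sample_r2_equals_q2(self):
        data = generate_regression(SyntheticSpec(60, 4, (1, -1, 2, -2),
                                                 noise_sd=0.5, seed=11))
        m = fit_mlr(data)
        pred = design_matrix(data.X) @ np.concatenate(
            [[m.intercept], [c for _, c in m.terms]]
        )
        rep = fit_stats(data.y, pred)
        assert rep.r2 == pytest.approx(rep.q2, abs=1e-10)

    def test_zero_variance_observed_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fit_stats(np.ones(5), np.arange(5.0))


class TestExternalStats:
    def test_perfect_test_predictions(self):
        y_train = np.array([0.0, 1.0, 2.0])
        o = np.array([0.5, 1.5, 2.5])
        s = external_stats(y_train, o, o)
        assert s.q2_f1 == s.q2_f2 == s.q2_f3 == 1.0
        assert s.ccc == pytest.approx(1.0)

    def test_null_model_reference_gives_zero_q2f1(self):
        y_train = np.array([1.0, 3.0])  # mean 2
        o = np.array([1.0, 3.0])        # centred on the training mean
        pred = np.full(2, 2.0)
        s = external_stats(y_train, o, pred)
        assert s.q2_f1 == pytest.approx(0.0)

    def test_ccc_hand_value(self):
        s = external_stats(np.array([0.0, 1.0]), np.array([1.0, 2.0, 3.0]),
                           np.array([2.0, 3.0, 4.0]))
        assert s.ccc == pytest.approx(4 / 7)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        y_train = rng.normal(1.0, 2.0, 20)
        o = rng.normal(0.5, 1.5, 8)
        p = o + rng.normal(0, 0.7, 8)
        s = external_stats(y_train, o, p)
        ref = textbook_external(y_train, o, p)
        np.testing.assert_allclose(
            [s.q2_f1, s.q2_f2, s.q2_f3, s.ccc], ref, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_ccc_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(100 + seed)
        o = rng.normal(size=15)
        p = 0.8 * o + rng.normal(0, 0.5, 15) + 0.3
        s = external_stats(rng.normal(size=10), o, p)
        r = np.corrcoef(o, p)[0, 1]
        assert s.ccc <= abs(r) + 1e-12

    def test_ccc_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(4)
        o = rng.normal(size=200)
        p = rng.normal(size=200)
        # force identical mean and variance
        p = (p - p.mean()) / p.std() * o.std() + o.mean()
        s = external_stats(rng.normal(size=10), o, p)
        assert s.ccc == pytest.approx(np.corrcoef(o, p)[0, 1], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_q2f2_below_q2f1_when_means_differ(self, seed):
        rng = np.random.default_rng(200 + seed)
        y_train = rng.normal(2.0, 1.0, 20)
        o = rng.normal(0.0, 1.0, 10)  # test mean differs from train mean
        p = o + rng.normal(0, 0.4, 10)
        s = external_stats(y_train, o, p)
        assert s.q2_f2 <= s.q2_f1 + 1e-12


class TestLooCv:
    def test_noise_free_data(self):
        data = generate_regression(SyntheticSpec(25, 3, (1.0, 2.0, -1.0), seed=2))
        q2cv, rmsecv, preds = loo_cv(data)
        assert q2cv == pytest.approx(1.0, abs=1e-10)
        assert rmsecv == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(preds, data.y, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_shortcut_equals_explicit_refits(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 3
        data = QsarDataset(
            tuple(map(str, range(n))),
            pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"D{j}" for j in range(p)]),
            rng.standard_normal(n),
        )
        q2cv, rmsecv, preds = loo_cv(data)
        # explicit n-refit oracle
        press = 0.0
        explicit = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            Xd = design_matrix(data.X.iloc[mask])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ data.y[mask])
            xi = np.concatenate([[1.0], data.X.iloc[i].to_numpy()])
            explicit[i] = xi @ beta
            press += (data.y[i] - explicit[i]) ** 2
        sst = np.sum((data.y - data.y.mean()) ** 2)
        assert q2cv == pytest.approx(1 - press / sst, abs=1e-10)
        assert rmsecv == pytest.approx(np.sqrt(press / n), abs=1e-10)
        np.testing.assert_allclose(preds, explicit, atol=1e-10)

    def test_high_leverage_point_inflates_loo_residual(self):
        rng = np.random.default_rng(6)
        n = 15
        X = pd.DataFrame({"D0": np.append(rng.normal(size=n - 1), 8.0)})
        y = 2.0 * X["D0"].to_numpy() + rng.normal(0, 0.3, n)
        data = QsarDataset(tuple(map(str, range(n))), X, y)
        _, _, loo_preds = loo_cv(data)
        Xd = design_matrix(data.X)
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ data.y)
        in_sample = np.abs(data.y - Xd @ beta)
        loo_resid = np.abs(data.y - loo_preds)
        assert loo_resid[-1] > in_sample[-1]

    def test_descriptor_subset_selection(self):
        data = generate_regression(SyntheticSpec(30, 5, (1, 0, 2, 0, 0),
                                                 noise_sd=0.1, seed=7))
        q2_sub, _, _ = loo_cv(data, descriptors=list(data.X.columns[:3]))
        assert 0 < q2_sub <= 1
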