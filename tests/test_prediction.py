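"""CPM: edge selection, summary-sum models, cross-validation, transfer,
Steiger's z, FDR and bootstrap CIs."""

import numpy as np
import pytest
from scipy import stats

from gfconn.prediction import (
    CPMRegressor,
    bootstrap_ci,
    fdr_bh,
    fit_cpm,
    loocv_cpm,
    select_edges,
    steiger_z,
    transfer_cpm,
)


def _signal_data(n=200, e=300, k=3, r2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, e))
    w = np.zeros(e)
    w[:k] = [1.0, -1.0, 0.5][:k]
    lp = x @ w
    noise = rng.standard_normal(n) * np.sqrt(lp.var() * (1 - r2) / r2)
    return x, lp + noise, w


class TestSelectEdges:
    def test_noiseless_copy_selected_positive(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 10))
        y = x[:, 3].copy()
        pos, neg = select_edges(x, y)
        assert pos[3]
        assert not neg[3]

    def test_null_selection_rate_matches_threshold(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 10_000))
        y = rng.standard_normal(300)
        pos, neg = select_edges(x, y, p_thresh=0.01)
        frac = (pos.sum() + neg.sum()) / 10_000
        assert frac == pytest.approx(0.01, abs=0.003)

    def test_zero_threshold_empty_masks(self):
        rng = np.random.default_rng(3)
        pos, neg = select_edges(rng.standard_normal((30, 5)),
                                rng.standard_normal(30), p_thresh=0.0)
        assert not pos.any() and not neg.any()

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            select_edges(np.random.default_rng(0).standard_normal((20, 4)),
                         np.ones(20))


class TestCPMRegressor:
    def test_noiseless_signal_fit_exact(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 20))
        y = 2.0 * x[:, 5]
        model = fit_cpm(x, y)
        assert np.linalg.norm(model.predict(x) - y) < 1e-8

    def test_coefficients_match_normal_equations(self):
        x, y, _ = _signal_data(seed=5)
        model = fit_cpm(x, y)
        sums = np.column_stack([x[:, model.pos_mask_].sum(axis=1),
                                x[:, model.neg_mask_].sum(axis=1)])
        design = np.column_stack([np.ones(len(y)), sums])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept_ == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-10)

    def test_constant_shift_moves_only_intercept(self):
        x, y, _ = _signal_data(seed=6)
        m1 = fit_cpm(x, y)
        m2 = fit_cpm(x, y + 10.0)
        assert m2.intercept_ == pytest.approx(m1.intercept_ + 10.0, abs=1e-8)
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-10)

    def test_masks_disjoint(self):
        x, y, _ = _signal_data(seed=7)
        model = fit_cpm(x, y)
        assert not np.any(model.pos_mask_ & model.neg_mask_)

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        from sklearn.model_selection import LeaveOneOut, cross_val_predict

        x, y, _ = _signal_data(n=30, e=40, r2=0.8, seed=8)
        est = CPMRegressor(p_thresh=0.05)
        assert clone(est).get_params()["p_thresh"] == 0.05
        preds = cross_val_predict(est, x, y, cv=LeaveOneOut())
        assert preds.shape == y.shape

    def test_empty_mask_falls_back_to_mean(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        model = CPMRegressor(p_thresh=1e-12).fit(x, y)
        assert model.fallback_
        assert np.allclose(model.predict(x), y.mean())


class TestLOOCV:
    def test_strong_signal_recovered(self):
        # equal-magnitude weights: the summary-sum model is then well
        # specified and a near-noiseless signal must be recovered
        x, y, _ = _signal_data(n=120, e=100, k=2, r2=0.999, seed=10)
        res = loocv_cpm(x, y)
        assert res.rho >= 0.95

    def test_no_leakage_under_null(self):
        """Edge selection inside each fold: the leak-free LOO effect size is
        near zero while selecting once on all data inflates it."""
        rng = np.random.default_rng(11)
        rhos, leaky_rhos = [], []
        for _ in range(25):
            x = rng.standard_normal((60, 800))
            y = rng.standard_normal(60)
            rhos.append(loocv_cpm(x, y).rho)
            pos, neg = select_edges(x, y, 0.01)
            keep = pos | neg
            preds = np.empty(60)
            for i in range(60):
                tr = np.ones(60, dtype=bool)
                tr[i] = False
                sums = np.column_stack([x[:, pos].sum(axis=1), x[:, neg].sum(axis=1)])
                d = np.column_stack([np.ones(59), sums[tr]])
                beta, *_ = np.linalg.lstsq(d, y[tr], rcond=None)
                preds[i] = beta[0] + sums[i] @ beta[1:]
            leaky_rhos.append(stats.spearmanr(preds, y).statistic if keep.any() else 0.0)
        assert abs(np.mean(rhos)) < 0.1
        assert np.mean(leaky_rhos) > np.mean(rhos) + 0.2

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            loocv_cpm(np.zeros((5, 3)), np.zeros(5))


class TestTransfer:
    def test_matched_ground_truth_transfers(self):
        x_a, y_a, w = _signal_data(n=300, e=300, r2=0.4, seed=12)
        rng = np.random.default_rng(13)
        x_b = rng.standard_normal((300, 300))
        lp = x_b @ w
        y_b = lp + rng.standard_normal(300) * np.sqrt(lp.var() * 1.5)
        model = fit_cpm(x_a, y_a)
        res = transfer_cpm(model, x_b, y_b)
        assert res.rho > 0
        assert res.p < 0.01

    def test_permuted_phenotype_null(self):
        x_a, y_a, _ = _signal_data(n=300, e=300, r2=0.4, seed=14)
        rng = np.random.default_rng(15)
        model = fit_cpm(x_a, y_a)
        res = transfer_cpm(model, x_a, rng.permutation(y_a))
        assert abs(res.rho) < 0.15

    def test_self_transfer_consistency(self):
        x, y, _ = _signal_data(seed=16)
        model = fit_cpm(x, y)
        res = transfer_cpm(model, x, y)
        np.testing.assert_allclose(res.predictions, model.predict(x))

    def test_edge_count_mismatch_rejected(self):
        x, y, _ = _signal_data(seed=17)
        model = fit_cpm(x, y)
        with pytest.raises(ValueError, match="mismatch"):
            transfer_cpm(model, x[:, :-1], y)


class TestSteigerZ:
    def test_equal_correlations(self):
        z, p = steiger_z(0.4, 0.4, 0.3, 100)
        assert z == 0.0
        assert p == 1.0

    def test_monotone_in_difference(self):
        zs = [steiger_z(0.3 + d, 0.3, 0.5, 200)[0] for d in (0.05, 0.15, 0.3)]
        assert zs[0] < zs[1] < zs[2]
        assert all(z > 0 for z in zs)

    def test_sign_convention(self):
        z, _ = steiger_z(0.2, 0.5, 0.4, 150)
        assert z < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.5, 0.3, 100)
        with pytest.raises(ValueError):
            steiger_z(0.5, 0.4, 0.3, 3)


class TestFDR:
    def test_all_small_p_rejected(self):
        reject, _ = fdr_bh(np.full(10, 0.001), q=0.05)
        assert reject.all()

    def test_textbook_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        # step-up by hand: sorted p, compare to i/m * q
        m = 4
        expected = np.zeros(m, dtype=bool)
        order = np.argsort(p)
        k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank / m * 0.05:
                k = rank
        expected[order[:k]] = True
        reject, p_adj = fdr_bh(p, q=0.05)
        assert np.array_equal(reject, expected)
        assert np.all(p_adj >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestBootstrapCI:
    def test_point_inside_ci(self):
        rng = np.random.default_rng(18)
        true = rng.standard_normal(100)
        pred = 0.5 * true + rng.standard_normal(100)
        rho = stats.spearmanr(pred, true).statistic
        ci = bootstrap_ci(pred, true, n_boot=500, seed=1)
        assert ci["rho"][0] <= rho <= ci["rho"][1]

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(19)
        widths = []
        for n in (50, 200, 800):
            true = rng.standard_normal(n)
            pred = 0.5 * true + rng.standard_normal(n)
            ci = bootstrap_ci(pred, true, n_boot=400, seed=2)
            widths.append(ci["rho"][1] - ci["rho"][0])
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.6)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(20)
        true = rng.standard_normal(60)
        pred = true + rng.standard_normal(60)
        a = bootstrap_ci(pred, true, n_boot=200, seed=3)
        b = bootstrap_ci(pred, true, n_boot=200, seed=3)
        assert a == b
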