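"""Logistic risk model, Hosmer-Lemeshow, continuous NRI, IDI."""

import numpy as np
import pytest
from scipy.special import expit

from sicstrat import (ConvergenceError, ValidationError, continuous_nri,
                      fit_logistic, hosmer_lemeshow, idi)


class TestFitLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        n, a, b = 5000, -3.0, 0.05
        x = rng.normal(0, 30, n)
        y = rng.random(n) < expit(a + b * x)
        fit = fit_logistic(x, y)
        assert abs(fit.slope - b) < 3 * fit.slope_se
        assert fit.converged

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=4000)
        y = rng.random(4000) < 0.3  # independent of x
        fit = fit_logistic(x, y)
        assert abs(fit.slope) < 1.96 * fit.slope_se

    def test_constant_score_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_logistic([0.0] * 10, [0, 1] * 5)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ConvergenceError, match="separation"):
            fit_logistic(x, y)

    def test_predicted_is_inverse_logit(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=500)
        y = rng.random(500) < expit(x)
        fit = fit_logistic(x, y)
        np.testing.assert_allclose(
            fit.predicted, expit(fit.intercept + fit.slope * x), atol=1e-12)


class TestHosmerLemeshow:
    def test_exact_calibration_by_construction(self):
        # within each bin the predicted probability equals the empirical
        # event rate exactly -> chi2 = 0, p = 1
        p, y = [], []
        for k in range(1, 11):  # rates k/20 over 20 patients each: O == E
            p += [k / 20] * 20
            y += [1] * k + [0] * (20 - k)
        res = hosmer_lemeshow(np.array(p), np.array(y), g=10)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_df_is_bins_minus_two(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.05, 0.95, 2000)
        y = rng.random(2000) < p
        res = hosmer_lemeshow(p, y, g=10)
        assert res.df == 8
        assert res.bins.n.sum() == 2000

    def test_invariant_to_relabeling_within_bins(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(int)
        base = hosmer_lemeshow(p, y, g=10)
        # permute outcomes within each decile of predicted risk
        order = np.argsort(p, kind="stable")
        y2 = y.copy()
        for chunk in np.array_split(order, 10):
            y2[chunk] = y[rng.permutation(chunk)]
        perm = hosmer_lemeshow(p, y2, g=10)
        assert perm.chi2 == pytest.approx(base.chi2, rel=1e-12)

    def test_simple_spelling_is_algebraically_identical(self):
        # (O-E)^2 [1/E + 1/(n-E)] == (O-E)^2 n/(E(n-E)): the two common
        # spellings of the statistic are the same number
        rng = np.random.default_rng(23)
        p = rng.uniform(0.1, 0.9, 400)
        y = rng.random(400) < p
        a = hosmer_lemeshow(p, y, g=10, method="corrected")
        b = hosmer_lemeshow(p, y, g=10, method="simple")
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            hosmer_lemeshow([0.2, 0.8], [0, 1], g=2)

    def test_small_n_warns(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(0.2, 0.8, 30)
        y = rng.random(30) < p
        with pytest.warns(UserWarning, match="recommended"):
            hosmer_lemeshow(p, y, g=10)


class TestContinuousNri:
    def test_identity_is_zero(self):
        p = np.array([0.1, 0.4, 0.2, 0.8])
        y = [0, 1, 0, 1]
        assert continuous_nri(p, p, y, n_boot=10).nri == 0.0

    def test_four_patient_hand_example(self):
        # both events up (+1); one nonevent up, one down (0) -> NRI = 1.0
        po = np.array([0.2, 0.2, 0.2, 0.2])
        pn = np.array([0.3, 0.4, 0.25, 0.10])
        y = np.array([1, 1, 0, 0])
        res = continuous_nri(po, pn, y, n_boot=10)
        assert res.nri == 1.0
        assert res.nri_event == 1.0 and res.nri_nonevent == 0.0

    def test_constant_shift_cancels(self):
        # everyone moves up: events +1, nonevents -1 -> total NRI = 0
        rng = np.random.default_rng(31)
        po = rng.uniform(0.1, 0.5, 50)
        y = rng.random(50) < 0.4
        res = continuous_nri(po, po + 0.1, y, n_boot=10)
        assert res.nri == 0.0
        assert res.nri_event == 1.0 and res.nri_nonevent == -1.0

    def test_components_bounded(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            po = rng.uniform(0, 1, 30)
            pn = rng.uniform(0, 1, 30)
            y = rng.random(30) < 0.5
            if y.all() or not y.any():
                continue
            r = continuous_nri(po, pn, y, n_boot=5)
            assert -1 <= r.nri_event <= 1 and -1 <= r.nri_nonevent <= 1
            assert -2 <= r.nri <= 2
            assert r.nri_ci95[0] <= r.nri_ci95[1]

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            continuous_nri([0.1], [0.1, 0.2], [0, 1])


class TestIdi:
    def test_identity_is_zero(self):
        p = np.array([0.1, 0.4, 0.2, 0.8])
        assert idi(p, p, [0, 1, 0, 1], n_boot=10).idi == 0.0

    def test_four_patient_hand_example(self):
        # events: mean new-old = (0.2 + 0.0)/2 = 0.10
        # nonevents: mean new-old = (-0.05 + 0.1)/2 = 0.025 -> IDI 0.075
        po = np.array([0.2, 0.3, 0.1, 0.2])
        pn = np.array([0.4, 0.3, 0.05, 0.3])
        y = np.array([1, 1, 0, 0])
        assert idi(po, pn, y, n_boot=10).idi == pytest.approx(0.075, abs=1e-12)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(41)
        po = rng.uniform(0.1, 0.9, 40)
        pn = rng.uniform(0.1, 0.9, 40)
        y = rng.random(40) < 0.5
        assert idi(po, pn, y, n_boot=5).idi == pytest.approx(
            -idi(po, pn, ~y, n_boot=5).idi, abs=1e-12)


class TestBootstrapReproducibility:
    def test_bit_for_bit_given_seed(self):
        rng = np.random.default_rng(51)
        po = rng.uniform(0.1, 0.9, 100)
        pn = np.clip(po + rng.normal(0, 0.1, 100), 0.01, 0.99)
        y = rng.random(100) < po
        a = continuous_nri(po, pn, y, n_boot=200, seed=123)
        b = continuous_nri(po, pn, y, n_boot=200, seed=123)
        c = continuous_nri(po, pn, y, n_boot=200, seed=124)
        assert a.nri_ci95 == b.nri_ci95 and a.nri_p == b.nri_p
        assert a.nri_ci95 != c.nri_ci95
        d = idi(po, pn, y, n_boot=200, seed=123)
        e = idi(po, pn, y, n_boot=200, seed=123)
        assert d.idi_ci95 == e.idi_ci95
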