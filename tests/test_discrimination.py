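"""ROC curves, DeLong AUC/variance, paired comparison, Youden cutoffs."""

import numpy as np
import pytest
from scipy import stats

from sicstrat import (DegenerateDataError, ValidationError, auc_delong,
                      compare_auc_delong, empirical_roc,
                      optimal_cutoff_youden)


def brute_force_auc(score, label):
    """Exhaustive Mann-Whitney pair enumeration (independent oracle)."""
    s = np.asarray(score, float)
    y = np.asarray(label, bool)
    pos, neg = s[y], s[~y]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestEmpiricalRoc:
    def test_perfect_separation_reaches_corner(self):
        roc = empirical_roc([1, 2, 3], [0, 0, 1])
        idx = np.flatnonzero((roc.sensitivity == 1) & (roc.specificity == 1))
        assert len(idx) == 1  # the separating threshold
        # endpoints present
        assert (roc.sensitivity[0], roc.specificity[0]) == (0, 1)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1, 0)

    def test_all_ties_gives_two_point_diagonal(self):
        roc = empirical_roc([5, 5, 5, 5], [0, 1, 0, 1])
        assert len(roc.thresholds) == 2
        assert np.allclose(roc.sensitivity + (1 - roc.specificity),
                           2 * roc.sensitivity)  # on the diagonal

    def test_monotone_shape(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=100).round(1)  # ties on purpose
        y = rng.random(100) < 0.4
        roc = empirical_roc(s, y)
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.specificity) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            empirical_roc([1, 2, 3], [1, 1, 1])


class TestAucDelong:
    def test_hand_enumerated_example(self):
        # cases {3,1}, controls {2,0}: pairs +,+,-,+ -> 3/4
        assert auc_delong([3, 1, 2, 0], [1, 1, 0, 0]).auc == 0.75

    def test_perfect_separation(self):
        est = auc_delong([1, 2, 10, 11], [0, 0, 1, 1])
        assert est.auc == 1.0 and est.se == 0.0

    def test_constant_score_is_chance(self):
        assert auc_delong([7, 7, 7, 7], [0, 1, 0, 1]).auc == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 200)
            s = rng.normal(size=n).round(1)
            y = np.zeros(n, bool)
            y[rng.choice(n, max(1, int(n * rng.uniform(0.1, 0.9))),
                         replace=False)] = True
            if y.all() or not y.any():
                continue
            assert auc_delong(s, y).auc == pytest.approx(
                brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn_point_estimate(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        s = rng.normal(size=300).round(1)
        y = rng.random(300) < 0.3
        assert auc_delong(s, y).auc == pytest.approx(
            roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=80)
        y = rng.random(80) < 0.3
        a = auc_delong(s, y)
        b = auc_delong(np.exp(2 * s) + 1, y)
        assert a.auc == b.auc and a.se == pytest.approx(b.se, rel=1e-12)

    def test_se_matches_hanley_mcneil_closed_form(self):
        # continuous no-ties scores from the bi-exponential model, where the
        # Hanley-McNeil Q1/Q2 expressions hold exactly: the DeLong SE should
        # agree with the closed form within Monte-Carlo tolerance
        rng = np.random.default_rng(7)
        m, n = 300, 900
        ses, hms = [], []
        for _ in range(40):
            cases = rng.exponential(1 / 0.4, m)
            controls = rng.exponential(1.0, n)
            s = np.r_[cases, controls]
            y = np.r_[np.ones(m, bool), np.zeros(n, bool)]
            est = auc_delong(s, y)
            a = est.auc
            q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
            hm = np.sqrt((a * (1 - a) + (m - 1) * (q1 - a**2)
                          + (n - 1) * (q2 - a**2)) / (m * n))
            ses.append(est.se)
            hms.append(hm)
        assert np.mean(ses) == pytest.approx(np.mean(hms), rel=0.02)


class TestCompareAucDelong:
    def test_identical_scores(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        c = compare_auc_delong(s, s, y)
        assert c.z == 0.0 and c.p == 1.0

    def test_monotone_transform_is_identity(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        c = compare_auc_delong(s, np.tanh(s) * 3 + 10, y)
        assert c.auc_a == c.auc_b and c.p == 1.0

    def test_z_sign_matches_auc_difference(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=200)
        y = rng.random(200) < (1 / (1 + np.exp(-2 * z)))
        good = z + rng.normal(0, 0.3, 200)
        bad = z + rng.normal(0, 3.0, 200)
        c = compare_auc_delong(good, bad, y)
        assert (c.auc_a - c.auc_b) * c.z > 0

    def test_small_fixture_against_hand_computation(self):
        # n=10 paired fixture; expected values from explicit structural
        # components (placements) computed by enumeration below
        sa = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1])
        sb = np.array([0.8, 0.9, 0.3, 0.5, 0.25, 0.6, 0.4, 0.2, 0.7, 0.1])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0, 1, 0], bool)

        def components(s):
            pos, neg = s[y], s[~y]
            psi = (pos[:, None] > neg[None, :]) + 0.5 * (
                pos[:, None] == neg[None, :])
            return psi.mean(), psi.mean(1), psi.mean(0)

        auc_a, v10a, v01a = components(sa)
        auc_b, v10b, v01b = components(sb)
        m, n = v10a.size, v01a.size
        var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
        var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
        cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
               + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
        z_expected = (auc_a - auc_b) / np.sqrt(var_a + var_b - 2 * cov)

        c = compare_auc_delong(sa, sb, y)
        assert c.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert c.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert c.covariance == pytest.approx(cov, abs=1e-12)
        assert c.z == pytest.approx(z_expected, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compare_auc_delong([1, 2], [1, 2, 3], [0, 1])

    def test_null_rejection_rate_nominal(self):
        # two scores jointly exchangeable w.r.t. the outcome: the paired
        # test should reject at ~5% over many simulated datasets
        rng = np.random.default_rng(2024)
        n, reps = 200, 2000
        rejections = 0
        for _ in range(reps):
            latent = rng.normal(size=n)
            y = rng.random(n) < 1 / (1 + np.exp(-latent))
            if y.all() or not y.any():
                continue
            sa = latent + rng.normal(0, 1, n)
            sb = latent + rng.normal(0, 1, n)
            if compare_auc_delong(sa, sb, y).p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.015)


class TestYouden:
    def test_perfect_classifier(self):
        roc = empirical_roc([3, 4, 1, 2], [1, 1, 0, 0])
        cut, sens, spec = optimal_cutoff_youden(roc)
        assert sens == 1.0 and spec == 1.0
        assert 2 < cut < 3  # separating threshold

    def test_diagonal_ties_break_to_smallest(self):
        roc = empirical_roc([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        cut, sens, spec = optimal_cutoff_youden(roc)
        assert sens + spec - 1 == 0.0
        assert cut == 5.0  # the smallest threshold

    def test_one_mislabeled_control(self):
        # cases {3,4}, controls {1,2,3.5}: best J at threshold 3, cutoff
        # reported between 2 and 3 (enumerating all thresholds by hand)
        roc = empirical_roc([3, 4, 1, 2, 3.5], [1, 1, 0, 0, 0])
        cut, sens, spec = optimal_cutoff_youden(roc)
        assert 2 < cut < 3
        assert sens == 1.0 and spec == pytest.approx(2 / 3)
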