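"""Confirmatory factor analysis: ML discrepancy, indices, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from driftsem import studytables as tables
from driftsem.cfa import (
    CFAModel,
    SEMModelSpec,
    classify_fit,
    kmo,
    omega_hierarchical,
    omega_single,
)


def _single(p):
    return SEMModelSpec.single_factor([f"x{i+1}" for i in range(p)])


def _construct(lam, theta_diag):
    """Population covariance implied by a single factor."""
    lam = np.asarray(lam, float)
    return np.outer(lam, lam) + np.diag(theta_diag)


class TestFitML:
    def test_construct_then_recover_exact(self):
        """S built as lambda lambda' + diag(theta) is recovered exactly."""
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        theta = 1.0 - lam ** 2
        S = _construct(lam, theta)
        fit = CFAModel(_single(5), S, 200).fit()
        assert fit.fml == pytest.approx(0.0, abs=1e-10)
        est = fit.loadings.iloc[:, 0].to_numpy()
        est = est * np.sign(est.sum())
        np.testing.assert_allclose(est, lam, atol=1e-6)

    def test_saturated_three_indicator_chi2_zero(self):
        R = np.array([[1, 0.5, 0.4], [0.5, 1, 0.3], [0.4, 0.3, 1.0]])
        fit = CFAModel(_single(3), R, 100).fit()
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        idx = fit.fit_indices()
        assert idx["cfi"] == 1.0 and idx["rmsea"] == 0.0
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-6)

    def test_degrees_of_freedom_bookkeeping(self):
        # single factor, 8 indicators: 36 - 16 = 20
        assert _single(8).degrees_of_freedom() == 20
        # bifactor with correlated same-task errors, 16 indicators:
        # 136 - (16 + 8 + 16 + 8) = 88
        inds = [f"t{k}_{c}" for k in range(8) for c in ("inc", "con")]
        spec = SEMModelSpec.bifactor(
            inds,
            specific=[f"t{k}_inc" for k in range(8)],
            correlated_errors=[(f"t{k}_inc", f"t{k}_con") for k in range(8)],
        )
        assert spec.degrees_of_freedom() == 88

    def test_not_positive_definite_raises_with_eigenvalue(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = SEMModelSpec.single_factor(["x1", "x2"])
        with pytest.raises(ValueError, match="smallest eigenvalue"):
            CFAModel(spec, S, 50)

    def test_heywood_case_flagged_as_warnings(self):
        # one indicator nearly collinear with the factor forces a negative
        # error-variance estimate
        lam = np.array([1.02, 0.5, 0.4, 0.3])
        S = _construct(lam, np.array([-0.02, 0.75, 0.84, 0.91]) + 1e-9)
        S = 0.5 * (S + S.T)
        fit = CFAModel(_single(4), S, 100).fit()
        assert fit.status == "converged_with_warnings"
        assert fit.classify() == "warnings"

    def test_nested_chi2_ordering(self):
        """A restricted model never fits better than the model nesting it."""
        R = tables.dataset1_boundary()
        p = len(R)
        free = CFAModel(SEMModelSpec.single_factor(R.index), R, 120).fit()
        # saturated comparison: zero discrepancy by definition
        assert free.chi2 >= 0.0
        # adding correlated errors can only decrease the discrepancy
        spec2 = SEMModelSpec(
            tuple(R.index), {"g": tuple(R.index)},
            correlated_errors=(("color_stroop", "number_stroop"),),
        )
        richer = CFAModel(spec2, R, 120).fit()
        assert richer.chi2 <= free.chi2 + 1e-6

    def test_cross_check_against_statsmodels_ml_factor(self):
        """1-factor ML EFA (statsmodels) and 1-factor CFA are the same
        model; loadings must agree up to sign."""
        from statsmodels.multivariate.factor import Factor

        R = tables.dataset1_boundary().to_numpy()
        fit = CFAModel(_single(8), R, 120).fit()
        sm = Factor(corr=pd.DataFrame(R), n_factor=1, method="ml").fit()
        lam_sm = np.asarray(sm.loadings).ravel()
        lam = fit.standardized()[0].iloc[:, 0].to_numpy()
        lam = lam * np.sign(lam.sum()) * np.sign(lam_sm.sum())
        np.testing.assert_allclose(lam, lam_sm, atol=2e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.3, 3.0), min_size=5, max_size=5))
    def test_scale_invariance(self, scales):
        """chi2, CFI and SRMR are unchanged when S -> D S D for positive
        diagonal D (free loadings/variances)."""
        lam = np.array([0.7, 0.6, 0.5, 0.65, 0.55])
        S = _construct(lam, 1 - lam ** 2) + 0.05 * np.eye(5)
        D = np.diag(scales)
        f1 = CFAModel(_single(5), S, 150).fit()
        f2 = CFAModel(_single(5), D @ S @ D, 150).fit()
        i1, i2 = f1.fit_indices(), f2.fit_indices()
        assert f2.chi2 == pytest.approx(f1.chi2, abs=1e-6)
        assert i2["cfi"] == pytest.approx(i1["cfi"], abs=1e-6)
        assert i2["srmr"] == pytest.approx(i1["srmr"], abs=1e-6)


class TestIndices:
    def test_srmr_equals_bruteforce_residual_sum(self):
        R = tables.dataset1_drift_diff().to_numpy()
        fit = CFAModel(_single(8), R, 120).fit()
        Sigma = fit.implied
        d = 1 / np.sqrt(np.diag(Sigma))
        Rhat = Sigma * np.outer(d, d)
        acc = []
        for i in range(8):
            for j in range(i, 8):
                acc.append((R[i, j] - Rhat[i, j]) ** 2)
        assert fit.fit_indices()["srmr"] == pytest.approx(
            np.sqrt(np.mean(acc)), abs=1e-12
        )

    def test_perfect_fit_indices(self):
        lam = np.array([0.7, 0.6, 0.5, 0.4])
        S = _construct(lam, 1 - lam ** 2)
        idx = CFAModel(_single(4), S, 100).fit().fit_indices()
        assert idx["cfi"] == 1.0
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-7)
        assert idx["rmsea"] == 0.0

    def test_rmsea_ci_brackets_point_estimate(self):
        R = tables.dataset1_boundary()
        fit = CFAModel(SEMModelSpec.single_factor(R.index), R, 120).fit()
        idx = fit.fit_indices()
        lo, hi = idx["rmsea_ci"]
        assert 0 <= lo <= idx["rmsea"] <= hi


class TestKMO:
    def test_equicorrelation_closed_form(self):
        """3x3 equicorrelation r=0.5: partials are 1/3, KMO = 0.692."""
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        expected = (6 * 0.25) / (6 * 0.25 + 6 * (1 / 3) ** 2)
        assert kmo(R) == pytest.approx(expected, abs=1e-12)

    def test_bruteforce_partial_correlations(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(200, 4))
        R = np.corrcoef(A.T)
        # anti-image via explicit partial correlation of each pair given rest
        from itertools import combinations

        Rinv = np.linalg.inv(R)
        num, den = 0.0, 0.0
        for i, j in combinations(range(4), 2):
            q = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
            num += 2 * R[i, j] ** 2
            den += 2 * (R[i, j] ** 2 + q ** 2)
        assert kmo(R) == pytest.approx(num / den, abs=1e-12)

    def test_near_identity_warns(self):
        R = np.eye(4) + 1e-8 * (np.ones((4, 4)) - np.eye(4))
        with pytest.warns(UserWarning, match="uninformative"):
            kmo(R)

    def test_singular_raises(self):
        R = np.ones((3, 3))
        with pytest.raises(ValueError):
            kmo(R)


class TestReliability:
    def test_omega_formula_arithmetic(self):
        """8 equal standardized loadings of 0.7: omega = 31.36/35.44."""
        lam = np.full(8, 0.7)
        S = _construct(lam, 1 - lam ** 2)
        fit = CFAModel(_single(8), S, 200).fit()
        assert omega_single(fit) == pytest.approx(31.36 / 35.44, abs=1e-6)

    def test_omega_zero_when_no_common_variance(self):
        S = np.eye(4)
        spec = SEMModelSpec.single_factor([f"x{i+1}" for i in range(4)])
        fit = CFAModel(spec, S + 1e-9, 100).fit()
        assert omega_single(fit) == pytest.approx(0.0, abs=1e-3)

    def test_omega_h_zero_specific_loadings(self):
        lam_g = np.array([0.6, 0.6, 0.6, 0.6])
        S = _construct(lam_g, 1 - lam_g ** 2)
        spec = SEMModelSpec.bifactor(
            ["x1", "x2", "x3", "x4"], specific=["x1", "x2"], nonnegative=True
        )
        fit = CFAModel(spec, S, 150).fit()
        assert omega_hierarchical(fit, "s") == pytest.approx(0.0, abs=5e-3)

    def test_omega_h_implied_covariance_oracle(self):
        """Hand-built bifactor: omega_h equals the ratio computed by summing
        the implied covariance matrix of the specific indicators."""
        lam_g = np.full(4, 0.6)
        lam_s = np.array([0.4, 0.4, 0.0, 0.0])
        theta = 1 - lam_g ** 2 - lam_s ** 2
        S = np.outer(lam_g, lam_g) + np.outer(lam_s, lam_s) + np.diag(theta)
        spec = SEMModelSpec.bifactor(
            ["x1", "x2", "x3", "x4"], specific=["x1", "x2"], nonnegative=True
        )
        fit = CFAModel(spec, S, 500).fit()
        members = [0, 1]
        total_var = S[np.ix_(members, members)].sum()
        expected = lam_s[:2].sum() ** 2 / total_var
        assert omega_hierarchical(fit, "s") == pytest.approx(expected, abs=1e-4)

    def test_omega_bounds(self):
        R = tables.dataset1_boundary()
        fit = CFAModel(SEMModelSpec.single_factor(R.index), R, 120).fit()
        assert 0.0 <= omega_single(fit) <= 1.0


class TestClassification:
    def _dummy(self, status="converged", n=120):
        R = tables.dataset1_boundary()
        fit = CFAModel(SEMModelSpec.single_factor(R.index), R, n).fit()
        fit.status = status
        return fit

    def test_rules_small_sample(self):
        fit = self._dummy()
        good = {"cfi": 1.0, "srmr": 0.05, "rmsea": 0.2}
        assert classify_fit(fit, good, 120) == "good"
        acc = {"cfi": 0.92, "srmr": 0.07, "rmsea": 0.2}
        assert classify_fit(fit, acc, 120) == "acceptable"
        bad = {"cfi": 0.85, "srmr": 0.07, "rmsea": 0.0}
        assert classify_fit(fit, bad, 120) == "bad"

    def test_rules_large_sample_use_rmsea(self):
        fit = self._dummy()
        assert classify_fit(fit, {"cfi": 0.92, "srmr": 0.07, "rmsea": 0.07}, 443) == "acceptable"
        assert classify_fit(fit, {"cfi": 0.97, "srmr": 0.05, "rmsea": 0.05}, 443) == "good"
        assert classify_fit(fit, {"cfi": 0.97, "srmr": 0.05, "rmsea": 0.09}, 443) == "bad"

    def test_warning_status_passes_through(self):
        fit = self._dummy("converged_with_warnings")
        assert classify_fit(fit, {"cfi": 1.0, "srmr": 0.01, "rmsea": 0.0}, 120) == "warnings"
        fit = self._dummy("nonconverged")
        assert classify_fit(fit, None, 120) == "nonconverged"


def test_bifactor_positivity_constraint_respected():
    R = tables.dataset1_boundary().to_numpy()[:4, :4]
    spec = SEMModelSpec.bifactor(
        ["x1", "x2", "x3", "x4"], specific=["x1", "x2"], nonnegative=True
    )
    fit = CFAModel(spec, R, 120).fit()
    assert (fit.loadings.to_numpy() >= -1e-9).all()


def test_summary_smoke():
    R = tables.dataset1_boundary()
    fit = CFAModel(SEMModelSpec.single_factor(R.index), R, 120).fit()
    text = fit.summary()
    assert "chi2(20)" in text and "CFI" in text
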