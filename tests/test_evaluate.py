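"""Comparison metrics against hand-computed oracles, and cohort reporting."""

import numpy as np
import pytest

from co2exchange import (
    OmegaVector,
    ThetaParams,
    VentilationRecord,
    aic,
    asymptotic_variance,
    equation_error_residuals,
    omega_from_theta,
    paired_ttest,
    rmse,
)
from co2exchange.evaluate import compare_cohort, omega_jacobian


def flatish_record(n=120, x1=None, u=None, ts_s=5.0):
    if x1 is None:
        x1 = np.full(n, 46.0)
    if u is None:
        u = np.full(n, 2.24)
    return VentilationRecord(ts_s, np.arange(n) * ts_s, x1, u, subject_id="m")


class TestRmse:
    def test_zero_for_identical(self):
        x = np.linspace(35, 45, 50)
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.linspace(35, 45, 50)
        assert rmse(x, x + 1.0) == pytest.approx(1.0)

    def test_hand_residuals(self):
        assert rmse(np.array([3.0, 0.0]), np.array([0.0, 4.0])) == pytest.approx(
            np.sqrt(25 / 2)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(5), np.zeros(6))


class TestEquationErrorResiduals:
    def test_zero_on_self_generated_data(self, discrete_subject):
        res, lam = equation_error_residuals(
            discrete_subject.theta, discrete_subject.theta.tau,
            discrete_subject.record, "M3",
        )
        assert lam < 1e-18
        assert np.max(np.abs(res)) < 1e-8

    def test_noise_gives_positive_variance(self, discrete_subject):
        rng = np.random.default_rng(0)
        rec = discrete_subject.record
        noisy = VentilationRecord(
            rec.ts_s, rec.t_s, rec.petco2 + rng.normal(0, 0.5, len(rec)),
            rec.vdot,
        )
        _, lam = equation_error_residuals(
            discrete_subject.theta, discrete_subject.theta.tau, noisy, "M3"
        )
        assert lam > 0

    def test_worked_second_difference_case(self):
        """x1 = (1,4,9,...) with zero coefficients: the equation error is
        the raw second difference, 2/Ts^2 at every interior sample."""
        n = 12
        x1 = (np.arange(1, n + 1).astype(float)) ** 2
        rec = VentilationRecord(5.0, np.arange(n) * 5.0, x1, np.zeros(n))
        w = OmegaVector("M2", (1e-300, 1e-300, 1e-300, 1e-300))
        res, _ = equation_error_residuals(w, 0, rec, "M2")
        ts_min = 5.0 / 60.0
        assert res[0] == pytest.approx(2.0 / ts_min**2)


class TestAsymptoticVariance:
    def test_zero_residuals_zero_variance(self, discrete_subject):
        av = asymptotic_variance(
            discrete_subject.theta, discrete_subject.theta.tau,
            discrete_subject.record, "M3",
        )
        assert np.all(av.var < 1e-12)

    def test_inverse_n_scaling(self):
        """Doubling the record with the same residual statistics halves the
        asymptotic variance (the 1/N prefactor)."""
        rng = np.random.default_rng(3)
        th = ThetaParams(0.44, 2.95, 0.26, 3.95, tau=2)
        u = 2.24 + 0.5 * np.sin(np.arange(480) / 7.0)
        x1 = 46.0 + 2.0 * np.sin(np.arange(480) / 11.0) + rng.normal(0, 0.5, 480)
        rec_long = flatish_record(480, x1=x1, u=u)
        rec_short = flatish_record(240, x1=x1[:240], u=u[:240])
        av_l = asymptotic_variance(th, 2, rec_long, "M3")
        av_s = asymptotic_variance(th, 2, rec_short, "M3")
        ratio = av_s.var / av_l.var
        assert np.all(ratio > 1.2)  # shrinks with N (statistics differ slightly)

    def test_orthonormal_toy_design(self):
        """Brute-force check on a constructed design: with orthonormal
        regressors and unit residual variance, each parameter variance is
        1/N."""
        rng = np.random.default_rng(1)
        n, k = 100, 2
        q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        sens = q * np.sqrt(n)  # (1/N) S^T S = I
        res = rng.standard_normal(n)
        lam = float(np.mean(res**2))
        cov = sens.T @ sens / n
        var = lam / n * np.diag(np.linalg.inv(cov))
        assert var == pytest.approx(np.full(k, lam / n), rel=1e-9)

    def test_theta4_least_excited_direction(self, discrete_subject):
        """The metabolic parameter's regressor is the constant 1, so theta4
        carries the largest percent asymptotic deviation."""
        rng = np.random.default_rng(4)
        rec = discrete_subject.record
        noisy = VentilationRecord(
            rec.ts_s, rec.t_s, rec.petco2 + rng.normal(0, 0.5, len(rec)), rec.vdot
        )
        av = asymptotic_variance(
            discrete_subject.theta, discrete_subject.theta.tau, noisy, "M3"
        )
        assert av.sd_pct[3] > max(av.sd_pct[:3])

    def test_jacobian_matches_finite_differences(self):
        th = ThetaParams(0.7, 2.1, 0.4, 5.0)
        J = omega_jacobian(th, "M3")
        eps = 1e-7
        base = np.array(omega_from_theta(th, "M3").coeffs)
        for j, name in enumerate(["theta1", "theta2", "theta3", "theta4"]):
            kw = {k: getattr(th, k) for k in ("theta1", "theta2", "theta3", "theta4")}
            kw[name] += eps
            bumped = np.array(omega_from_theta(ThetaParams(**kw), "M3").coeffs)
            np.testing.assert_allclose(J[:, j], (bumped - base) / eps, atol=1e-5)


class TestAic:
    def test_direct_formula_small_k(self):
        """N=100, K=2, unit residual variance: 0 + 4 + 12/97."""
        assert _aic_formula(100, 2, 1.0) == pytest.approx(4.1237, abs=1e-4)

    def test_direct_formula_larger_k_penalised(self):
        assert _aic_formula(100, 4, 1.0) == pytest.approx(8.4211, abs=1e-4)
        assert _aic_formula(100, 4, 1.0) > _aic_formula(100, 2, 1.0)

    def test_log_variance_term(self):
        assert _aic_formula(100, 3, np.e) - _aic_formula(100, 3, 1.0) == pytest.approx(
            100.0
        )

    def test_increasing_in_k_and_variance(self):
        for k in range(2, 6):
            assert _aic_formula(200, k + 1, 1.3) > _aic_formula(200, k, 1.3)
        assert _aic_formula(200, 3, 2.0) > _aic_formula(200, 3, 1.5)

    def test_module_aic_on_record_matches_formula(self, discrete_subject):
        rng = np.random.default_rng(9)
        rec = discrete_subject.record
        noisy = VentilationRecord(
            rec.ts_s, rec.t_s, rec.petco2 + rng.normal(0, 0.5, len(rec)), rec.vdot
        )
        from co2exchange.evaluate import prediction_residuals

        res, lam = prediction_residuals(
            discrete_subject.theta, discrete_subject.theta.tau, noisy, "M3"
        )
        got = aic(discrete_subject.theta, discrete_subject.theta.tau, noisy, "M3")
        assert got == pytest.approx(_aic_formula(len(res), 5, lam))

    def test_small_sample_guard(self, discrete_subject):
        with pytest.raises(ValueError, match="N="):
            aic(
                discrete_subject.theta, discrete_subject.theta.tau,
                discrete_subject.record, "M3", K_override=1000,
            )


def _aic_formula(n, k, lam):
    return n * np.log(lam) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class TestPairedTTest:
    def test_printed_pairs(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.1, 2.3, 3.2])
        assert t == pytest.approx(-3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_identical_vectors_no_significance(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(t) or abs(t) < 1e-12 or p > 0.9


@pytest.fixture(scope="module")
def small_cohort_fits():
    from co2exchange import FitOptions, fit_model
    from co2exchange.cohort import generate_cohort

    cohort = generate_cohort(3, master_seed=21, noise_sd=0.5, method="discrete")
    opts = FitOptions(n_starts=2, seed=3, tau_grid=(1, 3, 5, 7, 9, 11))
    fits, records = {}, {}
    for sub in cohort:
        sid = sub.record.subject_id
        records[sid] = sub.record
        fits[sid] = {m: fit_model(sub.record, m, opts) for m in ("M1", "M2", "M3")}
    return fits, records


class TestCompareCohort:

    def test_win_counts_sum_to_cohort_size(self, small_cohort_fits):
        fits, records = small_cohort_fits
        comp = compare_cohort(fits, records)
        assert sum(comp.aic_win_counts.values()) == len(fits)

    def test_summary_and_tests_present(self, small_cohort_fits):
        fits, records = small_cohort_fits
        comp = compare_cohort(fits, records)
        assert set(comp.summary) == {"M1", "M2", "M3"}
        assert "VL_l" in comp.summary["M3"] and "VL_l" not in comp.summary["M1"]
        assert "rmse_M2_vs_M3" in comp.ttests
        for res in comp.ttests.values():
            assert 0.0 <= res["p"] <= 1.0

    def test_missing_model_rejected(self, small_cohort_fits):
        fits, records = small_cohort_fits
        broken = {s: dict(m) for s, m in fits.items()}
        next(iter(broken.values())).pop("M2")
        with pytest.raises(ValueError, match="lacks fits"):
            compare_cohort(broken, records)

    def test_two_subjects_skips_ttests(self, small_cohort_fits):
        fits, records = small_cohort_fits
        two = dict(list(fits.items())[:2])
        with pytest.warns(UserWarning, match="fewer than 3"):
            comp = compare_cohort(two, records)
        assert comp.ttests == {}
        assert sum(comp.aic_win_counts.values()) == 2
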