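"""Power-law and Carreau model evaluation, fitting, goodness of fit."""

import numpy as np
import pytest
from sklearn.base import clone

from hemorheo.errors import DomainError
from hemorheo.reference import (CARREAU_23C, CARREAU_37C, POWER_LAW_23C,
                                POWER_LAW_37C)
from hemorheo.rheology import (CarreauModel, PowerLawModel, ViscosityCurve,
                               carreau_viscosity, fit_carreau, fit_power_law,
                               goodness_of_fit, power_law_viscosity,
                               relative_viscosity)
from hemorheo.synthetic import gen_viscosity_samples


class TestModelEvaluation:
    def test_newtonian_limit(self):
        g = np.array([0.1, 1.0, 10.0, 100.0])
        np.testing.assert_allclose(power_law_viscosity(g, K=3.2, n=1.0), 3.2)

    def test_unit_shear_rate_returns_K(self):
        assert power_law_viscosity(1.0, K=50.9, n=0.156) == 50.9

    def test_published_power_law_row_at_ten_per_second(self):
        # 50.9 * 10^(0.156-1), evaluated independently
        assert power_law_viscosity(10.0, 50.9, 0.156) == pytest.approx(
            7.2898, abs=2e-3)

    def test_power_law_rejects_nonpositive_shear(self):
        with pytest.raises(DomainError):
            power_law_viscosity(0.0, 1.0, 0.5)
        with pytest.raises(DomainError):
            power_law_viscosity(np.array([1.0, -2.0]), 1.0, 0.5)

    def test_carreau_zero_shear_plateau(self):
        assert carreau_viscosity(0.0, 26.9, 1.6, 3.313, 0.353) == 26.9

    def test_carreau_equal_plateaus_constant(self):
        g = np.logspace(-2, 3, 20)
        np.testing.assert_allclose(carreau_viscosity(g, 5.0, 5.0, 3.3, 0.3),
                                   5.0)

    def test_published_carreau_row_at_unit_shear(self):
        # mu_inf + (mu_0-mu_inf)(1+lam^2)^((n-1)/2), evaluated independently
        assert carreau_viscosity(1.0, 118.6, 2.3, 3.312, 0.362) \
            == pytest.approx(54.984, abs=0.01)

    @pytest.mark.parametrize("params", list(CARREAU_23C.values()))
    def test_carreau_limits(self, params):
        """Plateaus are approached at the model's own rate (λγ̇)^(n−1)."""
        lo = carreau_viscosity(1e-8, params.mu_zero, params.mu_inf,
                               params.lam, params.n)
        assert lo == pytest.approx(params.mu_zero, rel=1e-6)
        # the high-shear plateau converges like γ̇^(n-1); for n ≈ 0.36 the
        # deviation reaches 1e-6 relative only around γ̇ ≈ 1e12 1/s
        hi = carreau_viscosity(1e12, params.mu_zero, params.mu_inf,
                               params.lam, params.n)
        assert hi == pytest.approx(params.mu_inf, rel=1e-6)
        drift = carreau_viscosity(1e8, params.mu_zero, params.mu_inf,
                                  params.lam, params.n) - params.mu_inf
        assert 0 < drift / params.mu_inf < 1e-3

    def test_shear_thinning_monotone_for_n_below_one(self):
        g = np.logspace(-1, 2, 200)
        assert np.all(np.diff(power_law_viscosity(g, 9.9, 0.603)) < 0)
        assert np.all(np.diff(carreau_viscosity(g, 26.9, 1.6, 3.313, 0.353))
                      < 0)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        gof = goodness_of_fit([1, 2, 3], [1, 2, 3], p=2)
        assert gof.rmse == 0.0 and gof.r_squared == 1.0

    def test_hand_example_single_residual(self):
        gof = goodness_of_fit([1, 2, 3], [1, 2, 4], p=2)
        assert gof.rmse == pytest.approx(1.0)

    def test_hand_example_constant_offset(self):
        gof = goodness_of_fit([0, 0, 0], [1, 1, 1], p=1)
        assert gof.rmse == pytest.approx(np.sqrt(1.5))

    def test_zero_dof_consistency(self):
        """p = 0 RMSE equals the plain residual RMS."""
        e = np.array([1.0, 3.0, 2.0, 5.0])
        f = np.array([1.5, 2.0, 2.5, 4.0])
        gof = goodness_of_fit(e, f, p=0)
        assert gof.rmse == pytest.approx(np.sqrt(np.mean((e - f) ** 2)))

    def test_too_few_dof_rejected(self):
        with pytest.raises(DomainError):
            goodness_of_fit([1, 2], [1, 2], p=2)


class TestPowerLawFit:
    def test_exact_newtonian_data(self):
        g = np.logspace(0, 2, 10)
        fit = fit_power_law(ViscosityCurve(g, np.ones_like(g)))
        assert fit.consistency_K == pytest.approx(1.0, rel=1e-12)
        assert fit.behaviour_index_n == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("params", list(POWER_LAW_23C.values())
                             + list(POWER_LAW_37C.values()))
    def test_noiseless_round_trip(self, params):
        curve = gen_viscosity_samples("powerlaw", params,
                                      gamma_range=(1, 50), m=40)
        fit = fit_power_law(curve)
        assert fit.consistency_K == pytest.approx(params.K, rel=1e-10)
        assert fit.behaviour_index_n == pytest.approx(params.n, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_five_percent(self):
        curve = gen_viscosity_samples("powerlaw", POWER_LAW_23C[10],
                                      gamma_range=(1, 50), m=50,
                                      noise_sigma=0.05, seed=3)
        fit = fit_power_law(curve)
        assert fit.consistency_K == pytest.approx(POWER_LAW_23C[10].K,
                                                  rel=0.05)
        assert fit.behaviour_index_n == pytest.approx(POWER_LAW_23C[10].n,
                                                      abs=0.05)

    def test_shear_rescaling_covariance(self):
        """Rescaling γ̇ by c maps K to K·c^(1−n) and leaves n unchanged."""
        g = np.logspace(0, 1.7, 30)
        mu = power_law_viscosity(g, 50.9, 0.156)
        c = 3.7
        base = PowerLawModel().fit(g, mu)
        scaled = PowerLawModel().fit(c * g, mu)
        assert scaled.n_ == pytest.approx(base.n_, abs=1e-10)
        assert scaled.K_ == pytest.approx(base.K_ * c ** (1 - base.n_),
                                          rel=1e-10)

    def test_nonpositive_data_lists_indices(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        mu = np.array([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(DomainError, match=r"\[1\]"):
            PowerLawModel().fit(np.array([1.0, -2.0, 3.0, 4.0]), mu)
        with pytest.raises(DomainError):
            PowerLawModel().fit(g[:2], mu[:2])


class TestCarreauFit:
    @pytest.mark.parametrize("hct", [5, 10, 15])
    def test_noiseless_round_trip_room_temperature(self, hct):
        p = CARREAU_23C[hct]
        curve = gen_viscosity_samples("carreau", p, gamma_range=(0.5, 100),
                                      m=60)
        fit = fit_carreau(curve)
        assert fit.converged
        assert fit.mu_zero == pytest.approx(p.mu_zero, rel=1e-3)
        assert fit.mu_inf == pytest.approx(p.mu_inf, rel=1e-3)
        assert fit.relaxation_lambda == pytest.approx(p.lam, rel=1e-3)
        assert fit.index_n == pytest.approx(p.n, rel=1e-3)

    def test_truth_initialization_is_stationary(self):
        p = CARREAU_23C[5]
        curve = gen_viscosity_samples("carreau", p, gamma_range=(0.5, 100),
                                      m=60)
        est = CarreauModel(init={"mu_zero": p.mu_zero, "mu_inf": p.mu_inf,
                                 "lam": p.lam, "n": p.n})
        est.fit(curve.shear_rates_s1, curve.viscosities_cp)
        assert est.mu_zero_ == pytest.approx(p.mu_zero, rel=1e-8)

    def test_noisy_recovery(self):
        """2% multiplicative noise: μ0 and n recover within 10% (median over
        seeds); λ is the least identifiable parameter (it trades off
        against μ0 near the knee) and recovers within 20%."""
        p = CARREAU_23C[15]
        errs = []
        for seed in range(5):
            curve = gen_viscosity_samples("carreau", p,
                                          gamma_range=(0.5, 100), m=60,
                                          noise_sigma=0.02, seed=seed)
            fit = fit_carreau(curve)
            errs.append([abs(fit.mu_zero - p.mu_zero) / p.mu_zero,
                         abs(fit.relaxation_lambda - p.lam) / p.lam,
                         abs(fit.index_n - p.n) / p.n])
        med = np.median(errs, axis=0)
        assert med[0] < 0.10
        assert med[1] < 0.20
        assert med[2] < 0.10

    def test_fixing_lambda_stabilizes_noisy_fit(self):
        p = CARREAU_23C[15]
        curve = gen_viscosity_samples("carreau", p, gamma_range=(0.5, 100),
                                      m=60, noise_sigma=0.02, seed=3)
        free = fit_carreau(curve)
        pinned = fit_carreau(curve, lam_fixed=p.lam)
        assert abs(pinned.mu_zero - p.mu_zero) <= abs(free.mu_zero
                                                      - p.mu_zero)

    def test_fixed_lambda_reduces_dof(self):
        p = CARREAU_23C[10]
        curve = gen_viscosity_samples("carreau", p, gamma_range=(0.5, 100),
                                      m=60)
        fit = fit_carreau(curve, lam_fixed=p.lam)
        assert fit.p == 3
        assert fit.relaxation_lambda == p.lam
        assert fit.mu_zero == pytest.approx(p.mu_zero, rel=1e-6)

    def test_negative_index_accepted_with_warning(self):
        p = CARREAU_37C[15]  # published row with n < 0
        curve = gen_viscosity_samples("carreau", p, gamma_range=(0.5, 100),
                                      m=60)
        with pytest.warns(UserWarning):
            fit = fit_carreau(curve)
        assert fit.index_n == pytest.approx(p.n, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            CarreauModel().fit([1, 2, 3, 4], [4, 3, 2, 1.5])


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = CarreauModel(lam_fixed=3.3, init={"n": 0.4})
        est2 = clone(est)
        assert est2.get_params()["lam_fixed"] == 3.3
        est2.set_params(lam_fixed=None)
        assert est2.lam_fixed is None

    def test_fitted_attributes_and_predict(self):
        g = np.logspace(0, 1.7, 25)
        mu = power_law_viscosity(g, 9.9, 0.603)
        est = PowerLawModel().fit(g.reshape(-1, 1), mu)
        assert est.K_ == pytest.approx(9.9)
        np.testing.assert_allclose(est.predict(g.reshape(-1, 1)), mu,
                                   rtol=1e-10)

    def test_regressor_score_is_r_squared(self):
        g = np.logspace(-0.3, 2, 40)
        mu = carreau_viscosity(g, 89.9, 1.6, 3.312, 0.369)
        est = CarreauModel().fit(g, mu)
        assert est.score(g.reshape(-1, 1), mu) == pytest.approx(1.0)


class TestRelativeViscosity:
    def test_published_plasma_viscosity_halving(self):
        assert relative_viscosity(4.38, 2.19) == pytest.approx(2.0)

    def test_identity_and_degenerate_zero(self):
        assert relative_viscosity(2.19, 2.19) == 1.0
        assert relative_viscosity(0.0, 2.19) == 0.0

    def test_nonpositive_plasma_rejected(self):
        with pytest.raises(DomainError):
            relative_viscosity(1.0, 0.0)

    def test_curve_relative_viscosities(self):
        c = ViscosityCurve([1, 10], [4.4, 2.2], plasma_viscosity_cp=2.2)
        np.testing.assert_allclose(c.relative_viscosities, [2.0, 1.0])
        assert ViscosityCurve([1], [1.0]).relative_viscosities is None
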