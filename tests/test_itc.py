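"""One-site ITC forward model, simulation, and parameter recovery."""

import numpy as np
import pytest

from ngpd import itc
from ngpd.itc import (
    FYLIR_PARAMS,
    InjectionHeats,
    TitrationProtocol,
    bound_fraction,
    effective_concentrations,
    fit_one_site,
    peak_noise_sd,
    predict_heats,
    simulate_titration,
    vp_itc_protocol,
)


class TestEffectiveConcentrations:
    def test_before_first_injection(self):
        p = vp_itc_protocol()
        m, x = effective_concentrations(p, 0)
        assert m == pytest.approx(30e-6)
        assert x == 0.0

    def test_asymptotic_limits(self):
        # a protocol whose cumulative volume vastly exceeds the cell volume
        p = TitrationProtocol(1.4e-3, 30e-6, 300e-6, tuple([1e-3] * 20))
        m, x = effective_concentrations(p, 20)
        assert m == pytest.approx(0.0, abs=1e-10)
        assert x == pytest.approx(300e-6, rel=1e-5)

    def test_against_discrete_stepwise_dilution_oracle(self):
        """Continuous displacement matches per-injection (1 - v/V0) products
        within 0.5% for 30 x 8 ul into 1.4 ml."""
        p = vp_itc_protocol(n_injections=30)
        v0 = p.cell_volume_l
        m_disc, x_disc = p.cell_conc_m, 0.0
        for i in range(1, 31):
            dv = p.injection_volumes_l[i - 1]
            f = 1 - dv / v0
            m_disc *= f
            x_disc = x_disc * f + p.syringe_conc_m * dv / v0
            m_cont, x_cont = effective_concentrations(p, i)
            assert m_cont == pytest.approx(m_disc, rel=5e-3)
            assert x_cont == pytest.approx(x_disc, rel=5e-3)

    def test_out_of_range_injection_rejected(self):
        with pytest.raises(ValueError):
            effective_concentrations(vp_itc_protocol(n_injections=5), 6)


class TestBoundFraction:
    def test_no_titrant_no_complex(self):
        assert bound_fraction(30e-6, 0.0, 1e-6) == 0.0

    def test_tight_binding_limit(self):
        # Kd -> 0 with X < N*M: everything injected is bound
        c = bound_fraction(30e-6, 10e-6, 1e-15)
        assert c == pytest.approx(10e-6, rel=1e-6)

    def test_bounds(self):
        c = bound_fraction(30e-6, 50e-6, 5e-6, n_sites=1.2)
        assert 0 <= c <= min(1.2 * 30e-6, 50e-6)

    def test_against_root_bracketing_oracle(self, rng):
        """Closed-form root equals a bracketing root-finder solution of the
        mass-action balance Kd*c = (N*M - c)(X - c) to 1e-10 relative."""
        from scipy.optimize import brentq

        for _ in range(200):
            m = 10 ** rng.uniform(-7, -3)
            x = 10 ** rng.uniform(-8, -3)
            kd = 10 ** rng.uniform(-9, -3)
            n = rng.uniform(0.5, 2.0)
            c = bound_fraction(m, x, kd, n)
            f = lambda cc: (n * m - cc) * (x - cc) - kd * cc
            c_oracle = brentq(f, 0.0, min(n * m, x), xtol=1e-25, rtol=1e-15)
            assert c == pytest.approx(c_oracle, rel=1e-10, abs=1e-20)


class TestPredictHeats:
    def test_zero_enthalpy_gives_flat_offset(self):
        p = vp_itc_protocol()
        heats = predict_heats(p, 1.0, 8.86e-6, 0.0, q_dil_kcal_per_mol=-0.1)
        np.testing.assert_allclose(heats.normalized_kcal_per_mol, -0.1, atol=1e-15)

    def test_heat_conservation_saturating_titration(self):
        """Sum of raw heats approaches N*M0*V0*dH for a to-saturation titration."""
        p = vp_itc_protocol(n_injections=40, syringe_um=3000.0)
        n_sites, kd, dh = 1.0, 1e-9, -10.0  # tight binding, saturates early
        heats = predict_heats(p, n_sites, kd, dh)
        total = heats.raw_heats_cal.sum()
        expected = n_sites * p.cell_conc_m * p.cell_volume_l * dh * 1e3
        assert total == pytest.approx(expected, rel=0.02)

    def test_wiseman_shape_shallow_at_low_c(self):
        """At c = 30/8.86 ~ 3.4 the isotherm is a shallow sigmoid: the maximum
        finite-difference slope magnitude stays well below the near-step slope
        of a high-c titration."""
        p = vp_itc_protocol()
        low_c = predict_heats(p, 1.0, 8.86e-6, -10.0).normalized_kcal_per_mol
        high_c = predict_heats(p, 1.0, 1e-9, -10.0).normalized_kcal_per_mol
        assert 0.1 < 30 / 8.86 / 10 < 1  # c-value ~3.4 by arithmetic
        assert np.abs(np.diff(low_c)).max() < 0.3 * np.abs(np.diff(high_c)).max()

    def test_exothermic_endothermic_antisymmetry(self):
        p = vp_itc_protocol()
        a = predict_heats(p, 1.0, 5e-6, -10.0)
        b = predict_heats(p, 1.0, 5e-6, +10.0)
        np.testing.assert_allclose(
            a.normalized_kcal_per_mol, -b.normalized_kcal_per_mol, rtol=1e-12
        )

    def test_against_independent_discrete_oracle(self, rng):
        """Discrete-dilution model heats match a from-scratch implementation
        (mass-action quadratic + stepwise dilution) within 1e-8 relative on
        random protocols."""
        for _ in range(20):
            p = vp_itc_protocol(
                n_injections=int(rng.integers(10, 30)),
                injection_ul=rng.uniform(2, 10),
                cell_um=rng.uniform(10, 100),
                syringe_um=rng.uniform(100, 1000),
            )
            n_sites = rng.uniform(0.5, 2)
            kd = 10 ** rng.uniform(-8, -4)
            dh = rng.uniform(-20, -1)
            mine = predict_heats(p, n_sites, kd, dh, dilution="discrete").raw_heats_cal
            # independent discrete-dilution forward model
            v0 = p.cell_volume_l
            m, x, q_prev = p.cell_conc_m, 0.0, 0.0
            oracle = []
            for dv in p.injection_volumes_l:
                f = 1 - dv / v0
                m *= f
                x = x * f + p.syringe_conc_m * dv / v0
                b = n_sites * m + x + kd
                c = (b - np.sqrt(b * b - 4 * n_sites * m * x)) / 2
                q = v0 * dh * 1e3 * c
                oracle.append(q - q_prev + dv / v0 * (q + q_prev) / 2)
                q_prev = q
            scale = np.abs(oracle).max()
            np.testing.assert_allclose(mine, oracle, rtol=1e-8, atol=1e-8 * scale)


class TestSimulateTitration:
    def test_zero_noise_equals_model(self):
        p = vp_itc_protocol()
        a = simulate_titration(p, **FYLIR_PARAMS, noise_sd=0.0)
        b = predict_heats(p, **FYLIR_PARAMS)
        np.testing.assert_array_equal(a.normalized_kcal_per_mol, b.normalized_kcal_per_mol)

    def test_seed_determinism(self):
        p = vp_itc_protocol()
        a = simulate_titration(p, **FYLIR_PARAMS, noise_sd=0.05, seed=4)
        b = simulate_titration(p, **FYLIR_PARAMS, noise_sd=0.05, seed=4)
        np.testing.assert_array_equal(a.normalized_kcal_per_mol, b.normalized_kcal_per_mol)

    def test_noise_moments(self):
        """Residuals over many seeds behave like the injected Gaussian noise."""
        p = vp_itc_protocol(n_injections=10)
        clean = predict_heats(p, **FYLIR_PARAMS).normalized_kcal_per_mol
        res = []
        for s in range(1000):
            sim = simulate_titration(p, **FYLIR_PARAMS, noise_sd=0.05, seed=s)
            res.extend(sim.normalized_kcal_per_mol - clean)
        res = np.asarray(res)
        assert res.mean() == pytest.approx(0.0, abs=3 * 0.05 / np.sqrt(res.size))
        assert res.std() == pytest.approx(0.05, rel=0.05)
        assert abs((res**3).mean() / 0.05**3) < 0.15  # skewness ~ 0

    def test_csv_round_trip(self, tmp_path):
        p = vp_itc_protocol(n_injections=12)
        sim = simulate_titration(p, **FYLIR_PARAMS, noise_sd=0.02, seed=1)
        sim.to_csv(tmp_path / "h.csv")
        back = InjectionHeats.from_csv(tmp_path / "h.csv", 1.4, 30.0, 300.0)
        np.testing.assert_allclose(back.normalized_kcal_per_mol, sim.normalized_kcal_per_mol)
        np.testing.assert_allclose(back.raw_heats_cal, sim.raw_heats_cal, rtol=1e-9)


class TestFitOneSite:
    def test_noise_free_self_consistency(self):
        """Noise-free simulated data: all parameters recovered within 0.1%."""
        p = vp_itc_protocol()
        truth = dict(n_sites=1.0, kd=8.86e-6, dh_kcal_per_mol=-10.0,
                     q_dil_kcal_per_mol=-0.05)
        heats = predict_heats(p, **truth)
        fit = fit_one_site(heats)
        assert fit.n_sites == pytest.approx(1.0, rel=1e-3)
        assert fit.kd_m == pytest.approx(8.86e-6, rel=1e-3)
        assert fit.dh_kcal_per_mol == pytest.approx(-10.0, rel=1e-3)
        assert fit.q_dil_kcal_per_mol == pytest.approx(-0.05, rel=1e-3)
        assert fit.converged

    def test_parameter_recovery_under_noise(self):
        """2% peak-scale noise at the c ~ 3.4 design: the K_D estimator is
        essentially unbiased (median within the published uncertainty), its
        spread is consistent with the asymptotic standard error, and dH is
        recovered to a few percent."""
        p = vp_itc_protocol()
        sd = peak_noise_sd(p, **FYLIR_PARAMS, frac=0.02)
        kd_hat, kd_err, dh_hat, dh_err, kd_se, dh_se = [], [], [], [], [], []
        for s in range(50):
            sim = simulate_titration(p, **FYLIR_PARAMS, noise_sd=sd, seed=s)
            fit = fit_one_site(sim)
            kd_hat.append(fit.kd_m)
            kd_err.append(abs(fit.kd_m - FYLIR_PARAMS["kd"]) / FYLIR_PARAMS["kd"])
            dh_hat.append(fit.dh_kcal_per_mol)
            dh_err.append(abs(fit.dh_kcal_per_mol + 10.0) / 10.0)
            kd_se.append(fit.kd_se_m)
            dh_se.append(fit.dh_se)
        # unbiasedness: the median estimates sit on the generating values
        assert abs(np.median(kd_hat) - 8.86e-6) < 1.13e-6  # published uncertainty
        assert abs(np.median(dh_hat) + 10.0) / 10.0 < 0.05
        # the sampling spread should track the Jacobian-based error estimates:
        # at c ~ 3.4 the information limit puts the relative K_D SE around
        # 20-25% and the dH SE near 8%, and the observed median errors cannot
        # be far above them
        assert np.median(kd_err) < 1.5 * np.median(kd_se) / FYLIR_PARAMS["kd"]
        assert np.median(kd_err) < 0.30
        assert np.median(dh_err) < 1.5 * np.median(dh_se) / 10.0
        assert np.median(dh_err) < 0.12

    def test_flat_heats_flag_unidentifiable_kd(self):
        p = vp_itc_protocol()
        heats = predict_heats(p, 1.0, 8.86e-6, 0.0, q_dil_kcal_per_mol=-0.02)
        fit = fit_one_site(heats, allow_extreme_c=True)
        assert not fit.kd_identifiable

    def test_extreme_c_withholds_kd_error_bar(self):
        p = vp_itc_protocol()
        heats = predict_heats(p, 1.0, 1e-9, -10.0)  # c = 30000
        with pytest.warns(UserWarning, match="c-value"):
            fit = fit_one_site(heats)
        assert np.isnan(fit.kd_se_m)

    def test_fixed_stoichiometry_option(self):
        p = vp_itc_protocol()
        heats = predict_heats(p, 1.0, 8.86e-6, -10.0)
        fit = fit_one_site(heats, float_n=False)
        assert fit.n_sites == 1.0 and fit.n_sites_se == 0.0
        assert fit.kd_m == pytest.approx(8.86e-6, rel=1e-3)

    def test_too_few_injections_rejected(self):
        p = vp_itc_protocol(n_injections=6)
        heats = predict_heats(p, 1.0, 8.86e-6, -10.0)
        with pytest.raises(ValueError, match="at least 6"):
            fit_one_site(heats)  # 6 minus the excluded first = 5 usable
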