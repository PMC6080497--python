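import numpy as np
import pytest

import canemetrics as cm
from canemetrics.errors import DomainError, InputError
from canemetrics.synthetic import homogeneous, zero_noise
from canemetrics.uncertainty import (
    build_precision_table,
    propagate_bmc,
    propagate_tch,
    replicate_sd,
    sigma_rho_s,
    total_precision_at_location,
)


class TestReplicateSd:
    def test_constant_replicates_have_zero_spread(self):
        assert replicate_sd([2, 2, 2, 2, 2]) == 0.0

    def test_hand_value(self):
        assert replicate_sd([1, 2, 3, 4, 5]) == pytest.approx(1.5811, abs=5e-5)

    def test_small_sample_bias_documented(self):
        """With 5 replicates the n-1 s.d. underestimates sigma by ~6% (c4)."""
        rng = np.random.default_rng(0)
        draws = rng.normal(1.0, 0.2, size=(10_000, 5))
        est = np.mean([replicate_sd(row) for row in draws])
        assert est == pytest.approx(0.188, rel=0.02)

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            replicate_sd([1.0])


class TestSigmaRhoS:
    def test_hand_value(self):
        s = sigma_rho_s(1000.0, 0.10, sigma_D=0.05 * 0.03, D=0.03,
                        sigma_H=0.05 * 3.0, H=3.0)
        assert s == pytest.approx(150.0, abs=0.01)

    def test_zero_sigmas(self):
        assert sigma_rho_s(1000.0, 0.0, 0.0, 0.03, 0.0, 3.0) == 0.0

    def test_homogeneity(self):
        a = sigma_rho_s(1000.0, 0.05, 0.001, 0.03, 0.1, 3.0)
        b = sigma_rho_s(1000.0, 0.10, 0.002, 0.03, 0.2, 3.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_dimensions_rejected(self):
        with pytest.raises(DomainError):
            sigma_rho_s(1000.0, 0.1, 0.001, 0.0, 0.1, 3.0)


REF = dict(D=0.03, H=3.0, rho_S=1100.0)
BMS0 = np.pi * 0.03**2 / 4 * 3.0 * 1100.0 * 0.977


class TestPropagateBmc:
    def test_printed_form_hand_values(self):
        """The typeset (theta+chi) composition reproduces the hand example."""
        sigma, terms = propagate_bmc(
            0.03, 3.0, 1100.0, 2.0,
            sigma_D=0.05 * 0.03, sigma_H=0.05 * 3.0, sigma_rho=0.05 * 1100.0,
            sigma_BML=0.05, second_order="additive",
        )
        assert terms.theta == pytest.approx(0.12247, abs=5e-6)
        assert terms.chi == pytest.approx(0.00791, abs=5e-6)
        assert sigma == pytest.approx(0.2655, abs=5e-5)

    def test_zero_sigmas_give_zero(self):
        sigma, _ = propagate_bmc(**REF, BM_S=2.0, sigma_D=0, sigma_H=0,
                                 sigma_rho=0, sigma_BML=0)
        assert sigma == 0.0

    def test_leaf_only_limit(self):
        sigma, _ = propagate_bmc(**REF, BM_S=2.0, sigma_D=0, sigma_H=0,
                                 sigma_rho=0, sigma_BML=0.05)
        assert sigma == pytest.approx(0.05, rel=1e-12)

    def test_first_order_homogeneity(self):
        kw = dict(sigma_D=0.001, sigma_H=0.1, sigma_rho=50.0, sigma_BML=0.02)
        a, _ = propagate_bmc(**REF, BM_S=2.0, second_order="none", **kw)
        b, _ = propagate_bmc(**REF, BM_S=2.0, second_order="none",
                             **{k: 3 * v for k, v in kw.items()})
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_second_order_vanishes_faster(self):
        ratios = []
        for cv in (0.10, 0.01, 0.001):
            _, terms = propagate_bmc(
                **REF, BM_S=2.0,
                sigma_D=cv * 0.03, sigma_H=cv * 3.0, sigma_rho=cv * 1100.0,
                sigma_BML=0.0,
            )
            ratios.append(terms.chi / (terms.theta + terms.chi))
        # the ratio shrinks roughly linearly with the CV scale
        assert ratios[1] < 0.2 * ratios[0]
        assert ratios[2] < 0.2 * ratios[1]

    def test_default_mode_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(12)
        n = 200_000
        cv = 0.08
        D = 0.03 * (1 + cv * rng.standard_normal(n))
        H = 3.0 * (1 + cv * rng.standard_normal(n))
        r = 1100.0 * (1 + cv * rng.standard_normal(n))
        L = 0.2 + 0.02 * rng.standard_normal(n)
        mc = (np.pi * D**2 / 4 * H * r * 0.977 + L).std(ddof=1)
        sigma, _ = propagate_bmc(**REF, BM_S=BMS0,
                                 sigma_D=cv * 0.03, sigma_H=cv * 3.0,
                                 sigma_rho=cv * 1100.0, sigma_BML=0.02)
        assert sigma == pytest.approx(mc, rel=0.02)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            propagate_bmc(0.0, 3.0, 1100.0, 2.0, 0, 0, 0, 0)


class TestPropagateTch:
    def test_printed_form_hand_values(self):
        sigma, terms = propagate_tch(
            0.03, 3.0, 1100.0, 2.0, 0.1, 8.0,
            sigma_D=0.05 * 0.03, sigma_H=0.05 * 3.0, sigma_rho=0.05 * 1100.0,
            sigma_BML=0.05, sigma_C=0.10 * 8.0, S=1.2,
            second_order="additive", density_covariance=False,
        )
        assert terms["tsh"] == pytest.approx(133.33, abs=0.005)
        assert terms["tlh"] == pytest.approx(6.667, abs=0.0005)
        assert terms["TSH"].theta == pytest.approx(0.15811, abs=5e-6)
        assert terms["TLH"].theta == pytest.approx(0.50990, abs=5e-6)
        assert sigma == pytest.approx(23.3, abs=0.05)

    def test_zero_sigmas_give_zero(self):
        sigma, _ = propagate_tch(0.03, 3.0, 1100.0, 2.0, 0.1, 8.0,
                                 0, 0, 0, 0, 0)
        assert sigma == 0.0

    def test_density_covariance_improves_monte_carlo_match(self):
        rng = np.random.default_rng(4)
        n = 300_000
        D = 0.03 * (1 + 0.02 * rng.standard_normal(n))
        H = 3.0 * (1 + 0.02 * rng.standard_normal(n))
        r = 1100.0 * (1 + 0.02 * rng.standard_normal(n))
        C = 10.0 * (1 + 0.10 * rng.standard_normal(n))
        L = 0.2 * (1 + 0.10 * rng.standard_normal(n))
        mc = ((np.pi * D**2 / 4 * H * r * 0.977 + L) * C * 10 / 1.2).std(ddof=1)
        kw = dict(sigma_D=0.02 * 0.03, sigma_H=0.02 * 3.0,
                  sigma_rho=0.02 * 1100.0, sigma_BML=0.02, sigma_C=1.0, S=1.2)
        with_cov, _ = propagate_tch(0.03, 3.0, 1100.0, BMS0, 0.2, 10.0, **kw)
        without, _ = propagate_tch(0.03, 3.0, 1100.0, BMS0, 0.2, 10.0,
                                   density_covariance=False, **kw)
        assert abs(with_cov - mc) < abs(without - mc)
        assert with_cov == pytest.approx(mc, rel=0.02)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            propagate_tch(0.03, 3.0, 1100.0, 2.0, 0.1, 0.0, 0, 0, 0, 0, 0)


class TestTotalPrecisionAtLocation:
    def test_identity_with_substituted_sigmas(self):
        args = (0.03, 3.0, 1100.0, 2.0)
        a, _ = total_precision_at_location(*args, 0.002, 0.2, 65.0, 0.058)
        b, _ = propagate_bmc(*args, sigma_D=0.002, sigma_H=0.2,
                             sigma_rho=65.0, sigma_BML=0.058)
        assert a == b

    def test_zero_fitting_reduces_to_geometry_only(self):
        args = (0.03, 3.0, 1100.0, 2.0)
        a, _ = total_precision_at_location(*args, 0.002, 0.2, 0.0, 0.0)
        b, _ = propagate_bmc(*args, sigma_D=0.002, sigma_H=0.2,
                             sigma_rho=0.0, sigma_BML=0.0)
        assert a == b


class TestPrecisionTable:
    def test_fitting_sigma_equals_trend_rmse(self, default_campaign,
                                             default_fits, default_precision):
        pt = default_precision
        for stage in ("early", "mid", "late"):
            assert pt.sigma("rho_S", stage, "fitting") == default_fits.rho_trend.rmse
            assert pt.sigma("BM_L", stage, "fitting") == default_fits.bml_trend.rmse

    def test_instrument_within_idealization_for_measured_params(
            self, default_precision):
        """Generator nests the tiers, so instrument <= idealization should
        hold for the directly measured biometrics up to sampling noise."""
        ok = bad = 0
        for param in ("D", "H", "C_row", "LAI_eff"):
            for stage in ("early", "mid", "late"):
                si = default_precision.sigma(param, stage, "instrument")
                sd = default_precision.sigma(param, stage, "idealization")
                if np.isfinite(si) and np.isfinite(sd):
                    ok += si <= sd * 1.25
                    bad += si > sd * 1.25
        assert ok >= 10 and bad <= 2

    def test_at_location_between_fitting_and_idealization(self, default_precision):
        """At mid/late stage the fit-based tier mix lies between the pure
        fitting and pure idealization rows."""
        for stage in ("mid", "late"):
            fit_row = default_precision.relative_value("BM_C", "fitting", stage)
            ideal = default_precision.relative_value("BM_C", "idealization", stage)
            loc = default_precision.relative_value("BM_C", "total_at_location", stage)
            assert fit_row < loc < ideal

    def test_sigma_recovery_with_many_replicates(self):
        """Recovered absolute sigmas match the generating sigmas when the
        replicate count makes the sampling error small."""
        cfg = cm.default_truth_config(seed=9)
        cfg.intensive_reps = 40
        camp = cm.simulate_campaign(cfg)
        fits = cm.fit_campaign(camp)
        pt = build_precision_table(camp, fits)
        for param in ("H", "C_row"):
            for tier in ("instrument", "idealization"):
                for stage in ("early", "mid", "late"):
                    got = pt.sigma(param, stage, tier)
                    want = cfg.sigma(param, tier, stage)
                    assert got == pytest.approx(want, rel=0.20), (param, tier, stage)

    def test_zero_noise_campaign_has_zero_sigmas(self):
        cfg = zero_noise(homogeneous(cm.default_truth_config(seed=2)))
        camp = cm.simulate_campaign(cfg)
        fits = cm.fit_campaign(camp, force_origin=False)
        pt = build_precision_table(camp, fits)
        assert np.nanmax(np.abs(pt.entries.sigma.to_numpy())) < 1e-6

    def test_missing_tier_reported_absent_not_zero(self, default_fits,
                                                   default_campaign):
        cfg, _ = default_campaign
        import copy

        cfg2 = copy.deepcopy(cfg)
        cfg2.include_intensive = False
        camp2 = cm.simulate_campaign(cfg2)
        fits2 = cm.fit_campaign(camp2)
        pt = build_precision_table(camp2, fits2)
        assert np.isnan(pt.sigma("H", "mid", "instrument"))
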