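import copy

import numpy as np
import pandas as pd
import pytest

from canemetrics.allometry import cane_biomass
from canemetrics.errors import DomainError
from canemetrics.growth import logistic
from canemetrics.synthetic import (
    EsuTruth,
    LogisticTruth,
    default_truth_config,
    homogeneous,
    invert_biometrics,
    simulate_campaign,
    true_curves,
    zero_noise,
)


class TestTrueCurves:
    def test_sigmoid_midpoint_and_asymptote(self):
        assert logistic(150.0, 2.5, 0.03, 150.0) == pytest.approx(1.25)
        assert logistic(1e6, 2.5, 0.03, 150.0) == pytest.approx(2.5, abs=1e-9)

    def test_tch_is_pointwise_product(self):
        cfg = default_truth_config()
        curves = true_curves(cfg, np.arange(0, 341, 10))
        f = cfg.fields[0]
        e = f.esus[1]
        tch = curves["tch"]
        sel = tch[tch.unit_id == e.unit_id]
        t = sel.t.to_numpy()
        expected = f.biomass(t) * e.density(t) * 10.0 / cfg.row_spacing
        np.testing.assert_allclose(sel.TCH.to_numpy(), expected, rtol=1e-12)

    def test_hand_arithmetic_tch_value(self):
        cfg = default_truth_config()
        cfg.fields = cfg.fields[:1]
        cfg.fields[0].biomass = LogisticTruth(2.379 * 2, 0.03, 150.0)
        cfg.fields[0].esus = [EsuTruth("U", LogisticTruth(8.0 * 2, 0.03, 150.0))]
        # at the shared midpoint both curves are at half their asymptote
        curves = true_curves(cfg, [150.0])
        assert curves["tch"].TCH.iloc[0] == pytest.approx(2.379 * 8 * 10 / 1.2,
                                                          abs=0.05)

    def test_out_of_domain_rejected(self):
        cfg = default_truth_config()
        with pytest.raises(DomainError):
            true_curves(cfg, [cfg.max_t() + 1])
        with pytest.raises(DomainError):
            true_curves(cfg, [-1.0])


class TestSimulateCampaign:
    def test_fixed_seed_is_deterministic(self):
        a = simulate_campaign(default_truth_config(seed=42))
        b = simulate_campaign(default_truth_config(seed=42))
        pd.testing.assert_frame_equal(a.biometrics_frame(), b.biometrics_frame())
        pd.testing.assert_frame_equal(a.biomass_frame(), b.biomass_frame())

    def test_different_seeds_differ(self):
        a = simulate_campaign(default_truth_config(seed=1))
        b = simulate_campaign(default_truth_config(seed=2))
        assert not a.biometrics_frame().equals(b.biometrics_frame())

    def test_adding_a_unit_leaves_other_units_unchanged(self):
        cfg = default_truth_config(seed=3)
        camp_a = simulate_campaign(cfg)
        cfg2 = copy.deepcopy(cfg)
        cfg2.fields[0].esus.append(
            EsuTruth("F1-EX", LogisticTruth(14.0, -0.009, 450.0)))
        camp_b = simulate_campaign(cfg2)
        fa = camp_a.biometrics_frame()
        fb = camp_b.biometrics_frame()
        fb = fb[fb.unit_id != "F1-EX"].reset_index(drop=True)
        pd.testing.assert_frame_equal(fa, fb)

    def test_zero_noise_records_lie_on_truth(self):
        """Estimating biomass from noise-free biometrics reproduces the
        configured biomass curve exactly (allometric self-consistency)."""
        cfg = zero_noise(default_truth_config(seed=0))
        camp = simulate_campaign(cfg)
        bio = camp.biometrics_frame()
        bio = bio[bio.tier.isna() & (bio.unit_kind != "INTENSIVE")]
        for f in cfg.fields:
            sub = bio[bio.field_id == f.field_id]
            for t, grp in sub.groupby("t"):
                est = cane_biomass(grp.D.iloc[0], grp.H.iloc[0],
                                   float(cfg.rho(t)), cfg.taper,
                                   float(cfg.bml(t)))
                assert est.BM_C == pytest.approx(f.biomass(t), rel=1e-9)

    def test_zero_noise_density_and_masses_exact(self):
        cfg = zero_noise(default_truth_config(seed=0))
        camp = simulate_campaign(cfg)
        dens = {f.field_id: {e.unit_id: e.density for e in f.esus}
                for f in cfg.fields}
        bio = camp.biometrics_frame()
        bio = bio[bio.tier.isna() & (bio.unit_kind != "INTENSIVE")]
        for rec in bio.itertuples():
            assert rec.C_row == pytest.approx(
                dens[rec.field_id][rec.unit_id](rec.t), rel=1e-12)
        bm = camp.biomass_frame()
        truth = {f.field_id: f.biomass for f in cfg.fields}
        for rec in bm[bm.tier.isna()].itertuples():
            assert rec.cane_mass == pytest.approx(
                truth[rec.field_id](rec.t), rel=1e-12)

    def test_noise_sigma_statistically_recovered(self):
        """Sample s.d. of stalk-height residuals matches the configured
        mid-stage idealization sigma (0.329 m) at large replicate counts."""
        cfg = default_truth_config(seed=6)
        cfg.fields = cfg.fields[:1]
        cfg.fields[0].esus = cfg.fields[0].esus[:1]
        cfg.fields[0].esus[0].is_esub = False
        cfg.schedule = list(range(150, 300))  # mid-stage days only
        cfg.replicates = 8
        cfg.include_intensive = False
        cfg.include_transect = False
        camp = simulate_campaign(cfg)
        bio = camp.biometrics_frame()
        f = cfg.fields[0]
        resid = [rec.H - invert_biometrics(cfg, f, rec.t)[1]
                 for rec in bio.itertuples()]
        assert len(resid) == 150 * 8
        assert np.std(resid, ddof=1) == pytest.approx(0.329, rel=0.05)

    def test_truncation_keeps_quantities_physical(self):
        cfg = default_truth_config(seed=8)
        cfg.sigmas["C_row"]["idealization"] = {s: 15.0 for s in
                                               ("early", "mid", "late")}
        camp = simulate_campaign(cfg)
        bio = camp.biometrics_frame()
        assert (bio.C_row.dropna() >= 0).all()

    def test_default_shape_matches_campaign_design(self):
        cfg = default_truth_config()
        assert len(cfg.fields) == 4
        for f in cfg.fields:
            assert 3 <= len(f.esus) <= 5
            assert 1 <= sum(e.is_esub for e in f.esus) <= 2
        # published sigma defaults are wired in (stalk height ideal mid 32.9 cm)
        assert cfg.sigma("H", "idealization", "mid") == 0.329
        assert cfg.sigma("C_row", "idealization", "early") == 6.3

    def test_homogeneous_helper_unifies_truths(self):
        cfg = homogeneous(default_truth_config())
        dys = {f.biomass.delta_y for f in cfg.fields}
        assert len(dys) == 1
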