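"""End-to-end campaign processing presets.

Wires the modules into the campaign's standard analysis chain:

1. fit the stalk-density line and leaf-biomass polynomial at the ESUBs,
2. estimate per-visit cane biomass at every unit from mean biometrics via
   the allometric relation (plus the directly weighed values at ESUBs),
3. fit the general (pooled) logistic for cane biomass and cane density,
   then re-fit per field (biomass) and per ESU (density) inside the
   widened general confidence bounds,
4. build the precision table from the replicate blocks and fit RMSEs,
5. form perturbed TCH profiles with one-s.d. bands per ESU,
6. compose intensive-transect TCH values for the variogram.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import allometry
from .errors import InputError
from .growth import (
    LogisticParams, TrendFit, fit_logistic, fit_trend, growth_stage,
    refit_constrained,
)
from .io import CampaignTable
from .perturbation import PerturbEnsemble, TCHProfile, perturb_and_refit, tch_profile
from .uncertainty import PrecisionTable, build_precision_table

__all__ = [
    "CampaignFits", "estimate_unit_biomass", "fit_campaign",
    "tch_profiles", "intensive_transect_tch",
]


@dataclass
class CampaignFits:
    """All fitted interpolators of one campaign."""

    rho_trend: TrendFit
    bml_trend: TrendFit
    general_biomass: LogisticParams
    field_biomass: dict[str, LogisticParams]
    general_density: LogisticParams
    esu_density: dict[str, LogisticParams]
    biomass_points: pd.DataFrame  # field_id, unit_id, t, BM_C, source
    density_points: pd.DataFrame  # field_id, unit_id, t, C
    lai_trend: TrendFit | None = None
    taper: float = allometry.DEFAULT_TAPER_FACTOR
    row_spacing: float = allometry.DEFAULT_ROW_SPACING


def _ordinary_biometrics(campaign: CampaignTable) -> pd.DataFrame:
    bio = campaign.biometrics_frame()
    if bio.empty:
        return bio
    return bio[bio.tier.isna() & (bio.unit_kind != "INTENSIVE")]


def estimate_unit_biomass(
    campaign: CampaignTable,
    rho_trend: TrendFit,
    bml_trend: TrendFit,
    F: float = allometry.DEFAULT_TAPER_FACTOR,
) -> pd.DataFrame:
    """Per-visit cane-biomass estimates from unit-mean biometrics.

    D and H are averaged over the corner replicates of each (unit, day)
    visit, then pushed through the allometric relation with the fitted
    stalk-density and leaf-biomass trends evaluated at that day.
    """
    bio = _ordinary_biometrics(campaign)
    rows = []
    for (fid, uid, t), grp in bio.groupby(["field_id", "unit_id", "t"]):
        D = grp.D.dropna().mean()
        H = grp.H.dropna().mean()
        if not (np.isfinite(D) and np.isfinite(H)):
            continue
        est = allometry.cane_biomass(
            D, H, float(rho_trend(float(t))), F, float(bml_trend(float(t)))
        )
        rows.append({
            "field_id": fid, "unit_id": uid, "t": int(t),
            "BM_C": est.BM_C, "BM_S": est.BM_S, "source": "estimated",
        })
    return pd.DataFrame(
        rows, columns=["field_id", "unit_id", "t", "BM_C", "BM_S", "source"]
    )


def _measured_unit_biomass(campaign: CampaignTable) -> pd.DataFrame:
    bm = campaign.biomass_frame()
    rows = []
    if not bm.empty:
        for (fid, uid, t), grp in bm[bm.tier.isna()].groupby(
            ["field_id", "unit_id", "t"]
        ):
            masses = grp.cane_mass.dropna()
            if len(masses):
                rows.append({
                    "field_id": fid, "unit_id": uid, "t": int(t),
                    "BM_C": float(masses.mean()), "BM_S": float("nan"),
                    "source": "measured",
                })
    return pd.DataFrame(
        rows, columns=["field_id", "unit_id", "t", "BM_C", "BM_S", "source"]
    )


def fit_campaign(
    campaign: CampaignTable,
    F: float = allometry.DEFAULT_TAPER_FACTOR,
    S: float = allometry.DEFAULT_ROW_SPACING,
    force_origin: bool = True,
    origin_weight: float = 1.0,
    expansion: float = 0.10,
    expansion_mode: str = "halfwidth",
    bml_through_origin: bool = True,
) -> CampaignFits:
    """Fit the full interpolator hierarchy of a campaign.

    ``force_origin``/``origin_weight`` control the origin pseudo-observation
    of the *biomass* logistic fits (growth starts from zero); density fits
    are never origin-forced (the stand starts the season densely tillered).
    """
    bm = campaign.biomass_frame()
    bm = bm[bm.tier.isna()] if not bm.empty else bm
    if bm.empty:
        raise InputError("campaign has no destructive biomass records to fit trends")
    rho_obs = bm.dropna(subset=["rho_S"])
    rho_trend = fit_trend(rho_obs.t.to_numpy(float), rho_obs.rho_S.to_numpy(float),
                          "linear")
    bml_obs = bm.dropna(subset=["BM_L"])
    bml_kind = "poly2_through_origin" if bml_through_origin else "linear"
    bml_trend = fit_trend(bml_obs.t.to_numpy(float), bml_obs.BM_L.to_numpy(float),
                          bml_kind)

    estimated = estimate_unit_biomass(campaign, rho_trend, bml_trend, F)
    measured = _measured_unit_biomass(campaign)
    biomass_points = pd.concat([estimated, measured], ignore_index=True)
    if biomass_points.empty:
        raise InputError("no biomass observations to fit")

    general_biomass = fit_logistic(
        biomass_points.t.to_numpy(float), biomass_points.BM_C.to_numpy(float),
        force_origin=force_origin, origin_weight=origin_weight,
    )
    field_biomass = {}
    for fid, grp in biomass_points.groupby("field_id"):
        field_biomass[fid] = refit_constrained(
            general_biomass, grp.t.to_numpy(float), grp.BM_C.to_numpy(float),
            expansion=expansion, expansion_mode=expansion_mode,
            force_origin=force_origin, origin_weight=origin_weight,
        )

    bio = _ordinary_biometrics(campaign)
    dens_rows = []
    for (fid, uid, t), grp in bio.groupby(["field_id", "unit_id", "t"]):
        c = grp.C_row.dropna()
        if len(c):
            dens_rows.append({"field_id": fid, "unit_id": uid,
                              "t": int(t), "C": float(c.mean())})
    density_points = pd.DataFrame(dens_rows,
                                  columns=["field_id", "unit_id", "t", "C"])
    general_density = fit_logistic(
        density_points.t.to_numpy(float), density_points.C.to_numpy(float),
        force_origin=False,
    )
    esu_density = {}
    for uid, grp in density_points.groupby("unit_id"):
        esu_density[uid] = refit_constrained(
            general_density, grp.t.to_numpy(float), grp.C.to_numpy(float),
            expansion=expansion, expansion_mode=expansion_mode,
        )

    lai = bio.dropna(subset=["LAI_eff"])
    lai_trend = None
    if len(lai) >= 2:
        lai_trend = fit_trend(lai.t.to_numpy(float), lai.LAI_eff.to_numpy(float),
                              "poly2_through_origin")

    return CampaignFits(
        rho_trend=rho_trend, bml_trend=bml_trend,
        general_biomass=general_biomass, field_biomass=field_biomass,
        general_density=general_density, esu_density=esu_density,
        biomass_points=biomass_points, density_points=density_points,
        lai_trend=lai_trend, taper=F, row_spacing=S,
    )


def _stage_sigmas(precision: PrecisionTable, quantity: str, t_values) -> np.ndarray:
    return np.array([
        precision.sigma_at_location(quantity, growth_stage(int(t)))
        for t in t_values
    ])


def tch_profiles(
    campaign: CampaignTable,
    fits: CampaignFits,
    precision: PrecisionTable | None = None,
    n_biomass: int = 100,
    n_density: int = 100,
    seed: int = 0,
    force_origin: bool = True,
    origin_weight: float = 1.0,
    expansion: float = 0.10,
) -> dict[str, TCHProfile]:
    """Perturbed TCH profile with a one-s.d. band for every ESU.

    Biomass observations are perturbed at each field with the per-stage
    total-at-location cane-biomass sigma, density observations at each ESU
    with the total-at-location density sigma; each perturbed series is
    re-fitted inside the general bounds and every biomass curve is paired
    with every density curve of its field's ESUs.
    """
    if precision is None:
        precision = build_precision_table(campaign, fits, F=fits.taper,
                                          S=fits.row_spacing)
    harvest = {
        f.field_id: (f.harvest - f.start_of_growth).days
        if (f.harvest and f.start_of_growth)
        else int(fits.biomass_points.t.max())
        for f in campaign.fields
    }

    bio_ens: dict[str, PerturbEnsemble] = {}
    for fid, grp in fits.biomass_points.groupby("field_id"):
        t = grp.t.to_numpy(float)
        y = grp.BM_C.to_numpy(float)
        t_grid = np.arange(0.0, float(harvest.get(fid, t.max())) + 1.0)
        bio_ens[fid] = perturb_and_refit(
            t, y, _stage_sigmas(precision, "BM_C", t), fits.general_biomass,
            n=n_biomass, seed=seed + zlib_crc(fid), t_grid=t_grid,
            force_origin=force_origin, origin_weight=origin_weight,
            expansion=expansion,
        )

    profiles: dict[str, TCHProfile] = {}
    for uid, grp in fits.density_points.groupby("unit_id"):
        fid = grp.field_id.iloc[0]
        t = grp.t.to_numpy(float)
        y = grp.C.to_numpy(float)
        dens = perturb_and_refit(
            t, y, _stage_sigmas(precision, "C", t), fits.general_density,
            n=n_density, seed=seed + zlib_crc(uid), t_grid=bio_ens[fid].t_grid,
            expansion=expansion,
        )
        profiles[uid] = tch_profile(bio_ens[fid], dens, S=fits.row_spacing,
                                    unit_id=uid)
    return profiles


def zlib_crc(name: str) -> int:
    """Stable non-negative hash for deriving per-unit seeds."""
    import zlib

    return zlib.crc32(name.encode()) & 0xFFFF


def intensive_transect_tch(
    campaign: CampaignTable,
    fits: CampaignFits,
    S: float | None = None,
) -> pd.DataFrame:
    """TCH at the intensive transect points, for the variogram.

    Biomass comes from the per-field re-fitted logistic evaluated at the
    transect date; density is the locally *measured* cane count, so the
    spatial variability of the product reflects the measured density line.
    """
    S = S if S is not None else fits.row_spacing
    bio = campaign.biometrics_frame()
    tr = bio[(bio.unit_kind == "INTENSIVE") & bio.x.notna() & bio.C_row.notna()]
    if tr.empty:
        raise InputError("campaign has no positioned intensive transect records")
    rows = []
    for _, rec in tr.iterrows():
        curve = fits.field_biomass.get(rec.field_id, fits.general_biomass)
        bm_c = float(curve(float(rec.t)))
        rows.append({
            "field_id": rec.field_id, "unit_id": rec.unit_id,
            "position": float(rec.x), "t": int(rec.t),
            "TCH": allometry.tch(bm_c, float(rec.C_row), S),
        })
    return pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
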