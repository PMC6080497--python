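"""Synthetic field-campaign generator with known ground truth.

Emulates the structure of a season-long sugarcane ground campaign so every
downstream stage (allometry, growth fitting, propagation, perturbation
bands) can be tested against a configured truth:

* per-field cane biomass BM_C(t): logistic growth toward an asymptote,
* per-ESU cane spatial density C(t): logistic with negative rate (the
  density declines over the season as weaker tillers die off),
* stalk mass density rho_S(t): linear increase (sucrose accumulation),
* leaf biomass per cane BM_L(t): second-order polynomial through the origin,
* effective LAI: polynomial through the origin plus a constant clumping
  offset.

Stalk height and diameter are *derived* from the biomass truth by inverting
the allometric relation at a configured diameter/height ratio, so a
noise-free campaign is exactly self-consistent: estimating biomass from the
simulated biometrics reproduces the configured curves.

Noise is additive Gaussian per precision tier (instrument / idealization),
with per-stage sigmas defaulting to the campaign's published intensive-
measurement values.  Draws that would be physically negative are redrawn
(truncation; the redraw count is logged because truncation slightly biases
small-mean quantities).  One master seed feeds per-unit substreams derived
from stable hashes, so adding a unit never perturbs the draws of another.
"""
from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import allometry
from .config import get_logger
from .errors import ConfigurationError, DomainError
from .growth import STAGES, growth_stage, logistic
from .io import BiomassRecord, BiometricRecord, CampaignTable, FieldInfo

logger = get_logger("canemetrics.synthetic")

#: Default per-stage absolute noise sigmas (SI units) per parameter and
#: tier, matching the published intensive-campaign precision table
#: (lengths were reported in cm, leaf masses in g).
DEFAULT_SIGMAS: dict = {
    "D": {
        "instrument": {"early": 0.002, "mid": 0.002, "late": 0.003},
        "idealization": {"early": 0.002, "mid": 0.003, "late": 0.004},
    },
    "H": {
        "instrument": {"early": 0.008, "mid": 0.102, "late": 0.118},
        "idealization": {"early": 0.056, "mid": 0.329, "late": 0.259},
    },
    "C_row": {
        "instrument": {"early": 0.8, "mid": 0.7, "late": 0.5},
        "idealization": {"early": 6.3, "mid": 4.0, "late": 2.1},
    },
    "LAI_eff": {
        "instrument": {"early": 0.2, "mid": 0.2, "late": 0.3},
        "idealization": {"early": 0.2, "mid": 0.4, "late": 0.4},
    },
    "rho_S": {
        "instrument": {"early": 73.0, "mid": 60.0, "late": 84.0},
        "idealization": {"early": 84.0, "mid": 121.0, "late": 143.0},
    },
    "BM_L": {
        "instrument": {"early": 0.0061, "mid": 0.0061, "late": 0.0061},
        "idealization": {"early": 0.0146, "mid": 0.0312, "late": 0.0153},
    },
}


@dataclass
class LogisticTruth:
    """Noise-free logistic trajectory (asymptote, rate 1/day, midpoint day)."""

    delta_y: float
    k: float
    t0: float

    def __call__(self, t):
        return logistic(t, self.delta_y, self.k, self.t0)


@dataclass
class EsuTruth:
    unit_id: str
    density: LogisticTruth  # cane spatial density, canes per row-metre
    is_esub: bool = False


@dataclass
class FieldTruth:
    field_id: str
    biomass: LogisticTruth  # cane biomass per cane, kg
    esus: list[EsuTruth]
    harvest_t: int  # days from start of growth to harvest
    ratoon_cycle: int = 1
    area_ha: float = 50.0
    start_of_growth: date = date(2014, 10, 15)


@dataclass
class TruthConfig:
    """Full specification of a synthetic campaign."""

    fields: list[FieldTruth]
    # stalk mass density rho_S(t) = rho_intercept + rho_slope * t  [kg/m^3]
    rho_intercept: float = 850.0
    rho_slope: float = 0.7
    # leaf biomass BM_L(t) = bml_c1*t + bml_c2*t^2  [kg], through origin
    bml_c1: float = 1.5e-3
    bml_c2: float = -2.2e-6
    # actual LAI(t) = lai_c1*t + lai_c2*t^2, through origin
    lai_c1: float = 0.02
    lai_c2: float = -3.0e-5
    lai_offset: float = 0.3  # clumping offset added to effective LAI
    taper: float = allometry.DEFAULT_TAPER_FACTOR
    row_spacing: float = allometry.DEFAULT_ROW_SPACING
    dh_ratio: float = 0.010  # stalk diameter / height
    #: explicit visit days; None derives a per-field schedule of
    #: ``visits_per_field`` days evenly spaced from day 30 until shortly
    #: before that field's harvest (campaigns follow the crop to harvest)
    schedule: list[int] | None = None
    visits_per_field: int = 12
    replicates: int = 4  # corner points per ESU visit
    plants_per_esub_visit: int = 4
    sigmas: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_SIGMAS))
    # plant-to-plant relative spread of cane mass at ESUBs, per stage
    cane_mass_rel_sigma: dict = field(
        default_factory=lambda: {"early": 0.20, "mid": 0.15, "late": 0.12}
    )
    weigh_sigma: float = 0.006  # absolute repeat-weighing sigma, kg
    wet_sigma: float = 0.02  # wet-content noise, fraction
    include_intensive: bool = True
    intensive_reps: int = 5
    include_transect: bool = True
    transect_t: int = 66
    transect_rel_sigma: float = 0.15
    seed: int = 0

    # ---- truth trend evaluations -----------------------------------------
    def rho(self, t):
        return self.rho_intercept + self.rho_slope * np.asarray(t, float)

    def bml(self, t):
        t = np.asarray(t, float)
        return self.bml_c1 * t + self.bml_c2 * t**2

    def lai(self, t):
        t = np.asarray(t, float)
        return self.lai_c1 * t + self.lai_c2 * t**2

    def sigma(self, parameter: str, tier: str, stage: str) -> float:
        return float(self.sigmas[parameter][tier][stage])

    def max_t(self) -> int:
        return max(f.harvest_t for f in self.fields)

    def field_schedule(self, field_truth: FieldTruth) -> list[int]:
        if self.schedule is not None:
            return [t for t in self.schedule if t <= field_truth.harvest_t]
        days = np.linspace(30.0, field_truth.harvest_t - 5.0, self.visits_per_field)
        return sorted({int(round(d)) for d in days})

    def validate(self) -> None:
        for f in self.fields:
            if f.biomass.delta_y <= 0:
                raise ConfigurationError(f"{f.field_id}: biomass asymptote must be > 0")
        ts = np.arange(0, self.max_t() + 1)
        if np.any(self.rho(ts) <= 0):
            raise ConfigurationError("rho_S(t) must stay positive on the schedule")
        if not 0 < self.taper <= 1.05:
            raise ConfigurationError("taper factor must be in (0, 1.05]")
        for p in self.sigmas.values():
            for tier in p.values():
                if any(s < 0 for s in tier.values()):
                    raise ConfigurationError("sigmas must be non-negative")


def default_truth_config(seed: int = 0) -> TruthConfig:
    """The shipped campaign shape: 4 fields, 3-5 ESUs and 1-2 ESUBs each.

    Per-field biomass asymptotes of 2.3-2.7 kg/cane reaching ~90% by day
    ~300, cane densities declining gently from ~14 to ~10 canes per
    row-metre (the stage-mean densities implied by the published absolute
    and relative density precisions), and the default noise tiers.
    """
    def esus(fid, specs):
        out = []
        for i, (dy, k, t0, is_esub) in enumerate(specs, start=1):
            out.append(EsuTruth(
                unit_id=f"{fid}-E{i}",
                density=LogisticTruth(dy, k, t0),
                is_esub=is_esub,
            ))
        return out

    fields = [
        FieldTruth(
            "F1", LogisticTruth(2.4, 0.021, 150),
            esus("F1", [(14.0, -0.009, 455, True), (15.0, -0.008, 470, False),
                        (13.0, -0.010, 440, False), (15.8, -0.0075, 480, False)]),
            harvest_t=340, ratoon_cycle=1, area_ha=58.0,
            start_of_growth=date(2014, 10, 30),
        ),
        FieldTruth(
            "F2", LogisticTruth(2.7, 0.019, 160),
            esus("F2", [(14.3, -0.009, 460, True), (12.8, -0.010, 445, True),
                        (16.3, -0.008, 475, False), (14.0, -0.009, 455, False),
                        (13.4, -0.0095, 450, False)]),
            harvest_t=420, ratoon_cycle=1, area_ha=115.0,
            start_of_growth=date(2014, 10, 14),
        ),
        FieldTruth(
            "F3", LogisticTruth(2.3, 0.023, 145),
            esus("F3", [(13.2, -0.0095, 445, True), (15.2, -0.008, 470, False),
                        (14.2, -0.009, 458, False)]),
            harvest_t=345, ratoon_cycle=2, area_ha=25.0,
            start_of_growth=date(2014, 8, 15),
        ),
        FieldTruth(
            "F4", LogisticTruth(2.6, 0.020, 155),
            esus("F4", [(15.6, -0.0075, 478, True), (12.4, -0.0105, 435, False),
                        (14.1, -0.009, 455, False), (15.0, -0.008, 468, False)]),
            harvest_t=355, ratoon_cycle=9, area_ha=59.0,
            start_of_growth=date(2014, 8, 1),
        ),
    ]
    return TruthConfig(fields=fields, seed=seed)


def zero_noise(config: TruthConfig) -> TruthConfig:
    """Copy of ``config`` with every noise source set to zero."""
    cfg = copy.deepcopy(config)
    for p in cfg.sigmas.values():
        for tier in p.values():
            for stage in tier:
                tier[stage] = 0.0
    cfg.cane_mass_rel_sigma = {s: 0.0 for s in cfg.cane_mass_rel_sigma}
    cfg.weigh_sigma = 0.0
    cfg.wet_sigma = 0.0
    cfg.transect_rel_sigma = 0.0
    return cfg


def homogeneous(config: TruthConfig) -> TruthConfig:
    """Copy where all fields share one biomass truth and all ESUs one
    density truth (useful for exact-recovery consistency checks: a pooled
    general fit can then reproduce every unit's truth)."""
    cfg = copy.deepcopy(config)
    bio = copy.deepcopy(cfg.fields[0].biomass)
    dens = copy.deepcopy(cfg.fields[0].esus[0].density)
    for f in cfg.fields:
        f.biomass = copy.deepcopy(bio)
        for e in f.esus:
            e.density = copy.deepcopy(dens)
    return cfg


# ---------------------------------------------------------------------------
# truth evaluation


def invert_biometrics(config: TruthConfig, field_truth: FieldTruth, t):
    """Noise-free (D, H) implied by the configured biomass truth at day t."""
    bm_c = field_truth.biomass(t)
    bm_s = bm_c - config.bml(t)
    if np.any(np.asarray(bm_s) <= 0):
        raise DomainError(
            f"{field_truth.field_id}: configured BM_L exceeds BM_C at t={t}"
        )
    rho = config.rho(t)
    # BM_S = pi/4 * (r*H)^2 * H * rho * F  with r = D/H
    H = (4.0 * np.asarray(bm_s) / (
        np.pi * config.dh_ratio**2 * rho * config.taper
    )) ** (1.0 / 3.0)
    return config.dh_ratio * H, H


def true_curves(config: TruthConfig, t_grid) -> dict[str, pd.DataFrame]:
    """Exact trajectories of the configured truth on ``t_grid``.

    Returns tidy frames: ``biomass`` (per field: BM_C, BM_S, rho_S, BM_L),
    ``density`` (per ESU: C) and ``tch`` (per ESU: TCH = BM_C*C*10/S).
    """
    t_grid = np.asarray(t_grid, float)
    if np.any(t_grid < 0) or np.any(t_grid > config.max_t()):
        raise DomainError(f"t_grid must lie within [0, {config.max_t()}]")
    bio_rows, dens_rows, tch_rows = [], [], []
    for f in config.fields:
        bm_c = f.biomass(t_grid)
        bio_rows.append(pd.DataFrame({
            "field_id": f.field_id, "t": t_grid, "BM_C": bm_c,
            "BM_L": config.bml(t_grid), "BM_S": bm_c - config.bml(t_grid),
            "rho_S": config.rho(t_grid),
        }))
        for e in f.esus:
            c = e.density(t_grid)
            dens_rows.append(pd.DataFrame({
                "field_id": f.field_id, "unit_id": e.unit_id, "t": t_grid, "C": c,
            }))
            tch_rows.append(pd.DataFrame({
                "field_id": f.field_id, "unit_id": e.unit_id, "t": t_grid,
                "TCH": bm_c * c * 10.0 / config.row_spacing,
            }))
    return {
        "biomass": pd.concat(bio_rows, ignore_index=True),
        "density": pd.concat(dens_rows, ignore_index=True),
        "tch": pd.concat(tch_rows, ignore_index=True),
    }


# ---------------------------------------------------------------------------
# simulation


def _rng_for(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-unit substream: master seed + stable name hashes."""
    entropy = [seed & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


_REDRAWS = {"count": 0}


def _draw_pos(rng, mean, sigma, floor=0.0):
    """Gaussian draw redrawn while <= floor (physical non-negativity)."""
    if sigma == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sigma)
        if v > floor or mean <= floor:
            return float(max(v, floor))
        _REDRAWS["count"] += 1
    return float(max(mean, floor))  # pragma: no cover - pathological sigma


def _stage_rep_t(schedule, harvest_t, stage) -> int | None:
    """Representative scheduled day for a growth stage (nearest midpoint)."""
    from .growth import STAGE_MIDPOINTS

    days = [t for t in schedule if t <= harvest_t and growth_stage(t) == stage]
    if not days:
        return None
    mid = STAGE_MIDPOINTS[stage]
    return min(days, key=lambda t: abs(t - mid))


def simulate_campaign(config: TruthConfig) -> CampaignTable:
    """Draw one campaign realization: truth + tiered Gaussian noise.

    The same config (same seed) always yields the identical table; with all
    sigmas zero every record lies exactly on the configured truth.
    """
    config.validate()
    _REDRAWS["count"] = 0
    biometrics: list[BiometricRecord] = []
    biomass: list[BiomassRecord] = []
    infos: list[FieldInfo] = []

    for f in config.fields:
        infos.append(FieldInfo(
            field_id=f.field_id, ratoon_cycle=f.ratoon_cycle,
            area_ha=f.area_ha, start_of_growth=f.start_of_growth,
            harvest=f.start_of_growth + timedelta(days=f.harvest_t),
        ))
        schedule = config.field_schedule(f)
        for e in f.esus:
            rng = _rng_for(config.seed, f.field_id, e.unit_id)
            kind = "ESUB" if e.is_esub else "ESU"
            for t in schedule:
                stage = growth_stage(t)
                D0, H0 = invert_biometrics(config, f, t)
                C0 = e.density(t)
                lai0 = config.lai(t) + config.lai_offset
                sD = config.sigma("D", "idealization", stage)
                sH = config.sigma("H", "idealization", stage)
                sC = config.sigma("C_row", "idealization", stage)
                sL = config.sigma("LAI_eff", "idealization", stage)
                for corner in range(1, config.replicates + 1):
                    biometrics.append(BiometricRecord(
                        field_id=f.field_id, unit_id=e.unit_id, unit_kind=kind,
                        t=t, corner=corner,
                        D=_draw_pos(rng, D0, sD),
                        H=_draw_pos(rng, H0, sH),
                        C_row=_draw_pos(rng, C0, sC),
                        LAI_eff=_draw_pos(rng, lai0, sL),
                    ))
                if e.is_esub:
                    biomass.extend(
                        _esub_records(config, f, e, t, stage, rng)
                    )

        if config.include_intensive:
            biometrics.extend(_intensive_biometrics(config, f))
            biomass.extend(_intensive_weighings(config, f))
        if config.include_transect and f is config.fields[min(1, len(config.fields) - 1)]:
            biometrics.extend(_transect_records(config, f))

    if _REDRAWS["count"]:
        logger.info("truncated-redraw count: %d", _REDRAWS["count"])
    return CampaignTable(biometrics=biometrics, biomass=biomass, fields=infos)


def _esub_records(config, f, e, t, stage, rng):
    """Destructive plant samples at one ESUB visit."""
    out = []
    bm_c0 = f.biomass(t)
    bml0 = float(config.bml(t))
    rho0 = float(config.rho(t))
    rel = config.cane_mass_rel_sigma[stage]
    s_bml = config.sigma("BM_L", "idealization", stage)
    s_rho = config.sigma("rho_S", "idealization", stage)
    wet_stalk0 = 0.85 - 0.15 * t / 365.0
    wet_leaf0 = 0.80 - 0.20 * t / 365.0
    for _ in range(config.plants_per_esub_visit):
        cane_mass = _draw_pos(rng, bm_c0, rel * bm_c0)
        cpp = int(rng.integers(10, 21))
        bml = _draw_pos(rng, bml0, s_bml)
        out.append(BiomassRecord(
            field_id=f.field_id, unit_id=e.unit_id, t=t,
            plant_mass=cane_mass * cpp, canes_per_plant=cpp,
            cane_mass=cane_mass,
            BM_L=bml,
            rho_S=_draw_pos(rng, rho0, s_rho),
            wet_content_stalk=min(1.0, _draw_pos(rng, wet_stalk0, config.wet_sigma)),
            wet_content_leaf=min(1.0, _draw_pos(rng, wet_leaf0, config.wet_sigma)),
            BM_S_measured=max(cane_mass - bml, 0.0),
        ))
    return out


def _intensive_biometrics(config, f):
    """Instrument/idealization replicate blocks, one visit per stage."""
    out = []
    e = f.esus[0]
    rng = _rng_for(config.seed, f.field_id, "intensive")
    for stage in STAGES:
        t = _stage_rep_t(config.field_schedule(f), f.harvest_t, stage)
        if t is None:
            continue
        D0, H0 = invert_biometrics(config, f, t)
        C0 = e.density(t)
        lai0 = config.lai(t) + config.lai_offset
        for tier in ("instrument", "idealization"):
            for _ in range(config.intensive_reps):
                out.append(BiometricRecord(
                    field_id=f.field_id, unit_id=f"{f.field_id}-IM-{tier}",
                    unit_kind="INTENSIVE", t=t, tier=tier,
                    D=_draw_pos(rng, D0, config.sigma("D", tier, stage)),
                    H=_draw_pos(rng, H0, config.sigma("H", tier, stage)),
                    C_row=_draw_pos(rng, C0, config.sigma("C_row", tier, stage)),
                    LAI_eff=_draw_pos(rng, lai0, config.sigma("LAI_eff", tier, stage)),
                ))
    return out


def _intensive_weighings(config, f):
    """Repeated weighings of the same canes (instrument tier of mass)."""
    out = []
    rng = _rng_for(config.seed, f.field_id, "weighing")
    esub = next((e for e in f.esus if e.is_esub), None)
    if esub is None:
        return out
    for stage in STAGES:
        t = _stage_rep_t(config.field_schedule(f), f.harvest_t, stage)
        if t is None:
            continue
        bm_c0 = f.biomass(t)
        for _ in range(config.intensive_reps):
            m = _draw_pos(rng, bm_c0, config.weigh_sigma)
            out.append(BiomassRecord(
                field_id=f.field_id, unit_id=f"{f.field_id}-IM-weigh", t=t,
                cane_mass=m, tier="instrument",
            ))
    return out


def _transect_positions() -> np.ndarray:
    """Along-line sampling positions with 5/10/20 m spacing segments."""
    return np.concatenate([
        np.arange(0.0, 45.0, 5.0),       # 9 points at 5 m
        np.arange(50.0, 130.0, 10.0),    # 8 points at 10 m
        np.arange(140.0, 280.0, 20.0),   # 7 points at 20 m
    ])


def _transect_records(config, f):
    """Single-date intensive line transect (spatially independent noise)."""
    t = int(config.transect_t)
    if t > f.harvest_t:
        return []
    rng = _rng_for(config.seed, f.field_id, "transect")
    stage = growth_stage(t)
    D0, H0 = invert_biometrics(config, f, t)
    C0 = f.esus[0].density(t)
    out = []
    for pos in _transect_positions():
        out.append(BiometricRecord(
            field_id=f.field_id, unit_id=f"{f.field_id}-TR", unit_kind="INTENSIVE",
            t=t, x=float(pos), y=0.0,
            D=_draw_pos(rng, D0, config.sigma("D", "idealization", stage)),
            H=_draw_pos(rng, H0, config.sigma("H", "idealization", stage)),
            C_row=_draw_pos(rng, C0, config.transect_rel_sigma * C0),
        ))
    return out
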