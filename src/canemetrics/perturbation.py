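"""Perturbation-based uncertainty bands for the fitted growth curves.

Instead of propagating measurement sigmas analytically through the yield
equation, each observation series (per-visit means of cane biomass for a
field, of cane density for an ESU) is perturbed with independent Gaussian
noise at the total-at-location sigmas, the constrained logistic is
re-fitted, and the spread of the re-fitted curves forms the band.  The TCH
band comes from the products of every perturbed biomass curve with every
perturbed density curve (default 100 x 100 = 10,000 combinations).

Because each re-fit pools a whole season of observations under the general
fit's box constraints, the band is far narrower than the direct
delta-method propagation of the same sigmas — the central benefit of the
interpolator approach.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import allometry
from .config import get_logger
from .errors import EnsembleError, FitError, InputError
from .growth import LogisticParams, STAGE_MIDPOINTS, refit_constrained

logger = get_logger("canemetrics.perturbation")


@dataclass
class PerturbationConfig:
    n_biomass: int = 100
    n_density: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_biomass < 2 or self.n_density < 2:
            raise InputError("ensemble sizes must be >= 2")


@dataclass
class PerturbEnsemble:
    """Re-fitted parameter ensemble and its pointwise curve band."""

    t_grid: np.ndarray
    base: LogisticParams  # fit of the unperturbed observations (any callable)
    params: list  # fitted objects, one per surviving replicate
    curves: np.ndarray  # (n_survivors, len(t_grid))
    band_sd: np.ndarray  # pointwise s.d. across the ensemble
    n_failed: int = 0

    @property
    def base_curve(self) -> np.ndarray:
        return self.base(self.t_grid)


def perturb_and_refit(
    t,
    y,
    sigma,
    general: LogisticParams | None = None,
    n: int = 100,
    seed: int = 0,
    t_grid=None,
    max_failure_fraction: float = 0.20,
    fitter=None,
    **refit_kwargs,
) -> PerturbEnsemble:
    """Perturb observations n times and re-fit the constrained logistic.

    Parameters
    ----------
    t, y:
        Observation days and values (typically per-visit unit means).
    sigma:
        Gaussian perturbation s.d.; scalar or per-observation array
        (e.g. the total-at-location sigma of the observation's stage).
    general:
        Pooled fit providing the box constraints for every re-fit.
    n, seed:
        Ensemble size and RNG seed (fixed seed -> identical ensemble).
    fitter:
        Optional override ``fitter(t, y) -> curve`` returning any callable
        evaluable on ``t_grid`` (e.g. a trend fit); by default the
        constrained logistic re-fit against ``general``.

    Individual non-converged re-fits are dropped and logged; more than
    ``max_failure_fraction`` failures raises :class:`EnsembleError`.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    sigma = np.broadcast_to(np.asarray(sigma, float), y.shape)
    if np.any(sigma < 0):
        raise InputError("sigma must be non-negative")
    if t_grid is None:
        t_grid = np.arange(0.0, float(t.max()) + 1.0)
    t_grid = np.asarray(t_grid, float)

    if fitter is None:
        if general is None:
            raise InputError("either a general fit or a fitter is required")

        def fitter(tt, yy):
            return refit_constrained(general, tt, yy, **refit_kwargs)

    base = fitter(t, y)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))

    params, curves, n_failed = [], [], 0
    for _ in range(n):
        y_pert = y + rng.normal(0.0, sigma)
        try:
            p = fitter(t, y_pert)
        except FitError as exc:
            n_failed += 1
            logger.debug("replicate re-fit dropped: %s", exc)
            continue
        params.append(p)
        curves.append(p(t_grid))
    if n_failed > max_failure_fraction * n:
        raise EnsembleError(
            f"{n_failed}/{n} replicate re-fits failed",
            n_failed=n_failed, n_total=n,
        )
    if n_failed:
        logger.info("perturbation ensemble: dropped %d/%d re-fits", n_failed, n)
    curves = np.asarray(curves)
    band_sd = curves.std(axis=0, ddof=1)
    return PerturbEnsemble(
        t_grid=t_grid, base=base, params=params, curves=curves,
        band_sd=band_sd, n_failed=n_failed,
    )


@dataclass
class TCHProfile:
    """Time profile of tons cane per hectare with a one-s.d. band."""

    unit_id: str
    t_grid: np.ndarray
    mean: np.ndarray  # t/ha; product of the unperturbed fitted curves
    sd: np.ndarray  # t/ha; spread of the pairwise-product ensemble
    quantiles: dict = field(default_factory=dict)

    def stage_relative_sd(self) -> dict[str, float]:
        """sd/mean (fraction) evaluated at each stage's midpoint day."""
        from .growth import growth_stage

        out = {}
        t_max = float(self.t_grid.max())
        for stage, tm in STAGE_MIDPOINTS.items():
            if tm > t_max:
                # field harvested before the nominal midpoint: evaluate at
                # the end of its season if that day is still in this stage
                if growth_stage(t_max) != stage:
                    continue
                tm = t_max
            i = int(np.argmin(np.abs(self.t_grid - tm)))
            if self.mean[i] > 0:
                out[stage] = float(self.sd[i] / self.mean[i])
        return out


def tch_profile(
    biomass_ensemble: PerturbEnsemble,
    density_ensemble: PerturbEnsemble,
    S: float = allometry.DEFAULT_ROW_SPACING,
    unit_id: str = "",
    quantile_levels=(),
) -> TCHProfile:
    """TCH band from all pairwise biomass x density curve products.

    The mean profile is the product of the *unperturbed* fitted curves
    (x 10/S); the band is the pointwise sample s.d. over the
    ``n_biomass * n_density`` products of perturbed curves.
    """
    if not np.array_equal(biomass_ensemble.t_grid, density_ensemble.t_grid):
        raise InputError("biomass and density ensembles must share one t_grid")
    t_grid = biomass_ensemble.t_grid
    mean = biomass_ensemble.base_curve * density_ensemble.base_curve * 10.0 / S
    a = biomass_ensemble.curves  # (nb, T)
    b = density_ensemble.curves  # (nd, T)
    products = (a[:, None, :] * b[None, :, :]).reshape(-1, t_grid.size) * 10.0 / S
    sd = products.std(axis=0, ddof=1)
    quantiles = {
        q: np.quantile(products, q, axis=0) for q in quantile_levels
    }
    return TCHProfile(unit_id=unit_id, t_grid=t_grid, mean=mean, sd=sd,
                      quantiles=quantiles)
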