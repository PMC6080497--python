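"""Temporal interpolators for campaign quantities.

Cane biomass and cane spatial density follow a three-parameter logistic in
days since start of growth,

    f(t) = delta_y / (1 + exp(-k * (t - t0))),

with ``delta_y`` the asymptote, ``k`` the growth rate (1/day; negative for
quantities that decline over the season, such as cane density) and ``t0``
the sigmoid midpoint.  A *general* fit pools all units; per-field (biomass)
and per-ESU (density) curves are then *re-fitted* inside box constraints
derived from the general fit's 95% confidence intervals, so sparse local
data cannot drag a curve outside what the pooled campaign supports.

Stalk mass density follows a linear trend in time and leaf biomass per cane
a second-order polynomial through the origin; their fit RMSEs double as the
"function fitting" precision tier of the uncertainty framework.

A logistic cannot pass exactly through the origin (f(0) > 0 for any finite
parameters), so "forcing through the origin" is implemented as an appended
pseudo-observation (t=0, y=0) with configurable weight.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError, InputError

__all__ = [
    "LogisticParams", "TrendFit", "logistic", "fit_logistic",
    "refit_constrained", "fit_trend", "growth_stage", "STAGE_MIDPOINTS",
    "STAGES",
]

STAGES = ("early", "mid", "late")
#: representative day used when a per-stage summary needs a single time
STAGE_MIDPOINTS = {"early": 75.0, "mid": 225.0, "late": 350.0}


def logistic(t, delta_y, k, t0):
    """Evaluate the logistic growth curve."""
    t = np.asarray(t, float)
    out = delta_y / (1.0 + np.exp(-k * (t - t0)))
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class LogisticParams:
    """Fitted logistic coefficients with linearized 95% confidence bounds."""

    delta_y: float
    k: float
    t0: float
    ci95: tuple[tuple[float, float], ...] = field(default=())  # per-coefficient
    rmse: float = float("nan")
    n_obs: int = 0

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.delta_y, self.k, self.t0])

    def __call__(self, t):
        return logistic(t, self.delta_y, self.k, self.t0)


@dataclass
class TrendFit:
    """Ordinary least-squares trend in the monomial basis."""

    kind: str  # linear | linear_through_origin | poly2_through_origin
    coefficients: np.ndarray  # ordered from the lowest retained power upward
    rmse: float
    n_obs: int

    def __call__(self, t):
        t = np.asarray(t, float)
        basis = _trend_basis(t, self.kind)
        out = basis @ self.coefficients
        return float(out[0]) if np.ndim(t) == 0 else out


_TREND_POWERS = {
    "linear": (0, 1),
    "linear_through_origin": (1,),
    "poly2_through_origin": (1, 2),
}


def _trend_basis(t, kind):
    try:
        powers = _TREND_POWERS[kind]
    except KeyError:
        raise InputError(f"unknown trend kind {kind!r}") from None
    t = np.atleast_1d(np.asarray(t, float))
    return np.stack([t**p for p in powers], axis=-1)


def fit_trend(t, y, kind: str) -> TrendFit:
    """Least-squares trend fit; RMSE over all residuals.

    The RMSE (n denominator) is the "function fitting" precision of the
    fitted quantity.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape:
        raise InputError("t and y must have equal length")
    basis = _trend_basis(t, kind)
    n, p = basis.shape
    if n < p:
        raise InputError(f"need at least {p} observations for kind {kind!r}, got {n}")
    coef, _, rank, _ = np.linalg.lstsq(basis, y, rcond=None)
    if rank < p:
        raise FitError(f"rank-deficient design for trend kind {kind!r}")
    resid = y - basis @ coef
    return TrendFit(kind=kind, coefficients=coef,
                    rmse=float(np.sqrt(np.mean(resid**2))), n_obs=int(n))


# ---------------------------------------------------------------------------
# logistic fitting


def _initial_guess(t, y):
    ymax = float(np.max(y))
    delta_y0 = max(1.05 * ymax, 1e-8)
    # max logistic slope is delta_y*k/4; estimate the sign and scale of k
    # from a straight-line fit
    slope = np.polyfit(t, y, 1)[0] if len(t) > 1 else 0.0
    k0 = 4.0 * slope / delta_y0
    if abs(k0) < 1e-6:
        k0 = 1e-3
    # t0: time at which y is closest to half the asymptote estimate
    t0 = float(t[np.argmin(np.abs(y - delta_y0 / 2.0))])
    return np.array([delta_y0, k0, t0])


_DEFAULT_LOWER = np.array([1e-12, -5.0, -1e4])
_DEFAULT_UPPER = np.array([np.inf, 5.0, 1e4])


def fit_logistic(
    t,
    y,
    force_origin: bool = False,
    origin_weight: float = 1.0,
    bounds=None,
    p0=None,
    xtol: float = 1e-10,
    max_nfev: int = 10_000,
) -> LogisticParams:
    """Fit the logistic growth curve by trust-region nonlinear least squares.

    Parameters
    ----------
    t, y:
        Observation days (>= 0) and values; at least 4 points.
    force_origin:
        Append a pseudo-observation (t=0, y=0) with weight ``origin_weight``
        (in units of one ordinary observation; 0 disables it even when the
        flag is set).
    bounds:
        Optional per-coefficient ``(lower, upper)`` pairs for
        (delta_y, k, t0).
    p0:
        Optional starting coefficients; otherwise derived from the data.

    Returns
    -------
    LogisticParams with 95% CIs from the linearized (Jacobian) covariance
    using t-quantiles at ``n_obs - 3`` degrees of freedom, and the RMSE over
    the real observations.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape:
        raise InputError("t and y must have equal length")
    if t.size < 4:
        raise InputError(f"need at least 4 observations, got {t.size}")
    if np.any(t < 0):
        raise DomainError("observation days must be non-negative")

    lower = _DEFAULT_LOWER.copy()
    upper = _DEFAULT_UPPER.copy()
    # near-linear data push the logistic into its degenerate limit
    # (delta_y -> inf, k -> 0); cap the asymptote at a physically sensible
    # multiple of the largest observation unless the caller says otherwise
    upper[0] = 10.0 * max(float(np.max(np.abs(y))), 1e-6)
    if bounds is not None:
        for i, pair in enumerate(bounds):
            if pair is None:
                continue
            lo, hi = pair
            if lo is not None:
                lower[i] = lo
            if hi is not None:
                upper[i] = hi
        # (near-)degenerate intervals, e.g. from an exact-fit CI: open them
        # by a tiny margin so the optimizer has room
        scale = np.maximum(np.abs(lower), np.where(np.isfinite(upper), np.abs(upper), 0.0))
        eps = np.maximum(1e-8 * scale, 1e-12)
        bad = (upper - lower) < eps
        lower[bad] -= eps[bad]
        upper[bad] += eps[bad]

    x0 = np.asarray(p0, float) if p0 is not None else _initial_guess(t, y)
    x0 = np.clip(x0, lower, upper)

    w_origin = np.sqrt(origin_weight) if (force_origin and origin_weight > 0) else 0.0

    def residuals(params):
        r = logistic(t, *params) - y
        if w_origin:
            r = np.append(r, w_origin * logistic(0.0, *params))
        return r

    try:
        res = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf",
            xtol=xtol, ftol=xtol, gtol=None, max_nfev=max_nfev,
        )
    except Exception as exc:  # scipy raises on e.g. NaN residuals
        raise FitError(f"logistic fit raised: {exc}", {"x0": x0}) from exc
    if not res.success:
        raise FitError(
            f"logistic fit did not converge: {res.message}",
            {"x0": x0, "status": res.status, "nfev": res.nfev},
        )

    params = res.x
    n = t.size
    dof = max(n - 3, 1)
    resid_real = logistic(t, *params) - y
    rmse = float(np.sqrt(np.mean(resid_real**2)))
    # linearized covariance from the optimizer's Jacobian
    J = res.jac
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)
    tq = stats.t.ppf(0.975, dof)
    ci = tuple((float(p - tq * s), float(p + tq * s)) for p, s in zip(params, se))
    return LogisticParams(
        delta_y=float(params[0]), k=float(params[1]), t0=float(params[2]),
        ci95=ci, rmse=rmse, n_obs=int(n),
    )


def widen_ci(ci95, expansion: float = 0.10, mode: str = "halfwidth"):
    """Widen per-coefficient confidence intervals into refit box bounds.

    ``halfwidth`` moves each endpoint outward by ``expansion`` times the
    interval half-width (symmetric widening); ``relative`` moves each
    endpoint outward by ``expansion`` times its own magnitude.
    """
    widened = []
    for lo, hi in ci95:
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise InputError("confidence bounds must be finite to derive refit bounds")
        if mode == "halfwidth":
            pad = expansion * (hi - lo) / 2.0
            widened.append((lo - pad, hi + pad))
        elif mode == "relative":
            widened.append((lo - expansion * abs(lo), hi + expansion * abs(hi)))
        else:
            raise InputError(f"unknown expansion mode {mode!r}")
    return tuple(widened)


def refit_constrained(
    general: LogisticParams,
    t,
    y,
    expansion: float = 0.10,
    expansion_mode: str = "halfwidth",
    force_origin: bool = False,
    origin_weight: float = 1.0,
    **fit_kwargs,
) -> LogisticParams:
    """Re-fit a logistic for one field/ESU inside the general fit's bounds.

    The general coefficients seed the optimizer and their widened 95% CIs
    become hard box constraints, so the returned coefficients always lie
    inside the widened bounds.
    """
    bounds = widen_ci(general.ci95, expansion, expansion_mode)
    # keep the asymptote physical even if the CI dips below zero
    lo0, hi0 = bounds[0]
    bounds = ((max(lo0, 1e-12), hi0),) + bounds[1:]
    p0 = np.clip(
        general.coefficients,
        [b[0] for b in bounds],
        [b[1] for b in bounds],
    )
    return fit_logistic(
        t, y, force_origin=force_origin, origin_weight=origin_weight,
        bounds=bounds, p0=p0, **fit_kwargs,
    )


def growth_stage(t) -> str:
    """Classify days since start of growth into early/mid/late.

    early: t < 150; mid: 150 <= t <= 300; late: t > 300.
    """
    if np.ndim(t) > 0:
        return np.array([growth_stage(ti) for ti in np.asarray(t).ravel()])
    if t < 0:
        raise DomainError(f"t must be non-negative, got {t}")
    if t < 150:
        return "early"
    if t <= 300:
        return "mid"
    return "late"
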