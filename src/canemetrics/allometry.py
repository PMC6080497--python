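"""Allometric cane-biomass estimation and satellite computations.

The central relation estimates the biomass of a single cane from its
non-destructively measured biometrics: the stalk is idealized as a tapered
cylinder of diameter ``D`` (m) and height ``H`` (m) filled with stalk matter
of mass density ``rho_S`` (kg/m^3), scaled by a dimensionless taper factor
``F`` that corrects the ideal cylinder volume for the stalk's tapered shape;
the leaves contribute their own mass ``BM_L`` (kg):

    BM_S = (pi * D**2 / 4) * H * rho_S * F
    BM_C = BM_S + BM_L

Yield per unit area is expressed as tons cane per hectare (TCH) from the
cane count per row-metre ``C_row`` and the mean row spacing ``S`` (m):

    TCH = BM_C * C_row * 10 / S        [t/ha]

``C_row / S`` is the areal cane density in canes/m^2 (counts are taken along
the crop row, so the count per metre of row must be spread over the row
spacing); the factor 10 converts kg/m^2 to t/ha.

All functions accept scalars or NumPy arrays and broadcast.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, InputError

#: Default taper scaling factor calibrated from destructive stalk weighings.
DEFAULT_TAPER_FACTOR = 0.977
#: Default mean row spacing in metres: the average of the 0.9 m and 1.5 m
#: spacings of the double-row planting pattern.
DEFAULT_ROW_SPACING = (0.9 + 1.5) / 2.0  # = 1.2


@dataclass
class BiomassEstimate:
    """Per-cane stalk and total cane biomass, kg."""

    BM_S: float | np.ndarray
    BM_C: float | np.ndarray


def _check_nonneg(**named):
    for name, value in named.items():
        if np.any(np.asarray(value) < 0):
            raise DomainError(f"{name} must be non-negative")


def cane_biomass(
    D,
    H,
    rho_S,
    F: float = DEFAULT_TAPER_FACTOR,
    BM_L=0.0,
) -> BiomassEstimate:
    """Estimate stalk and cane biomass (kg) from biometrics.

    Parameters
    ----------
    D, H : float or array
        Stalk diameter and height, m.
    rho_S : float or array
        Stalk mass density, kg/m^3.
    F : float
        Taper scaling factor (dimensionless, time-invariant).
    BM_L : float or array
        Leaf biomass per cane, kg.
    """
    _check_nonneg(D=D, H=H, rho_S=rho_S, BM_L=BM_L)
    if np.any(np.asarray(F) <= 0):
        raise DomainError("taper factor F must be positive")
    BM_S = np.pi * np.asarray(D, float) ** 2 / 4.0 * H * rho_S * F
    BM_C = BM_S + BM_L
    if np.ndim(BM_S) == 0:
        return BiomassEstimate(float(BM_S), float(BM_C))
    return BiomassEstimate(BM_S, BM_C)


def tch(BM_C, C_row, S: float = DEFAULT_ROW_SPACING):
    """Tons cane per hectare from per-cane biomass and linear cane density.

    ``BM_C`` in kg, ``C_row`` in canes per row-metre, ``S`` row spacing in m.
    """
    _check_nonneg(BM_C=BM_C, C_row=C_row)
    if np.any(np.asarray(S) <= 0):
        raise DomainError("row spacing S must be positive")
    out = np.asarray(BM_C, float) * C_row * 10.0 / S
    return float(out) if np.ndim(out) == 0 else out


def calibrate_taper_factor(
    measured_BM_S,
    estimated_uncorrected_BM_S,
    method: str = "mean_of_ratios",
) -> float:
    """Calibrate the taper factor F from destructive stalk weighings.

    Each sample pairs a weighed stalk biomass with the cylinder-volume
    estimate computed from the same stalk's biometrics *without* taper
    correction.  ``mean_of_ratios`` averages the per-sample ratios
    measured/estimated; ``pooled`` divides the summed measured masses by the
    summed estimates (the two differ at second order in the scatter).
    """
    measured = np.asarray(measured_BM_S, float)
    estimated = np.asarray(estimated_uncorrected_BM_S, float)
    if measured.shape != estimated.shape or measured.size == 0:
        raise InputError("measured and estimated lists must be equal-length and non-empty")
    if np.any(measured <= 0):
        raise DomainError("measured stalk biomass must be positive")
    if np.any(estimated <= 0):
        raise DomainError("estimated stalk biomass must be positive")
    if method == "mean_of_ratios":
        return float(np.mean(measured / estimated))
    if method == "pooled":
        return float(measured.sum() / estimated.sum())
    raise ConfigurationError(f"unknown taper calibration method {method!r}")


def stalk_density_from_sample(mass, D, H):
    """Stalk mass density (kg/m^3) from a weighed stalk sample.

    The volume is the ideal cylinder ``pi*D^2/4*H``; no taper correction is
    applied at this stage (the taper factor is calibrated against exactly
    these uncorrected estimates).
    """
    _check_nonneg(mass=mass)
    if np.any(np.asarray(D) <= 0) or np.any(np.asarray(H) <= 0):
        raise DomainError("D and H must be positive")
    out = np.asarray(mass, float) / (np.pi * np.asarray(D, float) ** 2 / 4.0 * H)
    return float(out) if np.ndim(out) == 0 else out


def wet_content(dry_mass, wet_mass):
    """Wet-matter content: the complement of the dried/wet mass ratio."""
    dry = np.asarray(dry_mass, float)
    wet = np.asarray(wet_mass, float)
    if np.any(wet <= 0):
        raise DomainError("wet mass must be positive")
    if np.any(dry < 0) or np.any(dry > wet):
        raise DomainError("dry mass must satisfy 0 <= dry <= wet")
    out = 1.0 - dry / wet
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class LaiCorrection:
    """Result of the effective-to-actual LAI offset correction."""

    actual: np.ndarray  # offset-subtracted LAI (may be slightly negative)
    offset: float  # mean(measured - observed) over calibration pairs
    negative_mask: np.ndarray  # True where the corrected value fell below 0

    def clamped(self) -> np.ndarray:
        """Export copy with negative values clamped to zero (for plotting)."""
        return np.maximum(self.actual, 0.0)


def correct_lai(effective, calib_pairs) -> LaiCorrection:
    """Correct optically measured (effective) LAI for leaf clumping.

    The instrument under-segments clumped canopies, so a constant offset is
    estimated from destructive calibrations: ``calib_pairs`` is a sequence
    of ``(measured, observed)`` LAI pairs where *measured* is the instrument
    reading and *observed* the destructively determined leaf area fraction.
    The mean difference is subtracted from every effective reading.  Values
    driven slightly below zero are retained and flagged; use
    :meth:`LaiCorrection.clamped` for a zero-floored export.
    """
    pairs = np.asarray(calib_pairs, float)
    if pairs.size == 0:
        raise ConfigurationError("at least one LAI calibration pair is required")
    pairs = pairs.reshape(-1, 2)
    offset = float(np.mean(pairs[:, 0] - pairs[:, 1]))
    actual = np.asarray(effective, float) - offset
    return LaiCorrection(actual=actual, offset=offset, negative_mask=actual < 0)
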