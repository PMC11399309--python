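"""Bioclimatic variables from monthly climate.

Three variables summarise the climatic controls on vegetation physiognomy:

* ``ln MI`` — natural log of the moisture index, annual precipitation over
  annual potential evapotranspiration (unitless); the log emphasises
  differences at the dry end of the moisture range.
* ``MTCO`` — mean temperature of the coldest month (°C), winter cold.
* ``MGST`` — mean growing-season temperature (°C), summer warmth, the
  growing-degree-day heat sum above 0 °C divided by the number of days
  above 0 °C.

PET, when not supplied, comes from a Priestley–Taylor formulation driven by
monthly shortwave radiation and temperature.  All functions accept either
12-vectors (per-plot path) or ``(12, ny, nx)`` stacks (raster path); the two
paths share the same code and therefore agree bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Days per month of a 365-day climatological year.
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31],
                         dtype=float)

# Priestley-Taylor / psychrometric constants
PT_ALPHA = 1.26          # Priestley-Taylor coefficient
GAMMA_KPA = 0.0665       # psychrometric constant, kPa/degC
LAMBDA_MJ = 2.45         # latent heat of vaporisation, MJ/kg (~mm water)
NET_RADIATION_FRACTION = 0.77  # Rn approximated as (1 - albedo 0.23) * srad


class BioclimError(ValueError):
    """Raised for undefined or inconsistent bioclimatic inputs."""


@dataclass
class MonthlyClimate:
    """Monthly climate for one location or a grid.

    ``tas`` (°C), ``pr`` (mm/month) and ``pet`` (mm/month) carry the month
    axis first.  ``gdd0``/``ngd0`` may be supplied (e.g. from a climatology
    product) or derived from daily temperatures interpolated from ``tas``.
    """

    tas: np.ndarray
    pr: np.ndarray
    pet: np.ndarray | None = None
    srad: np.ndarray | None = None
    gdd0: np.ndarray | float | None = None
    ngd0: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.tas = np.asarray(self.tas, dtype=float)
        self.pr = np.asarray(self.pr, dtype=float)
        for name in ("tas", "pr"):
            arr = getattr(self, name)
            if arr.shape[0] != 12:
                raise BioclimError(f"{name} must have 12 months first, "
                                   f"got shape {arr.shape}")
        if np.any(self.pr < 0):
            raise BioclimError("precipitation must be non-negative")
        if self.pet is not None:
            self.pet = np.asarray(self.pet, dtype=float)
            if np.any(self.pet < 0):
                raise BioclimError("PET must be non-negative")
        if self.srad is not None:
            self.srad = np.asarray(self.srad, dtype=float)


def pet_priestley_taylor(tas, srad, month_length=None):
    """Monthly potential evapotranspiration (mm) via Priestley-Taylor.

    PET = alpha * s/(s+gamma) * Rn / lambda, with ``s`` the slope of the
    saturation vapour-pressure curve at ``tas`` (°C), ``Rn`` approximated as
    a fixed fraction of the monthly shortwave total ``srad`` (kJ/m2/month).
    Linear in ``srad`` at fixed temperature; zero radiation gives zero PET.
    ``month_length`` is accepted for interface symmetry (srad is already a
    monthly total, so it does not enter).
    """
    tas = np.asarray(tas, dtype=float)
    srad = np.asarray(srad, dtype=float)
    if np.any(srad < 0):
        raise BioclimError("shortwave radiation must be non-negative")
    # FAO-56 slope of saturation vapour pressure curve, kPa/degC
    es = 0.6108 * np.exp(17.27 * tas / (tas + 237.3))
    s = 4098.0 * es / (tas + 237.3) ** 2
    rn_mj = NET_RADIATION_FRACTION * srad / 1000.0  # kJ -> MJ per m2 month
    pet = PT_ALPHA * (s / (s + GAMMA_KPA)) * rn_mj / LAMBDA_MJ
    return np.maximum(pet, 0.0)


def moisture_index(climate: MonthlyClimate):
    """Moisture index: annual precipitation over annual PET.

    Returns ``(mi, ln_mi)``.  ``ln_mi`` is -inf where annual precipitation
    is zero (flagged out-of-domain downstream); zero annual PET raises.
    """
    if climate.pet is None:
        if climate.srad is None:
            raise BioclimError("PET not supplied and no srad to derive it from")
        climate.pet = pet_priestley_taylor(climate.tas, climate.srad)
    pr_sum = climate.pr.sum(axis=0)
    pet_sum = climate.pet.sum(axis=0)
    if np.any(pet_sum <= 0):
        raise BioclimError("annual PET is zero: moisture index undefined")
    mi = pr_sum / pet_sum
    with np.errstate(divide="ignore"):
        ln_mi = np.log(mi)
    return mi, ln_mi


def mtco(climate: MonthlyClimate):
    """Mean temperature of the coldest month (°C)."""
    if climate.tas.shape[0] != 12 or np.any(np.isnan(climate.tas)):
        raise BioclimError("12 finite monthly temperatures required")
    return climate.tas.min(axis=0)


def gdd_from_daily(daily_tas: np.ndarray):
    """Growing-degree statistics from a daily temperature series.

    ``gdd0`` is the heat sum of positive daily means; ``ngd0`` the count of
    days above 0 °C.  The day axis is axis 0; length must be 365 or 366.
    """
    daily = np.asarray(daily_tas, dtype=float)
    if daily.shape[0] not in (365, 366):
        raise BioclimError(
            f"daily series must cover a year (365/366 days), got {daily.shape[0]}"
        )
    positive = daily > 0
    gdd0 = np.where(positive, daily, 0.0).sum(axis=0)
    ngd0 = positive.sum(axis=0)
    return gdd0, ngd0


def daily_from_monthly(tas: np.ndarray) -> np.ndarray:
    """Daily temperatures by periodic linear interpolation between
    month-midpoint means (365-day year)."""
    tas = np.asarray(tas, dtype=float)
    mid = np.cumsum(MONTH_LENGTHS) - MONTH_LENGTHS / 2.0  # day-of-year midpoints
    days = np.arange(365) + 0.5
    # pad one month on each side for periodic wraparound
    xp = np.concatenate(([mid[-1] - 365.0], mid, [mid[0] + 365.0]))
    flat = tas.reshape(12, -1)
    out = np.empty((365, flat.shape[1]))
    for j in range(flat.shape[1]):
        fp = np.concatenate(([flat[-1, j]], flat[:, j], [flat[0, j]]))
        out[:, j] = np.interp(days, xp, fp)
    return out.reshape((365,) + tas.shape[1:])


def mgst(climate: MonthlyClimate):
    """Mean growing-season temperature (°C): GDD0 / NGD0.

    NaN (no growing season) where NGD0 = 0; a positive heat sum with zero
    growing days is inconsistent and raises.
    """
    if climate.gdd0 is None or climate.ngd0 is None:
        gdd0, ngd0 = gdd_from_daily(daily_from_monthly(climate.tas))
        climate.gdd0, climate.ngd0 = gdd0, ngd0
    gdd0 = np.asarray(climate.gdd0, dtype=float)
    ngd0 = np.asarray(climate.ngd0, dtype=float)
    if np.any((gdd0 > 0) & (ngd0 == 0)):
        raise BioclimError("gdd0 > 0 with ngd0 = 0 is inconsistent")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ngd0 > 0, gdd0 / np.where(ngd0 > 0, ngd0, 1.0), np.nan)
    return out


def bioclim_triple(climate: MonthlyClimate):
    """(ln MI, MTCO, MGST) for a location or grid; see module docstring."""
    _, ln_mi = moisture_index(climate)
    return ln_mi, mtco(climate), mgst(climate)
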