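"""Per-cell environmental change drivers: temperature trend, SPEI trend,
population-density change.

* ``delta_temperature`` — OLS slope of mean annual temperature against
  calendar year (degC/yr), per cell.
* ``spei_24`` — the standardized precipitation-evapotranspiration index on a
  24-month window. The climatic water balance D = P - PET (PET by the
  temperature-only Thornthwaite method) is summed over rolling 24-month
  windows; for each calendar month the window sums are fit with a
  three-parameter log-logistic distribution by unbiased probability-weighted
  moments, and the fitted CDF value is mapped through the standard-normal
  quantile, giving a z-score where values below -1.5 indicate severe drought.
* ``delta_spei`` — OLS slope of SPEI against month index (SPEI/month).
* ``delta_population`` — change in population density between the 1831
  census and the per-cell maximum of the 1871/1951/2001 censuses
  (persons/km^2), log10(x+1)-transformed for modeling.

Long-format climate tables have columns ``cell``, ``year``, ``month``
(1-12), ``tmean`` (degC), ``prcp`` (mm), plus a per-cell ``latitude``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as gamma_fn

__all__ = [
    "ols_slope",
    "delta_temperature",
    "thornthwaite_pet",
    "loglogistic_pwm_params",
    "loglogistic_cdf",
    "spei_24",
    "delta_spei",
    "delta_population",
]

#: clipping of CDF probabilities before the inverse-normal step
SPEI_PROB_EPS = 1e-6

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_MONTH_DAY = np.cumsum(_DAYS_IN_MONTH) - _DAYS_IN_MONTH / 2.0


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("slope requires at least 2 points")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def delta_temperature(climate: pd.DataFrame) -> pd.Series:
    """Linear slope of mean annual temperature per calendar year, per cell."""
    counts = climate.groupby(["cell", "year"])["tmean"].count()
    if (counts != 12).any():
        bad = counts[counts != 12].index[:5].tolist()
        raise ValueError(f"incomplete years in climate series, e.g. {bad}")
    annual = climate.groupby(["cell", "year"])["tmean"].mean().reset_index()
    return annual.groupby("cell").apply(
        lambda g: ols_slope(g["year"], g["tmean"]), include_groups=False
    ).rename("delta_temperature")


def thornthwaite_pet(tmean: np.ndarray, latitude: float) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), Thornthwaite formulation.

    ``tmean`` is a monthly series starting in January whose length is a
    multiple of 12. Per year: heat index I = sum_m (max(T_m,0)/5)^1.514,
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239, and
    PET_m = 16 K_m (10 max(T_m,0)/I)^a, with K_m the day-length/month-length
    correction from ``latitude`` (degrees) and mid-month solar declination.
    Months at or below 0 degC get PET 0; a year with I = 0 gets PET 0 with a
    warning.
    """
    t = np.asarray(tmean, dtype=float)
    if t.ndim != 1 or t.size % 12:
        raise ValueError("tmean must be a flat monthly series, length % 12 == 0")
    years = t.reshape(-1, 12)
    tpos = np.maximum(years, 0.0)

    phi = np.deg2rad(latitude)
    delta = 0.4093 * np.sin(0.0172 * _MID_MONTH_DAY - 1.405)
    omega = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    daylen = 24.0 * omega / np.pi
    K = (daylen / 12.0) * (_DAYS_IN_MONTH / 30.0)

    I = np.sum((tpos / 5.0) ** 1.514, axis=1)
    pet = np.zeros_like(years)
    dead = I <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} year(s) with all months <= 0 degC: PET set to 0",
            stacklevel=2,
        )
    live = ~dead
    if live.any():
        a = (
            6.75e-7 * I[live] ** 3
            - 7.71e-5 * I[live] ** 2
            + 1.792e-2 * I[live]
            + 0.49239
        )
        pet[live] = (
            16.0
            * K
            * (10.0 * tpos[live] / I[live, None]) ** a[:, None]
        )
    return pet.ravel()


def _unbiased_pwm(x_sorted: np.ndarray, s: int) -> float:
    """Unbiased probability-weighted moment w_s = E[X (1-F(X))^s].

    Computed from ascending order statistics as
    w_s = n^-1 sum_i x_(i) * C(n-i, s) / C(n-1, s).
    """
    n = x_sorted.size
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    for r in range(s):
        w *= (n - i - r) / (n - 1 - r)
    return float(np.mean(w * x_sorted))


def loglogistic_pwm_params(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic distribution by unbiased PWMs.

    Returns (alpha, beta, gamma) = (scale, shape, location) with
    CDF F(x) = (1 + (alpha / (x - gamma))^beta)^-1 for x > gamma.
    """
    x = np.sort(np.asarray(x, dtype=float))
    if x.size < 4:
        raise ValueError("log-logistic fit requires at least 4 values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: fit undefined")
    b0 = _unbiased_pwm(x, 0)
    b1 = _unbiased_pwm(x, 1)
    b2 = _unbiased_pwm(x, 2)
    denom = 6.0 * b1 - b0 - 6.0 * b2
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("degenerate sample: log-logistic fit undefined")
    beta = (2.0 * b1 - b0) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        raise ValueError(
            f"log-logistic shape estimate {beta!r} outside valid range (>1)"
        )
    g1g2 = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (b0 - 2.0 * b1) * beta / g1g2
    gamma = b0 - alpha * g1g2
    if alpha <= 0 or not np.isfinite(alpha) or not np.isfinite(gamma):
        raise ValueError("log-logistic fit produced invalid parameters")
    return alpha, beta, gamma


def loglogistic_cdf(
    x: np.ndarray, alpha: float, beta: float, gamma: float
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    above = x > gamma
    out[above] = 1.0 / (1.0 + (alpha / (x[above] - gamma)) ** beta)
    return out


def spei_24(
    tmean: np.ndarray,
    prcp: np.ndarray,
    latitude: float,
    scale: int = 24,
    eps: float = SPEI_PROB_EPS,
) -> np.ndarray:
    """24-month SPEI series; NaN for the first ``scale``-1 months.

    The water balance D = P - PET is aggregated by an unweighted rolling sum
    ending at the indexed month; the distribution is fit separately per
    calendar month over the full series (the reference period), and CDF
    probabilities are clipped to [eps, 1-eps] before the normal quantile.
    """
    t = np.asarray(tmean, dtype=float)
    p = np.asarray(prcp, dtype=float)
    if t.shape != p.shape:
        raise ValueError("temperature and precipitation series differ in length")
    if (p < 0).any():
        raise ValueError("negative precipitation")
    pet = thornthwaite_pet(t, latitude)
    d = p - pet
    n = d.size
    if n < scale + 4 * 12:
        raise ValueError("series too short for the requested SPEI scale")
    window = np.convolve(d, np.ones(scale), mode="valid")  # sums ending at i
    agg = np.full(n, np.nan)
    agg[scale - 1 :] = window

    spei = np.full(n, np.nan)
    months = np.arange(n) % 12
    for m in range(12):
        sel = (months == m) & np.isfinite(agg)
        if sel.sum() < 4:
            continue
        x = agg[sel]
        try:
            alpha, beta, gamma = loglogistic_pwm_params(x)
            probs = loglogistic_cdf(x, alpha, beta, gamma)
        except ValueError:
            # left-skewed sample: the log-logistic (right-skewed member of
            # the generalized-logistic family) cannot fit it directly; fit
            # its reflection and use the complementary probability
            alpha, beta, gamma = loglogistic_pwm_params(-x)
            probs = 1.0 - loglogistic_cdf(-x, alpha, beta, gamma)
        probs = np.clip(probs, eps, 1.0 - eps)
        spei[sel] = stats.norm.ppf(probs)
    return spei


def delta_spei(spei: np.ndarray) -> float:
    """OLS slope of SPEI against month index, over defined values."""
    spei = np.asarray(spei, dtype=float)
    idx = np.flatnonzero(np.isfinite(spei))
    if idx.size < 2:
        raise ValueError("fewer than 2 defined SPEI values")
    return ols_slope(idx, spei[idx])


def delta_population(census: pd.DataFrame) -> pd.DataFrame:
    """Population-density change per cell, and its log10(x+1) transform.

    ``census`` is long format with columns ``cell``, ``year``, ``density``.
    Delta = max(density in 1871, 1951, 2001) - density in 1831. A negative
    delta is retained but its log transform is NaN (excluded from log-scale
    modeling) with a warning.
    """
    wide = census.pivot_table(index="cell", columns="year", values="density")
    required = [1831, 1871, 1951, 2001]
    missing = [y for y in required if y not in wide.columns]
    if missing or wide[required].isna().any().any():
        raise ValueError(f"census incomplete; need all of {required} per cell")
    delta = wide[[1871, 1951, 2001]].max(axis=1) - wide[1831]
    neg = delta < 0
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} cell(s) with negative population change: "
            "excluded from log-scale modeling",
            stacklevel=2,
        )
    log_delta = pd.Series(np.nan, index=delta.index)
    log_delta[~neg] = np.log10(delta[~neg] + 1.0)
    return pd.DataFrame(
        {"delta_population": delta, "log_delta_population": log_delta}
    )
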