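"""Assay precision and quality statistics.

Covers replicate precision (mean, sample SD, CV%), the Z'-factor screening
statistic, dose-response fits over a serial dilution series, and detection of
the assay's linear range with its lower/upper limits of detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PrecisionStats",
    "SubrangeFit",
    "DoseResponseFits",
    "LinearRangeResult",
    "precision",
    "cv_from_moments",
    "z_prime",
    "dose_response_fits",
    "find_linear_range",
]


@dataclass
class PrecisionStats:
    group: str
    n: int
    mean: float
    sd: float
    cv_percent: float | None
    z_prime: float | None = None
    flag: str = ""


def cv_from_moments(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, CV% = 100 * SD / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def precision(values: Sequence[float], group: str = "") -> PrecisionStats:
    """Replicate precision: mean, sample SD (n-1 denominator) and CV%."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("precision needs n >= 2 replicates")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mean == 0:
        return PrecisionStats(group=group, n=vals.size, mean=mean, sd=sd,
                              cv_percent=None, flag="cv_undefined_zero_mean")
    return PrecisionStats(
        group=group, n=vals.size, mean=mean, sd=sd, cv_percent=cv_from_moments(mean, sd)
    )


def z_prime(
    pos_mean: float, pos_sd: float, neg_mean: float, neg_sd: float
) -> tuple[float, str]:
    """Z'-factor: z' = 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|.

    Returns ``(z', classification)`` with classification ``excellent`` for
    0.5-1, ``marginal`` for 0-0.5 and ``below_marginal`` for z' < 0.
    """
    if pos_mean == neg_mean:
        raise ValueError("Z'-factor undefined for equal control means")
    if pos_sd < 0 or neg_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    z = 1.0 - 3.0 * (pos_sd + neg_sd) / abs(pos_mean - neg_mean)
    if z >= 0.5:
        cls = "excellent"
    elif z >= 0.0:
        cls = "marginal"
    else:
        cls = "below_marginal"
    return z, cls


@dataclass
class SubrangeFit:
    """OLS fit of responses over one contiguous dilution subrange."""

    start: int                  # index into the dilution series (sorted ascending)
    stop: int                   # inclusive
    dilution_lo: float
    dilution_hi: float
    slope: float
    intercept: float
    r_squared: float


@dataclass
class DoseResponseFits:
    dilutions: np.ndarray
    responses: np.ndarray
    scale: str
    log_slope: float
    log_intercept: float
    r_squared_log: float
    subrange_fits: list[SubrangeFit]


def _x_for_scale(dilutions: np.ndarray, scale: str) -> np.ndarray:
    if scale == "concentration":
        return 1.0 / dilutions
    if scale == "dilution":
        return dilutions.astype(float)
    if scale == "log2_dilution":
        return np.log2(dilutions)
    raise ValueError(f"unknown scale {scale!r}")


def dose_response_fits(
    dilution_factors: Sequence[float],
    responses: Sequence[float],
    scale: str = "concentration",
) -> DoseResponseFits:
    """Fit the dilution series globally and on every contiguous subrange.

    The whole series is fitted against log2(dilution) — serial two-fold
    dilutions follow a logarithmic trend over their full range — and every
    contiguous subrange of >= 3 points is fitted linearly on the chosen
    concentration scale (default 1/dilution) to locate the linear range.
    """
    d = np.asarray(dilution_factors, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("dilution_factors and responses must have equal length")
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct dilutions")
    if np.any(d < 1):
        raise ValueError("dilution factors must be >= 1")
    order = np.argsort(d)
    d, y = d[order], y[order]

    res_log = stats.linregress(np.log2(d), y)
    x = _x_for_scale(d, scale)
    fits: list[SubrangeFit] = []
    k = len(d)
    for i in range(k):
        for j in range(i + 2, k):
            xs, ys = x[i : j + 1], y[i : j + 1]
            res = stats.linregress(xs, ys)
            r2 = float(res.rvalue**2) if np.ptp(ys) > 0 else 1.0
            fits.append(
                SubrangeFit(
                    start=i, stop=j, dilution_lo=float(d[i]), dilution_hi=float(d[j]),
                    slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
                )
            )
    return DoseResponseFits(
        dilutions=d, responses=y, scale=scale,
        log_slope=float(res_log.slope), log_intercept=float(res_log.intercept),
        r_squared_log=float(res_log.rvalue**2), subrange_fits=fits,
    )


@dataclass
class LinearRangeResult:
    dilution_lo: float
    dilution_hi: float
    r_squared_linear: float
    r_squared_log: float
    llod_percent: float | None
    ulod_percent: float | None
    empty: bool = False


def find_linear_range(fits: DoseResponseFits, r2_min: float = 0.95) -> LinearRangeResult:
    """Longest contiguous dilution subrange with linear R^2 >= r2_min.

    Ties on length are broken by higher R^2.  The detection limits are the
    fitted responses at the range ends: LLOD at the highest dilution (lowest
    concentration), ULOD at the lowest dilution.
    """
    qualifying = [f for f in fits.subrange_fits if f.r_squared >= r2_min]
    if not qualifying:
        return LinearRangeResult(
            dilution_lo=np.nan, dilution_hi=np.nan, r_squared_linear=np.nan,
            r_squared_log=fits.r_squared_log, llod_percent=None, ulod_percent=None,
            empty=True,
        )
    best = max(qualifying, key=lambda f: (f.stop - f.start, f.r_squared))
    x_lo = _x_for_scale(np.array([best.dilution_hi]), fits.scale)[0]  # highest dilution
    x_hi = _x_for_scale(np.array([best.dilution_lo]), fits.scale)[0]
    llod = best.slope * x_lo + best.intercept
    ulod = best.slope * x_hi + best.intercept
    return LinearRangeResult(
        dilution_lo=best.dilution_lo,
        dilution_hi=best.dilution_hi,
        r_squared_linear=best.r_squared,
        r_squared_log=fits.r_squared_log,
        llod_percent=float(llod),
        ulod_percent=float(ulod),
    )
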