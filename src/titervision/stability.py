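"""Vector-stability computations.

Stress studies (freeze/thaw cycles, temperature, salt, pump shear) reduce to
three statistics: infectivity as percent of an untreated control, an
exponential half-life fitted to a short titer kinetic, and the number of
passes of the sample through a peristaltic pump.  Significance testing of
group differences is delegated to standard routines (e.g. scipy.stats);
only the assay-specific quantities are computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DecayFit",
    "StressCondition",
    "percent_of_control",
    "fit_decay_half_life",
    "pump_pass_count",
]


@dataclass
class StressCondition:
    """One stress-study arm: treated titers versus untreated controls."""

    kind: str                      # freeze_thaw | temperature | salt | shear
    level: str
    titers: Sequence[float]
    control_titers: Sequence[float]

    def __post_init__(self) -> None:
        if self.kind not in ("freeze_thaw", "temperature", "salt", "shear"):
            raise ValueError(f"unknown stress kind {self.kind!r}")
        if len(self.titers) < 1 or len(self.control_titers) < 1:
            raise ValueError("replicate counts must be >= 1")


def percent_of_control(
    treated_titers: Sequence[float], control_titers: Sequence[float]
) -> tuple[float, float]:
    """Infectivity remaining and lost, as percent of the control mean."""
    treated = np.asarray(treated_titers, dtype=float)
    control = np.asarray(control_titers, dtype=float)
    if control.mean() <= 0:
        raise ValueError("control mean titer must be > 0")
    remaining = 100.0 * treated.mean() / control.mean()
    return remaining, 100.0 - remaining


@dataclass
class DecayFit:
    """Exponential titer decay: titer(t) = T0 * exp(-lambda * t)."""

    t0: float
    decay_rate_per_h: float
    half_life_h: float
    half_life_se_h: float
    r_squared: float
    n_points: int
    flag: str = ""

    @property
    def detectable(self) -> bool:
        return self.decay_rate_per_h > 0 and np.isfinite(self.half_life_h)


def fit_decay_half_life(times_h: Sequence[float], titers: Sequence[float]) -> DecayFit:
    """Half-life from a log-linear OLS fit of ln(titer) against time.

    Nonpositive titers are excluded with a warning (the log is undefined
    there); at least 3 usable timepoints are required.  The half-life is
    ln(2)/lambda with a delta-method standard error
    SE = ln(2) * SE_slope / lambda^2; a nonpositive decay rate is reported
    as not-detectable rather than as a negative half-life.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(titers, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and titers must have equal length")
    ok = y > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} nonpositive titer point(s) from the decay fit",
            stacklevel=2,
        )
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise ValueError("decay fit needs >= 3 timepoints with titer > 0")
    res = stats.linregress(t, np.log(y))
    lam = -float(res.slope)
    r2 = float(res.rvalue**2)
    if lam <= 0:
        return DecayFit(
            t0=float(np.exp(res.intercept)), decay_rate_per_h=lam,
            half_life_h=np.inf, half_life_se_h=np.nan, r_squared=r2,
            n_points=len(t), flag="not_detectable",
        )
    half_life = math.log(2.0) / lam
    se = math.log(2.0) * float(res.stderr) / lam**2 if np.isfinite(res.stderr) else 0.0
    return DecayFit(
        t0=float(np.exp(res.intercept)), decay_rate_per_h=lam,
        half_life_h=half_life, half_life_se_h=se, r_squared=r2, n_points=len(t),
    )


def pump_pass_count(flow_ml_per_min: float, duration_min: float, reservoir_ml: float) -> int:
    """Passes of the reservoir volume through a peristaltic pump.

    passes = flow * duration / reservoir, rounded half away from zero
    (19.5 mL/min x 30 min / 30 mL = 19.5 -> 20 passes; x 10 min -> 6.5 -> 7).
    """
    if flow_ml_per_min <= 0 or duration_min <= 0 or reservoir_ml <= 0:
        raise ValueError("flow, duration and reservoir volume must all be > 0")
    x = flow_ml_per_min * duration_min / reservoir_ml
    return int(math.floor(x + 0.5))
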