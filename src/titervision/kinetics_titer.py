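"""Per-well kinetics, readout-time selection, calibration and titer.

The titer of a lentiviral vector preparation in transducing units per mL is

    titer = P * N * D / (V * 100)

where ``P`` is the percentage of positive cells at the readout time, ``N``
the number of cells at the time of transduction, ``D`` the dilution factor
of the vector and ``V`` the transduction volume in mL.  ``P`` is measured
from image areas either over all cells,

    P2 = A_FF488 / A_C * 100,

or over viable cells only, excluding the infected-but-dead overlap area,

    P3 = (A_FF488 - A_PD) / (A_C - A_D) * 100.

``N`` is obtained per well from the phase-contrast confluence ``C`` via the
linear calibration ``N = (C - b) / m`` against an offline cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_io import PlateLayout
from .segmentation import FrameAreas

__all__ = [
    "WellTimeSeries",
    "CalibrationFit",
    "TiterResult",
    "SampleTiter",
    "build_timeseries",
    "normalized_positive_area",
    "viable_positive_percent",
    "select_readout",
    "fit_confluence_calibration",
    "cells_from_confluence",
    "infectious_titer",
    "plate_titer",
]


def normalized_positive_area(a_ff488: float, a_c: float) -> float:
    """P2: green-positive area as a percentage of the confluence area.

    May exceed 100% when the fluorescence mask is wider than the phase mask.
    """
    if a_c <= 0:
        raise ValueError("confluence area A_C must be > 0")
    if a_ff488 < 0:
        raise ValueError("A_FF488 must be >= 0")
    return a_ff488 / a_c * 100.0


def viable_positive_percent(a_ff488: float, a_pd: float, a_c: float, a_d: float) -> float:
    """P3: viable positive area as a percentage of the viable cell area."""
    if a_pd > a_ff488:
        raise ValueError("invariant violated: A_PD exceeds A_FF488")
    if a_c <= a_d:
        raise ValueError("no viable area: A_C must exceed A_D")
    return (a_ff488 - a_pd) / (a_c - a_d) * 100.0


@dataclass
class WellTimeSeries:
    """Kinetic record of one well: areas, P2/P3 and viability vs time."""

    well: str
    times_h: np.ndarray
    areas: list[FrameAreas]
    p2: np.ndarray
    p3: np.ndarray
    viability: np.ndarray
    flags: dict[float, str] = field(default_factory=dict)

    def confluence_at(self, time_h: float) -> float:
        """Confluence % at the frame closest to ``time_h`` (ties: earlier)."""
        dt = np.abs(self.times_h - time_h)
        return self.areas[int(np.argmin(dt))].confluence_pct

    def as_records(self) -> list[dict]:
        out = []
        for i, t in enumerate(self.times_h):
            a = self.areas[i]
            out.append(
                {
                    "well": self.well,
                    "time_h": float(t),
                    "a_c_um2": a.a_c_um2,
                    "a_ff488_um2": a.a_ff488_um2,
                    "a_d_um2": a.a_d_um2,
                    "a_pd_um2": a.a_pd_um2,
                    "field_area_um2": a.field_area_um2,
                    "confluence_pct": a.confluence_pct,
                    "p2": self.p2[i],
                    "p3": self.p3[i],
                    "viability": self.viability[i],
                    "flag": self.flags.get(float(t), ""),
                }
            )
        return out


def build_timeseries(areas_by_time: Mapping[float, FrameAreas], well: str) -> WellTimeSeries:
    """Assemble a well time series from per-timepoint area metrics.

    Timepoints with zero confluence area are flagged rather than dropped;
    quantities that cannot be computed there are NaN.  P3 and viability are
    NaN wherever the red channel (A_D) was not imaged — missing is not zero.
    """
    if not areas_by_time:
        raise ValueError("no timepoints supplied")
    times = np.array(sorted(areas_by_time), dtype=float)
    areas = [areas_by_time[t] for t in times]
    p2 = np.full(len(times), np.nan)
    p3 = np.full(len(times), np.nan)
    viability = np.full(len(times), np.nan)
    flags: dict[float, str] = {}
    for i, a in enumerate(areas):
        if a.a_c_um2 <= 0:
            flags[float(times[i])] = "zero_confluence"
            continue
        if a.a_ff488_um2 is not None:
            p2[i] = normalized_positive_area(a.a_ff488_um2, a.a_c_um2)
        if a.a_d_um2 is not None:
            viability[i] = 100.0 * (a.a_c_um2 - a.a_d_um2) / a.a_c_um2
            if a.a_ff488_um2 is not None:
                overlap = a.a_pd_um2 if a.a_pd_um2 is not None else 0.0
                if a.a_c_um2 > a.a_d_um2:
                    p3[i] = viable_positive_percent(
                        a.a_ff488_um2, overlap, a.a_c_um2, a.a_d_um2
                    )
                else:
                    flags[float(times[i])] = "no_viable_area"
    return WellTimeSeries(
        well=well, times_h=times, areas=areas, p2=p2, p3=p3, viability=viability, flags=flags
    )


def select_readout(
    times_h: Sequence[float],
    values: Sequence[float],
    window: tuple[float, float | None] | None = None,
) -> tuple[float, float]:
    """Readout time: the timepoint of maximum signal within the window.

    Ties are broken by the earliest time; NaN values are ignored.
    """
    times = np.asarray(times_h, dtype=float)
    vals = np.asarray(values, dtype=float)
    if times.shape != vals.shape:
        raise ValueError("times and values must have equal length")
    lo, hi = (window if window is not None else (-np.inf, None))
    hi = np.inf if hi is None else hi
    sel = (times >= lo) & (times <= hi) & np.isfinite(vals)
    if not sel.any():
        raise ValueError("no finite values inside the readout window")
    t_w, v_w = times[sel], vals[sel]
    order = np.argsort(t_w, kind="stable")
    t_w, v_w = t_w[order], v_w[order]
    i = int(np.argmax(v_w))  # argmax returns the first (earliest) maximum
    return float(t_w[i]), float(v_w[i])


@dataclass
class CalibrationFit:
    """Linear confluence-vs-cell-count calibration C = m*count + b."""

    m: float
    b: float
    r_squared: float
    n_points: int
    count_range: tuple[float, float] = (0.0, np.inf)


def fit_confluence_calibration(
    cell_counts: Sequence[float], confluences: Sequence[float]
) -> CalibrationFit:
    """OLS fit of confluence % against offline cell counts.

    Requires at least 3 distinct counts with non-zero variance.
    """
    counts = np.asarray(cell_counts, dtype=float)
    conf = np.asarray(confluences, dtype=float)
    if counts.shape != conf.shape:
        raise ValueError("cell_counts and confluences must have equal length")
    if len(np.unique(counts)) < 3:
        raise ValueError("calibration needs >= 3 distinct cell counts")
    if np.ptp(counts) == 0:
        raise ValueError("zero variance in cell counts")
    if np.ptp(conf) == 0:
        raise ValueError("constant confluence: slope is 0 and R^2 undefined")
    res = stats.linregress(counts, conf)
    return CalibrationFit(
        m=float(res.slope),
        b=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(counts),
        count_range=(float(counts.min()), float(counts.max())),
    )


def cells_from_confluence(confluence_pct: float, fit: CalibrationFit) -> float:
    """Invert the calibration: N = (C - b) / m, clipped at zero."""
    if fit.m <= 0:
        raise ValueError("calibration slope must be > 0")
    n = (confluence_pct - fit.b) / fit.m
    if n < 0:
        warnings.warn(
            f"confluence {confluence_pct:.3g}% below the calibration intercept; "
            "cell count clipped to 0",
            stacklevel=2,
        )
        n = 0.0
    lo, hi = fit.count_range
    if not (lo <= n <= hi):
        warnings.warn(
            f"cell count {n:.3g} extrapolates outside the calibrated range "
            f"[{lo:.3g}, {hi:.3g}]",
            stacklevel=2,
        )
    return n


def infectious_titer(p_percent: float, n_cells: float, dilution: float, volume_ml: float) -> float:
    """Infectious titer in TU/mL from P (%), N, D and V (mL)."""
    if p_percent < 0:
        raise ValueError("P must be >= 0")
    if n_cells < 0:
        raise ValueError("N must be >= 0")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if volume_ml <= 0:
        raise ValueError("transduction volume must be > 0")
    return p_percent * n_cells * dilution / (volume_ml * 100.0)


@dataclass
class TiterResult:
    """Per-well titer with the quantities entering the formula."""

    well: str
    sample_id: str
    mode: str
    p_percent: float
    n_cells: float
    dilution: float
    volume_ml: float
    titer_tu_per_ml: float
    readout_time_h: float
    in_range: bool = True
    flag: str = ""


@dataclass
class SampleTiter:
    """Replicate-averaged titer for one sample."""

    sample_id: str
    mode: str
    n_wells_used: int
    titer_tu_per_ml: float
    sd: float
    readout_time_h: float
    flag: str = ""


def plate_titer(
    series_by_well: Mapping[str, WellTimeSeries],
    layout: PlateLayout,
    calibration: CalibrationFit,
    mode: str = "all_cells",
    window: tuple[float, float | None] | None = (48.0, None),
    infection_time_h: float = 24.0,
    linear_range=None,
    plate_mean_n: bool = False,
) -> tuple[list[TiterResult], list[SampleTiter]]:
    """Titer every sample well and average over replicates.

    ``mode`` selects P2 (``all_cells``) or P3 (``viable_cells``).  ``N`` is
    taken from each well's own confluence at the transduction time (or the
    plate mean of sample wells when ``plate_mean_n``).  Wells whose peak P
    falls outside the assay's detection limits (``linear_range`` with
    ``llod_percent``/``ulod_percent``) are excluded from the sample mean and
    reported individually.
    """
    if mode not in ("all_cells", "viable_cells"):
        raise ValueError(f"unknown mode {mode!r}")
    layout.validate_for_titer()

    n_by_well: dict[str, float] = {}
    for well, series in series_by_well.items():
        if well in layout and layout[well].role == "sample":
            n_by_well[well] = cells_from_confluence(
                series.confluence_at(infection_time_h), calibration
            )
    if plate_mean_n and n_by_well:
        mean_n = float(np.mean(list(n_by_well.values())))
        n_by_well = {w: mean_n for w in n_by_well}

    llod = getattr(linear_range, "llod_percent", None)
    ulod = getattr(linear_range, "ulod_percent", None)

    well_results: list[TiterResult] = []
    for well, series in series_by_well.items():
        if well not in layout or layout[well].role != "sample":
            continue
        info = layout[well]
        curve = series.p2 if mode == "all_cells" else series.p3
        t_peak, p_peak = select_readout(series.times_h, curve, window)
        in_range = True
        flag = ""
        if llod is not None and p_peak < llod:
            in_range, flag = False, "below_llod"
        elif ulod is not None and p_peak > ulod:
            in_range, flag = False, "above_ulod"
        well_results.append(
            TiterResult(
                well=well,
                sample_id=info.sample_id,
                mode=mode,
                p_percent=p_peak,
                n_cells=n_by_well[well],
                dilution=info.dilution_factor,
                volume_ml=info.volume_ml,
                titer_tu_per_ml=infectious_titer(
                    p_peak, n_by_well[well], info.dilution_factor, info.volume_ml
                ),
                readout_time_h=t_peak,
                in_range=in_range,
                flag=flag,
            )
        )

    sample_results: list[SampleTiter] = []
    for sample_id in sorted({r.sample_id for r in well_results}):
        used = [r for r in well_results if r.sample_id == sample_id and r.in_range]
        if not used:
            sample_results.append(
                SampleTiter(
                    sample_id=sample_id, mode=mode, n_wells_used=0,
                    titer_tu_per_ml=np.nan, sd=np.nan, readout_time_h=np.nan,
                    flag="out_of_range",
                )
            )
            continue
        titers = np.array([r.titer_tu_per_ml for r in used])
        sd = float(np.std(titers, ddof=1)) if len(titers) > 1 else 0.0
        sample_results.append(
            SampleTiter(
                sample_id=sample_id,
                mode=mode,
                n_wells_used=len(used),
                titer_tu_per_ml=float(titers.mean()),
                sd=sd,
                readout_time_h=float(np.median([r.readout_time_h for r in used])),
            )
        )
    return well_results, sample_results
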