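"""End-to-end glue: frames -> areas -> time series -> calibration -> titer.

These helpers run the full measurement chain either on frames rendered in
memory by the simulator or on frames discovered on disk; the CLI and the
reproducibility script are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assay_qc import DoseResponseFits, LinearRangeResult, dose_response_fits, find_linear_range
from .config import AssayConfig
from .kinetics_titer import (
    CalibrationFit,
    SampleTiter,
    TiterResult,
    WellTimeSeries,
    build_timeseries,
    fit_confluence_calibration,
    plate_titer,
    select_readout,
)
from .plate_io import ImageFrame
from .segmentation import FrameAreas, SegmentationParams, frame_areas
from .synthetic_data import GroundTruth, SimConfig, render_frames, simulate_timecourse

__all__ = [
    "measure_frames",
    "measure_simulated_plate",
    "simulated_calibration",
    "peak_responses_by_dilution",
    "recover_plate_titer",
]


def measure_frames(
    frames: Iterable[ImageFrame],
    params: Mapping[str, SegmentationParams] | None = None,
) -> dict[str, WellTimeSeries]:
    """Segment frames, aggregate fields and assemble per-well time series."""
    grouped: dict[tuple[str, float], list[ImageFrame]] = {}
    for fr in frames:
        grouped.setdefault((fr.well, fr.time_h), []).append(fr)
    areas_by_well: dict[str, dict[float, FrameAreas]] = {}
    for (well, t), frs in grouped.items():
        areas_by_well.setdefault(well, {})[t] = frame_areas(frs, params)
    return {w: build_timeseries(by_t, w) for w, by_t in areas_by_well.items()}


def measure_simulated_plate(
    truth: GroundTruth,
    passes: Sequence[tuple[Sequence[float], Sequence[str]]],
    params: Mapping[str, SegmentationParams] | None = None,
    wells: Sequence[str] | None = None,
    fields: int = 1,
) -> dict[str, WellTimeSeries]:
    """Render and measure a simulated plate.

    ``passes`` lists (times, channels) groups so channels can be imaged on
    different schedules, e.g. phase-only before staining.
    """
    grouped: dict[tuple[str, float], list[ImageFrame]] = {}
    for times, channels in passes:
        for frame, _mask in render_frames(
            truth, wells=wells, times_h=times, channels=channels, fields=fields
        ):
            grouped.setdefault((frame.well, frame.time_h), []).append(frame)
    areas_by_well: dict[str, dict[float, FrameAreas]] = {}
    for (well, t), frs in grouped.items():
        areas_by_well.setdefault(well, {})[t] = frame_areas(frs, params)
    return {w: build_timeseries(by_t, w) for w, by_t in areas_by_well.items()}


def simulated_calibration(
    config: SimConfig,
    cell_counts: Sequence[int] = (2200, 6000, 13400, 26700, 53400),
    replicates: int = 3,
    params: Mapping[str, SegmentationParams] | None = None,
) -> CalibrationFit:
    """Confluence-vs-cell-count calibration from a simulated seeding run.

    Wells seeded at each count are imaged at the attachment time (cells are
    fully attached, growth has not yet moved the count) and the measured
    confluence is regressed against the known seeded count.
    """
    t_cal = [config.attachment_time_h]
    counts, confluences = [], []
    for i, count in enumerate(cell_counts):
        cfg = replace(
            config,
            seed=config.seed + 1000 + i,
            seeded_cells=int(count),
            dilution_series=(),
            replicates=replicates,
            n_matrix_controls=replicates,
        )
        truth = simulate_timecourse(cfg, times_h=t_cal)
        series = measure_simulated_plate(truth, [(t_cal, ("phase",))], params=params)
        for s in series.values():
            counts.append(count)
            confluences.append(s.areas[0].confluence_pct)
    return fit_confluence_calibration(counts, confluences)


def peak_responses_by_dilution(
    series_by_well: Mapping[str, WellTimeSeries],
    truth: GroundTruth,
    window: tuple[float, float | None],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean peak P2 per dilution over replicate wells, sorted by dilution."""
    by_d: dict[float, list[float]] = {}
    for well, series in series_by_well.items():
        info = truth.layout[well]
        if info.role != "sample":
            continue
        _, peak = select_readout(series.times_h, series.p2, window)
        by_d.setdefault(info.dilution_factor, []).append(peak)
    dils = np.array(sorted(by_d))
    means = np.array([np.mean(by_d[d]) for d in dils])
    return dils, means


def recover_plate_titer(
    sim_config: SimConfig,
    assay_config: AssayConfig | None = None,
    plate_times: Sequence[float] = (24.0, 56.0, 66.0, 76.0, 86.0, 96.0),
    calibration: CalibrationFit | None = None,
    mode: str = "all_cells",
) -> dict:
    """Full parameter-recovery run on one simulated plate.

    Simulates the plate, measures it with the segmentation chain, calibrates
    cell number from a separate seeding run, finds the assay's linear range
    on the dilution series and titers the in-range wells.

    Returns a dict with the ground truth titer, the recovered titer (median
    over in-range wells), per-sample results and the dose-response fits.
    """
    if assay_config is None:
        assay_config = AssayConfig()
    params = assay_config.segmentation
    window = assay_config.readout_window_h

    truth = simulate_timecourse(sim_config, times_h=plate_times)
    pre = [t for t in plate_times if t < sim_config.staining_time_h]
    post = [t for t in plate_times if t >= sim_config.staining_time_h]
    series = measure_simulated_plate(
        truth, [(pre, ("phase",)), (post, ("phase", "green"))], params=params
    )
    if calibration is None:
        calibration = simulated_calibration(sim_config, params=params)

    dils, peaks = peak_responses_by_dilution(series, truth, window)
    fits = dose_response_fits(dils, peaks, scale="concentration")
    linear_range = find_linear_range(fits)

    well_results, sample_results = plate_titer(
        series,
        truth.layout,
        calibration,
        mode=mode,
        window=window,
        infection_time_h=assay_config.infection_time_h,
        linear_range=None if linear_range.empty else linear_range,
    )
    in_range = [r.titer_tu_per_ml for r in well_results if r.in_range]
    recovered = float(np.median(in_range)) if in_range else float("nan")
    full_linear = [
        f for f in fits.subrange_fits if f.start == 0 and f.stop == len(dils) - 1
    ]
    return {
        "true_titer": sim_config.true_titer_tu_per_ml,
        "recovered_titer": recovered,
        "n_in_range_wells": len(in_range),
        "calibration": calibration,
        "linear_range": linear_range,
        "dose_response": fits,
        "r_squared_log": fits.r_squared_log,
        "r_squared_linear_full": full_linear[0].r_squared if full_linear else float("nan"),
        "well_results": well_results,
        "sample_results": sample_results,
        "series": series,
        "truth": truth,
    }
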