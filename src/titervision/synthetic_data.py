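"""Ground-truthed synthetic plates for the imaging titer assay.

The generator emulates the statistical structure the assay assumes, so the
whole pipeline is testable without an instrument:

* logistic cell growth per well, imaged on a fixed schedule;
* a single-hit Poisson dose-response across a two-fold dilution series:
  MOI = titer * V / (D * N) and P_inf = 1 - exp(-MOI), which saturates at
  low dilutions and is linear at high dilutions;
* a rise-then-decay green staining kinetic per infected cell,
  g(t') = (t'/tau)^s * exp(s * (1 - t'/tau)), peaking at tau hours after
  staining (surface labelling followed by internalization-driven loss);
* a constant fraction of dead, red-stained cells;
* rendered three-channel frames: textured ellipses on a noisy background
  (phase), fluorescent cells on a smooth background bump plus noise
  (green/red), with per-frame truth masks retained.

Rendered cells carry a one-pixel out-of-focus fringe in the phase texture
and in the green glow; the truth masks are the in-focus ellipses, so the
mask-refinement steps of the segmentation chain recover truth areas rather
than systematically eroded ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .plate_io import ImageFrame, PlateLayout, WellInfo, write_frame, write_plate_layout

__all__ = [
    "SimConfig",
    "WellTruth",
    "GroundTruth",
    "infection_probability",
    "green_kinetic",
    "confluence_curve",
    "simulate_timecourse",
    "render_frames",
    "simulate_plate_images",
]

_ROWS = "ABCDEFGH"


@dataclass
class SimConfig:
    """Study conditions for one simulated plate.

    Defaults mirror the assay protocol: 6e3 cells seeded per well, infection
    at 24 h with 50 uL of a two-fold dilution series (1:2 to 1:1024),
    staining 24 h post-infection, imaging every 2 h, and a green kinetic
    peaking 42 h after staining.  ``well_area_um2`` is the growth area of a
    96-well plate; it links cell counts to confluence.
    """

    seed: int = 0
    image_size_px: int = 256
    pixel_size_um: float = 1.24
    dilution_series: tuple[float, ...] = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)
    replicates: int = 3
    n_matrix_controls: int = 3
    true_titer_tu_per_ml: float = 2.0e7
    seeded_cells: int = 6000
    volume_ml: float = 0.05
    well_area_um2: float = 3.2e7
    doubling_time_h: float = 24.0
    carrying_confluence_pct: float = 95.0
    imaging_interval_h: float = 2.0
    t_start_h: float = 2.0
    t_end_h: float = 120.0
    attachment_time_h: float = 7.0
    infection_time_h: float = 24.0
    staining_time_h: float = 48.0
    green_peak_h: float = 42.0          # hours post staining
    green_shape: float = 2.0
    death_fraction: float = 0.001
    cell_radius_um: tuple[float, float] = (7.0, 11.0)
    green_intensity_gcu: float = 3.0
    green_intensity_cv: float = 0.25
    green_threshold_gcu: float = 1.3
    red_intensity_rcu: float = 1.0
    fluor_background_gcu: float = 0.5
    fluor_noise_sd: float = 0.03
    phase_background: float = 0.30
    phase_background_sd: float = 0.01
    phase_cell_level: float = 0.45
    phase_cell_sd: float = 0.12

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dilution_series):
            raise ValueError("dilution factors must be >= 1")
        for name in ("doubling_time_h", "green_peak_h", "green_shape", "imaging_interval_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.death_fraction <= 1:
            raise ValueError("death_fraction must be in [0, 1]")
        if len(self.dilution_series) > 11:
            raise ValueError("at most 11 dilutions fit on a 96-well row")
        if self.replicates > len(_ROWS):
            raise ValueError("too many replicates for a 96-well plate")

    @property
    def mean_cell_area_um2(self) -> float:
        r = 0.5 * (self.cell_radius_um[0] + self.cell_radius_um[1])
        return math.pi * r * r

    @property
    def seeded_confluence_pct(self) -> float:
        return 100.0 * self.seeded_cells * self.mean_cell_area_um2 / self.well_area_um2

    def times_h(self) -> np.ndarray:
        return np.arange(
            self.t_start_h, self.t_end_h + 1e-9, self.imaging_interval_h, dtype=float
        )


def infection_probability(
    true_titer: float, dilution: float, volume_ml: float, n_cells: float
) -> float:
    """Single-hit Poisson infection probability, P_inf = 1 - exp(-MOI)."""
    if true_titer <= 0 or dilution <= 0 or volume_ml <= 0 or n_cells <= 0:
        raise ValueError("all arguments must be > 0")
    moi = true_titer * volume_ml / (dilution * n_cells)
    return 1.0 - math.exp(-moi)


def green_kinetic(
    t_h: np.ndarray | float, staining_time_h: float, peak_h: float, shape: float = 2.0
) -> np.ndarray | float:
    """Unimodal staining kinetic, 0 before staining, peak 1 at ``peak_h``."""
    t = np.asarray(t_h, dtype=float)
    tp = t - staining_time_h
    with np.errstate(invalid="ignore"):
        g = np.where(
            tp > 0,
            (tp / peak_h) ** shape * np.exp(shape * (1.0 - tp / peak_h)),
            0.0,
        )
    return float(g) if np.isscalar(t_h) else g


def confluence_curve(
    config: SimConfig, times_h: np.ndarray, seeded_cells: int | None = None
) -> np.ndarray:
    """Logistic confluence %: flat until attachment, then logistic growth."""
    c0 = (
        config.seeded_confluence_pct
        if seeded_cells is None
        else 100.0 * seeded_cells * config.mean_cell_area_um2 / config.well_area_um2
    )
    k = config.carrying_confluence_pct
    r = math.log(2.0) / config.doubling_time_h
    t = np.asarray(times_h, dtype=float)
    dt = np.clip(t - config.attachment_time_h, 0.0, None)
    e = np.exp(r * dt)
    return k * c0 * e / (k + c0 * (e - 1.0))


@dataclass
class WellTruth:
    well: str
    sample_id: str
    role: str
    dilution: float | None
    seeded_cells: int
    n_at_infection: float
    moi: float
    p_inf: float
    infected_fraction: float


@dataclass
class GroundTruth:
    """Truth channel for a simulated plate."""

    config: SimConfig
    layout: PlateLayout
    wells: dict[str, WellTruth]
    table: pd.DataFrame  # well, time_h, confluence_pct, green_pct, dead_pct, overlap_pct

    def expected_p2_curve(self, well: str, times_h: np.ndarray) -> np.ndarray:
        """Model P2 (%): infected fraction times the staining kinetic."""
        w = self.wells[well]
        g = green_kinetic(
            times_h, self.config.staining_time_h, self.config.green_peak_h,
            self.config.green_shape,
        )
        return 100.0 * w.infected_fraction * np.asarray(g)


def _plate_wells(config: SimConfig) -> list[WellInfo]:
    """Replicate rows B, C, ...; matrix controls in column 1, dilutions in 2+."""
    infos: list[WellInfo] = []
    for rep in range(config.replicates):
        row = _ROWS[1 + rep]
        if rep < config.n_matrix_controls:
            infos.append(
                WellInfo(
                    well=f"{row}1", role="matrix_control", sample_id="matrix",
                    dilution_factor=1.0, volume_ml=config.volume_ml, group="matrix",
                )
            )
        for j, d in enumerate(config.dilution_series):
            infos.append(
                WellInfo(
                    well=f"{row}{2 + j}", role="sample", sample_id=f"LV_D{int(d)}",
                    dilution_factor=float(d), volume_ml=config.volume_ml,
                    group=f"dil_{int(d)}",
                )
            )
    return infos


def simulate_timecourse(
    config: SimConfig, times_h: Sequence[float] | None = None
) -> GroundTruth:
    """Draw per-well infection outcomes and tabulate true kinetic areas.

    The per-well infected fraction is Binomial(N_infection, P_inf) / N;
    everything is deterministic under a fixed seed.
    """
    times = np.asarray(times_h, dtype=float) if times_h is not None else config.times_h()
    layout = PlateLayout()
    wells: dict[str, WellTruth] = {}
    rows = []
    conf = confluence_curve(config, times)
    conf_inf = float(confluence_curve(config, np.array([config.infection_time_h]))[0])
    n_inf = (
        config.seeded_cells * conf_inf / config.seeded_confluence_pct
        if config.seeded_cells > 0
        else 0.0
    )
    g = np.asarray(
        green_kinetic(times, config.staining_time_h, config.green_peak_h, config.green_shape)
    )
    for widx, info in enumerate(_plate_wells(config)):
        layout.add(info)
        if info.role == "sample" and n_inf > 0:
            rng = np.random.default_rng([config.seed, widx, 101])
            moi = config.true_titer_tu_per_ml * config.volume_ml / (
                info.dilution_factor * n_inf
            )
            p_inf = infection_probability(
                config.true_titer_tu_per_ml, info.dilution_factor, config.volume_ml, n_inf
            )
            n_trials = int(round(n_inf))
            infected_frac = rng.binomial(n_trials, p_inf) / n_trials
        else:
            p_inf = moi = infected_frac = 0.0
        wells[info.well] = WellTruth(
            well=info.well, sample_id=info.sample_id, role=info.role,
            dilution=info.dilution_factor, seeded_cells=config.seeded_cells,
            n_at_infection=n_inf, moi=moi, p_inf=p_inf, infected_fraction=infected_frac,
        )
        dead_pct = config.death_fraction * conf
        green_pct = infected_frac * conf * g
        # infected-but-dead overlap exists only while the green stain is visible
        overlap_pct = infected_frac * g * dead_pct
        for i, t in enumerate(times):
            rows.append(
                {
                    "well": info.well,
                    "time_h": float(t),
                    "confluence_pct": float(conf[i]),
                    "green_pct": float(green_pct[i]),
                    "dead_pct": float(dead_pct[i]),
                    "overlap_pct": float(overlap_pct[i]),
                }
            )
    return GroundTruth(config=config, layout=layout, wells=wells, table=pd.DataFrame(rows))


class _Scene:
    """Persistent cell field for one well/field: positions never move, new
    cells appear as confluence grows."""

    def __init__(self, config: SimConfig, truth: WellTruth, well_idx: int, field: int):
        self.cfg = config
        self.truth = truth
        self.rng = np.random.default_rng([config.seed, well_idx, field, 7])
        n = config.image_size_px
        self.coverage = np.zeros((n, n), dtype=bool)
        self.cells: list[dict] = []
        # fixed smooth background bump per field (removed by the top-hat)
        self.bump_center = self.rng.uniform(0, n, size=2)
        self.bump_sigma = 0.6 * n

    def _new_cell(self) -> dict | None:
        cfg = self.cfg
        n = cfg.image_size_px
        r_lo, r_hi = (r / cfg.pixel_size_um for r in cfg.cell_radius_um)
        for attempt in range(40):
            cy, cx = self.rng.uniform(0, n, size=2)
            a, b = self.rng.uniform(r_lo, r_hi, size=2)
            theta = self.rng.uniform(0, math.pi)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(n, n), rotation=theta)
            if rr.size == 0:
                continue
            if self.coverage[rr, cc].mean() <= 0.3 or attempt == 39:
                rr_g, cc_g = draw_ellipse(cy, cx, a + 1, b + 1, shape=(n, n), rotation=theta)
                return {
                    "rr": rr, "cc": cc, "rr_glow": rr_g, "cc_glow": cc_g,
                    "infected": self.rng.random() < self.truth.infected_fraction,
                    "dead": self.rng.random() < self.cfg.death_fraction,
                    "green_gcu": float(
                        self.rng.lognormal(*_lognormal_params(
                            cfg.green_intensity_gcu, cfg.green_intensity_cv))
                    ),
                }
        return None

    def grow_to(self, conf_fraction: float) -> None:
        if conf_fraction > self.cfg.carrying_confluence_pct / 100.0 + 1e-9:
            raise ValueError("requested confluence exceeds the carrying capacity")
        guard = 0
        while self.coverage.mean() < conf_fraction and guard < 20000:
            cell = self._new_cell()
            guard += 1
            if cell is None:
                continue
            self.coverage[cell["rr"], cell["cc"]] = True
            self.cells.append(cell)

    def render(self, channel: str, time_h: float, noise_rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
        """Return (pixels, truth_mask) for one channel at one time."""
        cfg = self.cfg
        n = cfg.image_size_px
        truth_mask = np.zeros((n, n), dtype=bool)
        if channel == "phase":
            img = noise_rng.normal(cfg.phase_background, cfg.phase_background_sd, (n, n))
            textured = np.zeros((n, n), dtype=bool)
            for c in self.cells:
                textured[c["rr_glow"], c["cc_glow"]] = True
            tex = noise_rng.normal(cfg.phase_cell_level, cfg.phase_cell_sd, (n, n))
            img[textured] = tex[textured]
            truth_mask = self.coverage.copy()
        else:
            yy, xx = np.mgrid[0:n, 0:n]
            bump_amp = cfg.fluor_background_gcu if channel == "green" else 0.15
            img = bump_amp * np.exp(
                -((yy - self.bump_center[0]) ** 2 + (xx - self.bump_center[1]) ** 2)
                / (2 * self.bump_sigma**2)
            )
            img += noise_rng.normal(0.0, cfg.fluor_noise_sd, (n, n))
            if channel == "green":
                g = float(green_kinetic(
                    time_h, cfg.staining_time_h, cfg.green_peak_h, cfg.green_shape
                ))
                for c in self.cells:
                    if not c["infected"] or g <= 0:
                        continue
                    img[c["rr_glow"], c["cc_glow"]] += c["green_gcu"] * g
                    if c["green_gcu"] * g > cfg.green_threshold_gcu:
                        truth_mask[c["rr"], c["cc"]] = True
            else:  # red: dead cells, visible from staining time onward
                if time_h >= cfg.staining_time_h:
                    for c in self.cells:
                        if c["dead"]:
                            img[c["rr"], c["cc"]] += cfg.red_intensity_rcu
                            truth_mask[c["rr"], c["cc"]] = True
        np.clip(img, 0.0, None, out=img)
        return img.astype(np.float32), truth_mask


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def render_frames(
    truth: GroundTruth,
    wells: Iterable[str] | None = None,
    times_h: Sequence[float] | None = None,
    channels: Sequence[str] = ("phase", "green", "red"),
    fields: int = 1,
) -> Iterator[tuple[ImageFrame, np.ndarray]]:
    """Render frames for the requested wells/times, yielding
    ``(ImageFrame, truth_mask)`` pairs.

    Times must be processed in increasing order per well (cells only appear);
    identical seeds and arguments reproduce identical pixels.
    """
    cfg = truth.config
    if not 1 <= fields <= 4:
        raise ValueError("fields must be in 1..4")
    table = truth.table
    all_times = np.unique(table["time_h"].to_numpy())
    times = np.asarray(sorted(times_h), dtype=float) if times_h is not None else all_times
    well_order = {w: i for i, w in enumerate(truth.wells)}
    selected = list(truth.wells) if wells is None else list(wells)
    conf_by_time = {
        (r.well, r.time_h): r.confluence_pct for r in table.itertuples(index=False)
    }
    for well in selected:
        widx = well_order[well]
        for f in range(1, fields + 1):
            scene = _Scene(cfg, truth.wells[well], widx, f)
            for t in times:
                key = (well, float(t))
                if key not in conf_by_time:
                    raise KeyError(f"no ground truth for well {well} at t={t}")
                scene.grow_to(conf_by_time[key] / 100.0)
                for channel in channels:
                    noise_rng = np.random.default_rng(
                        [cfg.seed, widx, f, int(round(t * 10)),
                         ("phase", "green", "red").index(channel)]
                    )
                    pixels, mask = scene.render(channel, float(t), noise_rng)
                    frame = ImageFrame(
                        pixels=pixels, channel=channel, well=well, field=f,
                        time_h=float(t), pixel_size_um=cfg.pixel_size_um,
                    )
                    yield frame, mask


def simulate_plate_images(
    config: SimConfig,
    out_dir: str | Path,
    times_h: Sequence[float] | None = None,
    channels: Sequence[str] = ("phase", "green", "red"),
    fields: int = 1,
) -> GroundTruth:
    """Run the simulator and write TIFF frames, plate map and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_timecourse(config, times_h=times_h)
    frames_dir = out / "frames"
    for frame, _mask in render_frames(truth, times_h=times_h, channels=channels, fields=fields):
        write_frame(frame, frames_dir)
    write_plate_layout(truth.layout, out / "plate_map.csv")
    truth.table.to_csv(out / "ground_truth.csv", index=False)
    wt = pd.DataFrame([vars(w) for w in truth.wells.values()])
    wt.to_csv(out / "ground_truth_wells.csv", index=False)
    return truth
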