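"""Frame discovery, plate maps and metric tables.

File conventions
----------------
Images are single-channel grayscale TIFFs (8/16-bit unsigned or 32-bit
float), one file per (well, field, channel, timepoint), named

    {well}_f{field}_{channel}_t{HHH}.tif      e.g. B2_f3_green_t048.tif

with time in integer hours post-seeding.  The plate map is a CSV with header
``well,role,sample_id,dilution_factor,volume_ml,group``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ROLES",
    "ImageFrame",
    "FrameInfo",
    "WellInfo",
    "PlateLayout",
    "frame_filename",
    "discover_frames",
    "read_frame",
    "write_frame",
    "load_plate_layout",
    "write_plate_layout",
    "write_metrics",
    "read_metrics",
]

ROLES = frozenset(
    {
        "sample",
        "matrix_control",
        "isotype_control",
        "positive_ab_control",
        "triton_control",
        "untreated_control",
    }
)

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
DEFAULT_FRAME_PATTERN = (
    r"^(?P<well>[A-H]\d{1,2})_f(?P<field>\d)_(?P<channel>phase|green|red)"
    r"_t(?P<time>\d{1,4})\.tiff?$"
)


@dataclass
class ImageFrame:
    """One grayscale field image with acquisition metadata.

    ``unit_scale`` converts raw intensity to calibrated units (GCU/RCU) for
    fluorescence channels; images written by this package are already in
    calibrated units (unit_scale 1.0).
    """

    pixels: np.ndarray
    channel: str
    well: str
    field: int = 1
    time_h: float = 0.0
    pixel_size_um: float = 1.24
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("pixel intensities must be >= 0")
        if self.channel not in ("phase", "green", "red"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if not _WELL_RE.match(self.well):
            raise ValueError(f"invalid well ID {self.well!r}")
        if not 1 <= self.field <= 4:
            raise ValueError("field must be in 1..4")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be > 0")


@dataclass(frozen=True, order=True)
class FrameInfo:
    """Parsed frame metadata; the image itself is loaded on demand."""

    well: str
    time_h: float
    field: int
    channel: str
    path: Path

    def load(self, pixel_size_um: float = 1.24, unit_scale: float = 1.0) -> ImageFrame:
        return read_frame(self.path, self, pixel_size_um=pixel_size_um, unit_scale=unit_scale)


def frame_filename(well: str, field: int, channel: str, time_h: float) -> str:
    return f"{well}_f{field}_{channel}_t{int(round(time_h)):03d}.tif"


def discover_frames(
    root_path: str | Path, filename_pattern: str = DEFAULT_FRAME_PATTERN
) -> list[FrameInfo]:
    """Scan a directory for assay frames.

    Raises ``ValueError`` for a TIFF whose name does not parse, and for two
    files mapping to the same (well, field, channel, time).
    """
    root = Path(root_path)
    pattern = re.compile(filename_pattern)
    infos: list[FrameInfo] = []
    seen: dict[tuple, Path] = {}
    for path in sorted(root.glob("*.tif")) + sorted(root.glob("*.tiff")):
        m = pattern.match(path.name)
        if not m:
            raise ValueError(f"unparseable frame filename: {path}")
        d = m.groupdict()
        if not _WELL_RE.match(d["well"]):
            raise ValueError(f"invalid well ID in filename: {path}")
        info = FrameInfo(
            well=d["well"],
            time_h=float(int(d["time"])),
            field=int(d["field"]),
            channel=d["channel"],
            path=path,
        )
        key = (info.well, info.field, info.channel, info.time_h)
        if key in seen:
            raise ValueError(f"duplicate frame for {key}: {path} and {seen[key]}")
        seen[key] = path
        infos.append(info)
    infos.sort(key=lambda i: (i.well, i.time_h, i.field, i.channel))
    return infos


def read_frame(
    path: str | Path,
    info: FrameInfo | None = None,
    pixel_size_um: float = 1.24,
    unit_scale: float = 1.0,
) -> ImageFrame:
    pixels = tifffile.imread(str(path))
    if info is None:
        parsed = discover_single(Path(path))
        info = parsed
    return ImageFrame(
        pixels=np.asarray(pixels, dtype=np.float64),
        channel=info.channel,
        well=info.well,
        field=info.field,
        time_h=info.time_h,
        pixel_size_um=pixel_size_um,
        unit_scale=unit_scale,
    )


def discover_single(path: Path, filename_pattern: str = DEFAULT_FRAME_PATTERN) -> FrameInfo:
    m = re.compile(filename_pattern).match(path.name)
    if not m:
        raise ValueError(f"unparseable frame filename: {path}")
    d = m.groupdict()
    return FrameInfo(
        well=d["well"], time_h=float(int(d["time"])), field=int(d["field"]),
        channel=d["channel"], path=path,
    )


def write_frame(frame: ImageFrame, directory: str | Path) -> Path:
    """Write a frame as float32 TIFF under the package naming convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / frame_filename(frame.well, frame.field, frame.channel, frame.time_h)
    tifffile.imwrite(str(path), np.asarray(frame.pixels, dtype=np.float32))
    return path


@dataclass
class WellInfo:
    well: str
    role: str
    sample_id: str
    dilution_factor: float | None = None
    volume_ml: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if not _WELL_RE.match(self.well):
            raise ValueError(f"invalid well ID {self.well!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for well {self.well}")
        if self.role == "sample":
            if self.dilution_factor is None or self.dilution_factor < 1:
                raise ValueError(f"well {self.well}: sample dilution factor must be >= 1")
            if self.volume_ml is None or self.volume_ml <= 0:
                raise ValueError(f"well {self.well}: sample transduction volume must be > 0")


@dataclass
class PlateLayout:
    """96-well plate map: per-well sample identity, role, D and V."""

    wells: dict[str, WellInfo] = field(default_factory=dict)

    def add(self, info: WellInfo) -> None:
        if info.well in self.wells:
            raise ValueError(f"duplicate well {info.well}")
        self.wells[info.well] = info

    def __getitem__(self, well: str) -> WellInfo:
        return self.wells[well]

    def __contains__(self, well: str) -> bool:
        return well in self.wells

    def __len__(self) -> int:
        return len(self.wells)

    def wells_with_role(self, role: str) -> list[WellInfo]:
        return [w for w in self.wells.values() if w.role == role]

    def sample_groups(self) -> dict[str, list[WellInfo]]:
        groups: dict[str, list[WellInfo]] = {}
        for w in self.wells.values():
            if w.role == "sample":
                groups.setdefault(w.sample_id, []).append(w)
        return groups

    def validate_for_titer(self) -> None:
        if not self.wells_with_role("matrix_control"):
            raise ValueError("titer computation requires at least one matrix_control well")


def load_plate_layout(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path, dtype={"well": str, "role": str, "sample_id": str, "group": str})
    required = {"well", "role", "sample_id", "dilution_factor", "volume_ml", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map is missing columns: {sorted(missing)}")
    layout = PlateLayout()
    for row in df.itertuples(index=False):
        d = None if pd.isna(row.dilution_factor) else float(row.dilution_factor)
        v = None if pd.isna(row.volume_ml) else float(row.volume_ml)
        grp = "" if pd.isna(row.group) else str(row.group)
        layout.add(
            WellInfo(
                well=str(row.well), role=str(row.role), sample_id=str(row.sample_id),
                dilution_factor=d, volume_ml=v, group=grp,
            )
        )
    return layout


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {
            "well": w.well, "role": w.role, "sample_id": w.sample_id,
            "dilution_factor": w.dilution_factor, "volume_ml": w.volume_ml,
            "group": w.group,
        }
        for w in layout.wells.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _as_record(rec) -> dict:
    if isinstance(rec, dict):
        return rec
    if hasattr(rec, "as_record"):
        return rec.as_record()
    if hasattr(rec, "__dataclass_fields__"):
        return {k: getattr(rec, k) for k in rec.__dataclass_fields__}
    raise TypeError(f"cannot serialise record of type {type(rec)!r}")


def write_metrics(records: Sequence | Iterable, path: str | Path) -> pd.DataFrame:
    """Write metric records to CSV with a stable column order.

    Numeric values round-trip to 6 significant figures; an empty record set
    is an error, not an empty file.
    """
    rows = [_as_record(r) for r in records]
    if not rows:
        raise ValueError("refusing to write an empty metrics table")
    df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
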