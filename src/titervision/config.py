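"""Assay-level configuration (imaging schedule, segmentation settings)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .segmentation import SegmentationParams, default_params

__all__ = ["AssayConfig"]


@dataclass
class AssayConfig:
    """Timing and analysis settings for one assay run.

    Times are hours post cell seeding: cells attach by ``attachment_time_h``
    (confluence there calibrates the cell count), virus is added at
    ``infection_time_h``, and the staining mix at ``staining_time_h``
    (24 h post-infection).  The readout window for peak selection defaults
    to [staining time, end of run].
    """

    imaging_interval_h: float = 2.0
    attachment_time_h: float = 7.0
    infection_time_h: float = 24.0
    staining_time_h: float = 48.0
    readout_window_h: tuple[float, float | None] = (48.0, None)
    pixel_size_um: float = 1.24
    seed: int = 0
    segmentation: dict[str, SegmentationParams] = field(default_factory=default_params)

    def __post_init__(self) -> None:
        if self.imaging_interval_h <= 0:
            raise ValueError("imaging_interval_h must be > 0")
        if self.attachment_time_h < 0:
            raise ValueError("attachment_time_h must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg_raw = raw.pop("segmentation", {})
        seg = default_params()
        for channel, overrides in (seg_raw or {}).items():
            if channel not in seg:
                raise ValueError(f"unknown segmentation channel {channel!r}")
            base = asdict(seg[channel])
            base.update(overrides or {})
            seg[channel] = SegmentationParams(**base)
        if "readout_window_h" in raw and raw["readout_window_h"] is not None:
            raw["readout_window_h"] = tuple(raw["readout_window_h"])
        return cls(segmentation=seg, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["readout_window_h"] = list(self.readout_window_h)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
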