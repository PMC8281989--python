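"""Mask-building operators for phase-contrast and fluorescence frames.

The assay derives every readout from binary masks: a confluence mask from the
phase-contrast channel, an infected-cell mask from the green channel
(FabFluor-488 labelled surface receptor, in green calibrated units, GCU) and a
dead-cell mask from the red channel (Cytotox Red, RCU).  Fluorescence masks
are built by the operator chain

    top-hat background subtraction -> threshold -> clean-up -> area filter

with per-channel settings; the phase channel uses a texture (local standard
deviation) segmentation instead of the top-hat/threshold pair.  All areas are
reported in um^2 (pixel count x pixel_size_um^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

if TYPE_CHECKING:  # pragma: no cover
    from .plate_io import ImageFrame

__all__ = [
    "SegmentationParams",
    "MaskSet",
    "FrameAreas",
    "default_params",
    "tophat_subtract",
    "threshold_mask",
    "cleanup_mask",
    "area_filter",
    "confluence_segment",
    "fluor_segment",
    "overlap_area",
    "frame_areas",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Per-channel segmentation settings.

    Parameters
    ----------
    adjustment : float
        Multiplicative bias on the texture threshold (phase channel only).
    tophat_radius_um : float
        Radius of the top-hat structuring disc, in um (fluorescence only).
    threshold : float
        Intensity threshold in calibrated units (GCU or RCU).
    cleanup_px : int
        Signed boundary refinement: negative erodes the mask by ``|k|``
        pixels, positive dilates by ``k``, zero is the identity.
    min_area_um2, max_area_um2 : float or None
        Connected-component area limits; ``None`` means unbounded.
    texture_window_um : float
        Side of the local-standard-deviation window (phase channel).
    texture_sd_floor : float
        Absolute local-sd floor (intensity units) below which a pixel is
        never called cell; guards noise-only fields.
    edge_split : bool
        Object-splitting flag; deactivated for this assay and implemented as
        a no-op (area metrics need no object separation).
    """

    adjustment: float = 1.0
    tophat_radius_um: float = 20.0
    threshold: float = 1.3
    cleanup_px: int = 0
    min_area_um2: float | None = None
    max_area_um2: float | None = None
    texture_window_um: float = 3.0
    texture_sd_floor: float = 0.03
    edge_split: bool = False

    def __post_init__(self) -> None:
        if self.tophat_radius_um <= 0:
            raise ValueError("tophat_radius_um must be > 0")
        if (
            self.min_area_um2 is not None
            and self.max_area_um2 is not None
            and self.min_area_um2 > self.max_area_um2
        ):
            raise ValueError("min_area_um2 must be <= max_area_um2")


#: Operator settings used by the assay, per channel.
PHASE_DEFAULTS = SegmentationParams(adjustment=1.0, cleanup_px=-2, min_area_um2=170.0)
GREEN_DEFAULTS = SegmentationParams(
    tophat_radius_um=20.0, threshold=1.3, cleanup_px=-1, min_area_um2=35.0
)
RED_DEFAULTS = SegmentationParams(
    tophat_radius_um=20.0, threshold=0.3, cleanup_px=0,
    min_area_um2=35.0, max_area_um2=1400.0,
)


def default_params() -> dict[str, SegmentationParams]:
    """Fresh copy of the default per-channel parameter mapping."""
    return {
        "phase": replace(PHASE_DEFAULTS),
        "green": replace(GREEN_DEFAULTS),
        "red": replace(RED_DEFAULTS),
    }


@dataclass
class MaskSet:
    """Binary masks for one field, aligned to the source frame."""

    confluence_mask: np.ndarray | None = None
    green_mask: np.ndarray | None = None
    red_mask: np.ndarray | None = None


@dataclass
class FrameAreas:
    """Area metrics for one well at one timepoint, summed over fields.

    ``None`` marks a channel that was not imaged (missing, not zero).
    """

    a_c_um2: float
    a_ff488_um2: float | None
    a_d_um2: float | None
    a_pd_um2: float | None
    field_area_um2: float
    n_fields: int = 1

    def __post_init__(self) -> None:
        for name in ("a_c_um2", "a_ff488_um2", "a_d_um2", "a_pd_um2"):
            v = getattr(self, name)
            if v is not None and v < -1e-9:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.a_pd_um2 is not None:
            bounds = [v for v in (self.a_ff488_um2, self.a_d_um2) if v is not None]
            if bounds and self.a_pd_um2 > min(bounds) + 1e-9:
                raise ValueError("a_pd_um2 exceeds min(a_ff488_um2, a_d_um2)")

    def _pct(self, v: float | None) -> float | None:
        return None if v is None else 100.0 * v / self.field_area_um2

    @property
    def confluence_pct(self) -> float:
        return 100.0 * self.a_c_um2 / self.field_area_um2

    @property
    def green_pct(self) -> float | None:
        return self._pct(self.a_ff488_um2)

    @property
    def dead_pct(self) -> float | None:
        return self._pct(self.a_d_um2)

    @property
    def overlap_pct(self) -> float | None:
        return self._pct(self.a_pd_um2)


def _disc(radius_px: int) -> np.ndarray:
    return disk(radius_px).astype(bool)


def _radius_px(radius_um: float, pixel_size_um: float) -> int:
    # conservative: round the physical radius up to whole pixels
    return int(math.ceil(radius_um / pixel_size_um))


def tophat_subtract(frame: "ImageFrame", radius_um: float | None = None) -> np.ndarray:
    """White top-hat: frame minus its grayscale opening by a disc.

    Removes background structure larger than the disc while passing objects
    smaller than it; the disc radius should match the largest fluorescent
    object expected (20 um by default).
    """
    if frame.channel not in ("green", "red"):
        raise ValueError(f"top-hat expects a fluorescence channel, got {frame.channel!r}")
    if radius_um is None:
        radius_um = GREEN_DEFAULTS.tophat_radius_um
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    r = _radius_px(radius_um, frame.pixel_size_um)
    if r < 1:
        raise ValueError("structuring element radius is smaller than one pixel")
    img = np.asarray(frame.pixels, dtype=np.float64)
    opened = ndi.grey_opening(img, footprint=_disc(r), mode="reflect")
    out = img - opened
    # opening is anti-extensive, so this only clears float round-off
    np.clip(out, 0.0, None, out=out)
    return out


def threshold_mask(corrected: np.ndarray, threshold: float, unit_scale: float = 1.0) -> np.ndarray:
    """Detect pixels strictly brighter than ``threshold`` calibrated units."""
    if unit_scale <= 0:
        raise ValueError("unit_scale must be > 0")
    return np.asarray(corrected, dtype=np.float64) * unit_scale > threshold


def cleanup_mask(mask: np.ndarray, cleanup_px: int) -> np.ndarray:
    """Signed boundary refinement: erode (k < 0) or dilate (k > 0) by |k| px."""
    mask = np.asarray(mask, dtype=bool)
    k = int(cleanup_px)
    if k == 0:
        return mask.copy()
    fp = _disc(abs(k))
    if k < 0:
        return ndi.binary_erosion(mask, structure=fp, border_value=0)
    return ndi.binary_dilation(mask, structure=fp, border_value=0)


def area_filter(
    mask: np.ndarray,
    min_area_um2: float | None,
    max_area_um2: float | None,
    pixel_size_um: float,
) -> np.ndarray:
    """Keep 8-connected components whose area lies in [min, max] um^2."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    px_area = pixel_size_um**2
    lo = -np.inf if min_area_um2 is None else min_area_um2
    hi = np.inf if max_area_um2 is None else max_area_um2
    labels, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    areas = counts * px_area
    keep = (areas >= lo) & (areas <= hi)
    keep[0] = False  # background
    return keep[labels]


def confluence_segment(
    frame: "ImageFrame", params: SegmentationParams | None = None
) -> tuple[np.ndarray, float]:
    """Texture-based phase-contrast segmentation.

    Cells are textured, background is flat; a local standard-deviation filter
    (window ~3 um) turns texture into intensity, which is thresholded at
    ``adjustment x Otsu`` of the texture image.  When the Otsu split is
    degenerate — the two classes' mean local sd differ by less than a factor
    of two, i.e. the histogram is unimodal — the field is classified
    uniformly instead: all cell if the median local sd exceeds the absolute
    floor, all background otherwise.  This keeps a blank noise-only field at
    ~0% and a fully textured field at ~100% confluence.  Holes are filled,
    then the mask is refined by the clean-up filter and the minimum-area
    filter.

    Returns ``(mask, confluence_percent)``.
    """
    if frame.channel != "phase":
        raise ValueError(f"confluence_segment expects the phase channel, got {frame.channel!r}")
    if params is None:
        params = PHASE_DEFAULTS
    img = np.asarray(frame.pixels, dtype=np.float64)
    w = max(3, int(round(params.texture_window_um / frame.pixel_size_um)) | 1)
    mean = ndi.uniform_filter(img, size=w, mode="reflect")
    mean_sq = ndi.uniform_filter(img * img, size=w, mode="reflect")
    local_sd = np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))
    spread = float(local_sd.max() - local_sd.min())
    if spread <= 0:
        mask = np.zeros_like(img, dtype=bool)
    else:
        otsu = float(threshold_otsu(local_sd))
        lo = local_sd[local_sd <= otsu]
        hi = local_sd[local_sd > otsu]
        unimodal = (
            lo.size == 0
            or hi.size == 0
            or float(hi.mean()) < 2.0 * max(float(lo.mean()), 1e-12)
        )
        if unimodal:
            all_cells = float(np.median(local_sd)) > params.texture_sd_floor
            mask = np.full_like(img, all_cells, dtype=bool)
        else:
            thr = params.adjustment * max(otsu, params.texture_sd_floor)
            mask = local_sd > thr
            mask = ndi.binary_fill_holes(mask)
            mask = cleanup_mask(mask, params.cleanup_px)
            mask = area_filter(
                mask, params.min_area_um2, params.max_area_um2, frame.pixel_size_um
            )
    confluence = 100.0 * float(mask.sum()) / mask.size
    return mask, confluence


def fluor_segment(frame: "ImageFrame", params: SegmentationParams | None = None) -> np.ndarray:
    """Fluorescence mask: top-hat -> threshold -> clean-up -> area filter."""
    if frame.channel not in ("green", "red"):
        raise ValueError(f"fluor_segment expects green or red, got {frame.channel!r}")
    if params is None:
        params = GREEN_DEFAULTS if frame.channel == "green" else RED_DEFAULTS
    corrected = tophat_subtract(frame, params.tophat_radius_um)
    mask = threshold_mask(corrected, params.threshold, frame.unit_scale)
    mask = cleanup_mask(mask, params.cleanup_px)
    return area_filter(mask, params.min_area_um2, params.max_area_um2, frame.pixel_size_um)


def overlap_area(green_mask: np.ndarray, red_mask: np.ndarray, pixel_size_um: float) -> float:
    """Area of the green/red mask intersection (infected-but-dead cells)."""
    green_mask = np.asarray(green_mask, dtype=bool)
    red_mask = np.asarray(red_mask, dtype=bool)
    if green_mask.shape != red_mask.shape:
        raise ValueError(f"mask shapes differ: {green_mask.shape} vs {red_mask.shape}")
    return float(np.logical_and(green_mask, red_mask).sum()) * pixel_size_um**2


def segment_field(
    frames: Mapping[str, "ImageFrame"], params: Mapping[str, SegmentationParams]
) -> MaskSet:
    """Segment the available channels of one field."""
    out = MaskSet()
    if "phase" in frames:
        out.confluence_mask, _ = confluence_segment(frames["phase"], params.get("phase"))
    if "green" in frames:
        out.green_mask = fluor_segment(frames["green"], params.get("green"))
    if "red" in frames:
        out.red_mask = fluor_segment(frames["red"], params.get("red"))
    return out


def frame_areas(
    frames: Iterable["ImageFrame"],
    params: Mapping[str, SegmentationParams] | None = None,
) -> FrameAreas:
    """Area metrics for one well/timepoint, summed over its 1-4 fields.

    Each field contributes the masks of the channels it was imaged with;
    a channel absent from every field is reported as ``None``.
    """
    if params is None:
        params = default_params()
    by_field: dict[int, dict[str, "ImageFrame"]] = {}
    for fr in frames:
        by_field.setdefault(fr.field, {})[fr.channel] = fr
    if not by_field:
        raise ValueError("no frames supplied")
    if len(by_field) > 4:
        raise ValueError(f"at most 4 fields per well/timepoint, got {len(by_field)}")
    if not any("phase" in chans for chans in by_field.values()):
        raise ValueError("no phase frame at this timepoint")

    a_c = 0.0
    a_g: float | None = None
    a_d: float | None = None
    a_pd: float | None = None
    field_area = 0.0
    for _, chans in sorted(by_field.items()):
        any_frame = next(iter(chans.values()))
        px2 = any_frame.pixel_size_um**2
        field_area += any_frame.pixels.size * px2
        masks = segment_field(chans, params)
        if masks.confluence_mask is not None:
            a_c += float(masks.confluence_mask.sum()) * px2
        if masks.green_mask is not None:
            a_g = (a_g or 0.0) + float(masks.green_mask.sum()) * px2
        if masks.red_mask is not None:
            a_d = (a_d or 0.0) + float(masks.red_mask.sum()) * px2
        if masks.green_mask is not None and masks.red_mask is not None:
            a_pd = (a_pd or 0.0) + overlap_area(
                masks.green_mask, masks.red_mask, any_frame.pixel_size_um
            )
    return FrameAreas(
        a_c_um2=a_c,
        a_ff488_um2=a_g,
        a_d_um2=a_d,
        a_pd_um2=a_pd,
        field_area_um2=field_area,
        n_fields=len(by_field),
    )
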