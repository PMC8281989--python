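"""Independent brute-force reference implementations for the tests.

These deliberately avoid scipy.ndimage / scikit-image: morphology is done by
explicit neighborhood min/max over shifted copies, labelling by stack-based
flood fill, and OLS by the closed-form normal equations.
"""

from __future__ import annotations

import numpy as np


def disc_offsets(radius: int) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def _shifted(padded: np.ndarray, dy: int, dx: int, r: int, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return padded[r + dy : r + dy + h, r + dx : r + dx + w]


def brute_grey_erosion(img: np.ndarray, radius: int) -> np.ndarray:
    """Neighborhood minimum over a disc, reflecting at the borders."""
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, radius, mode="symmetric")
    out = np.full(img.shape, np.inf)
    for dy, dx in disc_offsets(radius):
        np.minimum(out, _shifted(padded, dy, dx, radius, img.shape), out=out)
    return out


def brute_grey_dilation(img: np.ndarray, radius: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, radius, mode="symmetric")
    out = np.full(img.shape, -np.inf)
    for dy, dx in disc_offsets(radius):
        np.maximum(out, _shifted(padded, -dy, -dx, radius, img.shape), out=out)
    return out


def brute_tophat(img: np.ndarray, radius: int) -> np.ndarray:
    """Image minus its opening (erosion then dilation by the same disc)."""
    opened = brute_grey_dilation(brute_grey_erosion(img, radius), radius)
    return np.clip(np.asarray(img, dtype=float) - opened, 0.0, None)


def brute_binary_erosion(mask: np.ndarray, radius: int) -> np.ndarray:
    """Pixel kept iff every neighbor within the disc is set (border: unset)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, radius, mode="constant", constant_values=False)
    out = np.ones(mask.shape, dtype=bool)
    for dy, dx in disc_offsets(radius):
        out &= _shifted(padded, dy, dx, radius, mask.shape)
    return out


def brute_binary_dilation(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, radius, mode="constant", constant_values=False)
    out = np.zeros(mask.shape, dtype=bool)
    for dy, dx in disc_offsets(radius):
        out |= _shifted(padded, -dy, -dx, radius, mask.shape)
    return out


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp: set[tuple[int, int]] = set()
            stack = [(sy, sx)]
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(comp)
    return comps


def brute_area_filter(
    mask: np.ndarray, min_area_um2: float | None, max_area_um2: float | None, px_um: float
) -> np.ndarray:
    lo = -np.inf if min_area_um2 is None else min_area_um2
    hi = np.inf if max_area_um2 is None else max_area_um2
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask):
        area = len(comp) * px_um * px_um
        if lo <= area <= hi:
            for y, x in comp:
                out[y, x] = True
    return out


def brute_overlap_count(a: np.ndarray, b: np.ndarray) -> int:
    count = 0
    for pa, pb in zip(np.asarray(a, dtype=bool).ravel(), np.asarray(b, dtype=bool).ravel()):
        if pa and pb:
            count += 1
    return count


def normal_equation_ols(x, y) -> tuple[float, float, float]:
    """(slope, intercept, r_squared) from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)
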