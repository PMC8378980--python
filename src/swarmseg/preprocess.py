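"""Gray-scale preprocessing: contrast stretch, binarization, connected
components with area filtering, and Gaussian smoothing.

Images are 2-D ``uint8`` arrays (row-major, origin top-left); binary masks
are 2-D ``uint8`` arrays of {0, 1}.  Every integer raster produced here is
rounded half-away-from-zero so results are bit-exact across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "RegionLabeling",
    "round_half_away",
    "linear_stretch",
    "percentile_window",
    "binarize",
    "label_connected",
    "area_filter",
    "gaussian_smooth",
]

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    return image


@dataclass(frozen=True)
class RegionLabeling:
    """Connected-component labels (0 = background) and per-label areas."""

    labels: np.ndarray
    region_areas: dict[int, int]

    @property
    def n_regions(self) -> int:
        return len(self.region_areas)


def linear_stretch(image: np.ndarray, in_low: int, in_high: int) -> np.ndarray:
    """Linear contrast stretch of the window ``[in_low, in_high]`` to [0, 255].

    Values at or below ``in_low`` map to 0, at or above ``in_high`` to 255,
    and the window is mapped linearly in between.
    """
    image = _as_gray(image)
    in_low, in_high = int(in_low), int(in_high)
    if not (0 <= in_low < in_high <= 255):
        raise ValueError(f"need 0 <= in_low < in_high <= 255, got ({in_low}, {in_high})")
    clipped = np.clip(image.astype(float), in_low, in_high)
    stretched = 255.0 * (clipped - in_low) / (in_high - in_low)
    return np.clip(round_half_away(stretched), 0, 255).astype(np.uint8)


def percentile_window(image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> tuple[int, int]:
    """Intensity window at the given percentiles, for auto contrast stretch.

    Returns integer ``(in_low, in_high)`` suitable for :func:`linear_stretch`.
    Raises ``ValueError`` when the window collapses (near-constant image).
    """
    image = _as_gray(image)
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    lo = int(np.floor(np.percentile(image, p_low)))
    hi = int(np.ceil(np.percentile(image, p_high)))
    if lo >= hi:
        raise ValueError(
            f"percentile window collapsed: p{p_low}={lo}, p{p_high}={hi} "
            "(image has no usable intensity spread)"
        )
    return max(lo, 0), min(hi, 255)


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground = pixels strictly above ``threshold``.

    The strict inequality matches the thresholding class convention: a
    single threshold ``t`` puts levels ``[0..t]`` in the lower class.
    """
    image = _as_gray(image)
    threshold = int(threshold)
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return (image > threshold).astype(np.uint8)


def label_connected(mask: np.ndarray, connectivity: int = 8) -> RegionLabeling:
    """Label maximal connected foreground components.

    Labels are renumbered 1..L in row-major first-encounter order, so the
    numbering is independent of the underlying labeling library.
    """
    mask = _as_gray(mask)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    raw = measure.label(mask > 0, connectivity=1 if connectivity == 4 else 2)
    flat = raw.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        return RegionLabeling(labels=np.zeros_like(raw, dtype=np.int64), region_areas={})
    first_seen, order = np.unique(flat, return_index=True)
    keep = first_seen > 0
    first_seen, order = first_seen[keep], order[keep]
    renumber = np.zeros(int(flat.max()) + 1, dtype=np.int64)
    for new_label, old_label in enumerate(first_seen[np.argsort(order)], start=1):
        renumber[old_label] = new_label
    labels = renumber[raw]
    areas = np.bincount(labels.ravel())
    region_areas = {int(lbl): int(areas[lbl]) for lbl in range(1, areas.size)}
    return RegionLabeling(labels=labels, region_areas=region_areas)


def area_filter(
    labeling: RegionLabeling,
    min_area: int = 1,
    max_area: int | None = None,
) -> np.ndarray:
    """Keep only regions whose pixel area lies in ``[min_area, max_area]``.

    Regions outside the band are set to background.  ``max_area=None``
    means unbounded above.
    """
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    if max_area is not None and min_area > max_area:
        raise ValueError(f"min_area={min_area} exceeds max_area={max_area}")
    keep = {
        lbl
        for lbl, area in labeling.region_areas.items()
        if area >= min_area and (max_area is None or area <= max_area)
    }
    return np.isin(labeling.labels, sorted(keep)).astype(np.uint8)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass filter (truncated at 4σ, reflective boundary).

    The kernel is the sampled, normalized Gaussian; the result is rounded
    back to an 8-bit raster.
    """
    image = _as_gray(image)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    smoothed = ndimage.gaussian_filter(
        image.astype(float), sigma=sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )
    return np.clip(round_half_away(smoothed), 0, 255).astype(np.uint8)
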