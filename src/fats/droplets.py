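"""Per-droplet radius estimation: background subtraction + circular Hough.

Adipogenesis shifts the droplet-size distribution upward; to measure it,
slowly varying background is removed by subtracting a large-window
Gaussian-smoothed copy of the lipid channel (clamped at zero), an edge map
is taken at a fixed percentile of the gradient magnitude, and a circular
Hough transform votes over the configured radius range.  Peaks above
``sensitivity`` x the maximum accumulator, non-maximum-suppressed at the
minimum radius, become detections.  Heavily overlapping droplets are not
deconvolved and will under-count; the method targets monolayer cultures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d
from skimage.filters import sobel
from skimage.transform import hough_circle, hough_circle_peaks

from .binarize import kernel_size_px, make_gaussian_kernel
from .core import ParameterError, PixelGrid


@dataclass(frozen=True)
class DropletDetection:
    """One detected droplet: centre (row, col), radius, Hough vote."""

    center: tuple[float, float]
    radius_um: float
    accumulator_score: float


@dataclass(frozen=True)
class DropletSizeSummary:
    """Count, mean radius and radius histogram of a detection list."""

    n_droplets: int
    mean_radius_um: float | None
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray


def subtract_background(
    lipid: PixelGrid,
    window_um: float,
    expected_max_droplet_um: float | None = None,
) -> PixelGrid:
    """Remove slowly varying background by large-window Gaussian smoothing.

    Output = clamp-at-zero(input - smoothed input).  A disc much smaller
    than the window contributes negligibly to the smoothed field, so
    droplet-scale structure survives while gradients and blotches vanish.
    """
    if expected_max_droplet_um is not None and window_um < 2 * expected_max_droplet_um:
        warnings.warn(
            "background window below 2x the maximum droplet diameter; "
            "droplets will be attenuated",
            UserWarning,
            stacklevel=2,
        )
    size = kernel_size_px(window_um, lipid.pixel_pitch_um)
    w1 = make_gaussian_kernel(size).weights_1d
    smooth = correlate1d(lipid.values.astype(np.float64), w1, axis=0, mode="nearest")
    smooth = correlate1d(smooth, w1, axis=1, mode="nearest")
    out = np.clip(np.rint(lipid.values.astype(np.float64) - smooth), 0, lipid.max_value)
    return PixelGrid(out.astype(lipid.values.dtype), lipid.pixel_pitch_um)


def detect_droplets(
    lipid_bgsub: PixelGrid,
    r_min_um: float = 0.5,
    r_max_um: float = 10.0,
    sensitivity: float = 0.5,
    edge_percentile: float = 90.0,
) -> list[DropletDetection]:
    """Circular-Hough droplet detection on a background-subtracted field."""
    if not 0 < r_min_um < r_max_um:
        raise ParameterError("need 0 < r_min_um < r_max_um")
    if not 0 < sensitivity <= 1:
        raise ParameterError("sensitivity must be in (0, 1]")
    pitch = lipid_bgsub.pixel_pitch_um
    r_min_px = r_min_um / pitch
    r_max_px = r_max_um / pitch
    if r_min_px < 1:
        raise ParameterError(
            f"r_min_um={r_min_um} is below one pixel at pitch {pitch} um/px"
        )
    grad = sobel(lipid_bgsub.values.astype(np.float64))
    nonzero = grad[grad > 0]
    if nonzero.size == 0:
        return []
    edges = grad >= np.percentile(nonzero, edge_percentile)
    radii = np.arange(int(np.floor(r_min_px)), int(np.ceil(r_max_px)) + 1)
    radii = radii[radii >= 1]
    spaces = hough_circle(edges, radii)
    min_dist = max(1, int(round(r_min_px)))
    accums, cx, cy, rad = hough_circle_peaks(
        spaces,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=sensitivity * float(spaces.max()),
    )
    candidates = sorted(
        zip(accums, cx, cy, rad), key=lambda t: (-t[0], t[2], t[1])
    )
    # greedy non-maximum suppression: a weaker circle whose centre falls
    # within a kept circle (or within r_min of its centre) is an arc fit
    # of the same droplet, not a separate one
    kept: list[tuple[float, float, float, float]] = []
    for a, x, y, r in candidates:
        if all(
            np.hypot(y - ky, x - kx) >= max(min_dist, kr)
            for _, kx, ky, kr in kept
        ):
            kept.append((float(a), float(x), float(y), float(r)))
    return [
        DropletDetection(
            center=(y, x), radius_um=r * pitch, accumulator_score=a
        )
        for a, x, y, r in kept
    ]


def summarize_radii(
    detections: list[DropletDetection], bins: int = 20
) -> DropletSizeSummary:
    """Mean and histogram of detected radii; empty input reports missing."""
    if not detections:
        return DropletSizeSummary(
            n_droplets=0,
            mean_radius_um=None,
            histogram_edges=np.array([0.0, 1.0]),
            histogram_counts=np.array([0]),
        )
    radii = np.array([d.radius_um for d in detections], dtype=float)
    counts, edges = np.histogram(radii, bins=bins)
    return DropletSizeSummary(
        n_droplets=len(detections),
        mean_radius_um=float(radii.mean()),
        histogram_edges=edges,
        histogram_counts=counts,
    )
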