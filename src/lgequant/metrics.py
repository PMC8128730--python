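"""Image-quality measurements: ROI statistics, SNR, CNR and edge sharpness.

Definitions follow common cardiac-MR practice:

* SNR = mean SI of a tissue ROI / SD of background air SI. On a static
  phantom the air SD is the average SD of three background ROIs; on
  patient-like images a single air ROI is used.
* CNR between scar and remote myocardium = (mean SI scar - mean SI remote)
  / (1.5 * SD of air).
* Edge sharpness = 1 / d, where d (in cm) is the distance between the
  points at 20% and 80% of the total intensity range of a line profile
  drawn across the edge. Sharper edges give larger values (units 1/cm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .datatypes import GeometryError, ImageStack, ROI, UndefinedMetricError


@dataclass(frozen=True)
class ROIStats:
    """Sample mean and SD (n-1 denominator) of signal intensity over an ROI."""

    mean_si: float
    sd_si: float
    n_pixels: int


@dataclass(frozen=True, eq=False)
class SharpnessProfile:
    """A line profile: sample positions along the line (cm) and intensities."""

    positions_cm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != x.shape or pos.size < 2:
            raise ValueError("profile needs matching 1-D positions and intensities (>= 2 samples)")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions_cm", pos)
        object.__setattr__(self, "intensities", x)

    @property
    def range_r(self) -> float:
        return float(self.intensities.max() - self.intensities.min())


def roi_stats(image: ImageStack, roi: ROI) -> ROIStats:
    """Sample mean and SD of image intensity over the ROI pixels."""
    values = roi.values(image)
    if values.size < 2:
        raise GeometryError("ROI must contain >= 2 pixels for SD to be defined")
    return ROIStats(
        mean_si=float(values.mean()),
        sd_si=float(values.std(ddof=1)),
        n_pixels=int(values.size),
    )


def _noise_sd(image: ImageStack, noise_roi: ROI | Sequence[ROI]) -> float:
    """Background noise SD; for several ROIs, the average of their SDs."""
    rois = [noise_roi] if isinstance(noise_roi, ROI) else list(noise_roi)
    sd = float(np.mean([roi_stats(image, r).sd_si for r in rois]))
    if sd == 0.0:
        raise UndefinedMetricError("background SD is zero; SNR/CNR undefined (noiseless image)")
    return sd


def snr(image: ImageStack, signal_roi: ROI, noise_roi: ROI | Sequence[ROI]) -> float:
    """Signal-to-noise ratio: signal-ROI mean over background-ROI SD."""
    return roi_stats(image, signal_roi).mean_si / _noise_sd(image, noise_roi)


def cnr(
    image: ImageStack,
    scar_roi: ROI,
    remote_roi: ROI,
    noise_roi: ROI | Sequence[ROI],
) -> float:
    """Scar-to-remote contrast-to-noise ratio: (scar - remote) / (1.5 * air SD)."""
    diff = roi_stats(image, scar_roi).mean_si - roi_stats(image, remote_roi).mean_si
    return diff / (1.5 * _noise_sd(image, noise_roi))


def extract_profile(
    image: ImageStack,
    slice_index: int,
    start_px: tuple[float, float],
    end_px: tuple[float, float],
    samples_per_px: float = 4.0,
) -> SharpnessProfile:
    """Sample a line profile across one slice with bilinear interpolation.

    ``start_px`` and ``end_px`` are ``(row, col)`` pixel coordinates; sample
    positions are converted to cm with the in-plane pixel spacing, so the
    profile spans the physical distance between the two endpoints.
    """
    if not 0 <= slice_index < image.n_slices:
        raise GeometryError("slice index out of range")
    r0, c0 = start_px
    r1, c1 = end_px
    nrow, ncol = image.slice_shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= nrow - 1 and 0 <= c <= ncol - 1):
            raise GeometryError("profile endpoints must lie within the image")
    length_px = float(np.hypot(r1 - r0, c1 - c0))
    if length_px < 2.0:
        raise GeometryError("profile must span at least 3 pixels")
    sr, sc = image.pixel_spacing_mm
    dist_cm = float(np.hypot((r1 - r0) * sr, (c1 - c0) * sc)) / 10.0
    n = int(round(length_px * samples_per_px)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    vals = map_coordinates(image.voxels[slice_index], [rows, cols], order=1)
    return SharpnessProfile(positions_cm=t * dist_cm, intensities=vals)


def _monotone_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal monotone (non-decreasing or non-increasing) index runs."""
    runs = []
    i, n = 0, len(x)
    while i < n - 1:
        j = i
        if x[j + 1] >= x[j]:
            while j < n - 1 and x[j + 1] >= x[j]:
                j += 1
        else:
            while j < n - 1 and x[j + 1] <= x[j]:
                j += 1
        runs.append((i, j))
        i = j
    return runs


def _cross_position(pos: np.ndarray, x: np.ndarray, lo: int, hi: int, t: float) -> float:
    """First crossing of level ``t`` on the monotone segment lo..hi (rising or falling)."""
    rising = x[hi] >= x[lo]
    prev = lo
    for k in range(lo, hi + 1):
        reached = x[k] >= t if rising else x[k] <= t
        if reached:
            if k == lo or x[k] == x[prev]:
                return float(pos[k])
            frac = (t - x[prev]) / (x[k] - x[prev])
            return float(pos[prev] + frac * (pos[k] - pos[prev]))
        prev = k
    raise UndefinedMetricError("threshold never crossed on the selected edge")


def sharpness(profile: SharpnessProfile) -> float:
    """Edge sharpness in 1/cm from the 20%-80% crossing distance.

    Thresholds are at 20% and 80% of the total intensity range; crossings
    are located by linear interpolation on the monotone run with the largest
    intensity span that covers both thresholds (a noisy profile may contain
    several monotone segments; the dominant edge is the intended one, ties
    broken toward the first such run).
    """
    x = profile.intensities
    pos = profile.positions_cm
    r = profile.range_r
    if r <= 0:
        raise UndefinedMetricError("flat profile; sharpness undefined")
    lo_t = float(x.min()) + 0.2 * r
    hi_t = float(x.min()) + 0.8 * r

    best: tuple[int, int] | None = None
    best_span = -np.inf
    for i, j in _monotone_runs(x):
        seg_lo, seg_hi = min(x[i], x[j]), max(x[i], x[j])
        if seg_lo <= lo_t and seg_hi >= hi_t:
            span = abs(float(x[j] - x[i]))
            if span > best_span:
                best, best_span = (i, j), span
    if best is None:
        raise UndefinedMetricError("no monotone edge crosses both the 20% and 80% levels")

    i, j = best
    p_lo = _cross_position(pos, x, i, j, lo_t)
    p_hi = _cross_position(pos, x, i, j, hi_t)
    d = abs(p_hi - p_lo)
    if d == 0:
        raise UndefinedMetricError("degenerate edge: 20% and 80% crossings coincide")
    return 1.0 / d
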