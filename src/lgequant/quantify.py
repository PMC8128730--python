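"""LGE scar quantification: contour rasterization, kSD and FWHM thresholds.

Threshold-based scar quantification compares myocardial signal intensity (SI)
against a reference threshold and reports the supra-threshold fraction of the
left-ventricular (LV) myocardium:

* **kSD method** — threshold = mean(remote ROI) + k * SD(remote ROI), with
  k = 2, 4 or 6. Because the threshold depends on the noise-driven SD of the
  remote region, it is sensitive to any reconstruction step that changes the
  noise level.
* **FWHM method** — threshold = half of the maximum SI within the scar ROI.
  It depends on signal amplitude, not on noise SD, which is what makes it
  comparatively robust to denoising.
* **manual** — stands in for a human reader; returns the generator's
  ground-truth scar mask unchanged.

Pixels exactly at the threshold count as scar (``>=`` comparison); this
convention is fixed so results are bit-exact and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .datatypes import (
    ContourSet,
    GeometryError,
    GroundTruth,
    ImageStack,
    ROI,
    UndefinedMetricError,
    _polygon,
)
from .metrics import roi_stats

#: k values of the SD-threshold methods, keyed by method name.
METHOD_KS = {"sd2": 2.0, "sd4": 4.0, "sd6": 6.0}

METHODS = ("sd2", "sd4", "sd6", "fwhm", "manual")


@dataclass(frozen=True)
class QuantResult:
    """Outcome of one scar quantification on one image.

    ``degenerate`` flags a kSD threshold computed from a remote ROI with zero
    SD (possible at 100% noise reduction on a texture-free phantom); the
    threshold then collapses to the remote mean and the result is kept.
    """

    method: str
    threshold: float | None
    scar_pixels_per_slice: tuple[int, ...]
    scar_percent_lv: float
    nr_level: float = 0.0
    degenerate: bool = False
    remote_mean: float | None = None
    remote_sd: float | None = None


def rasterize_polygon(vertices_rc: np.ndarray, slice_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie strictly inside the polygon."""
    poly = _polygon(vertices_rc)
    rows, cols = np.mgrid[0 : slice_shape[0], 0 : slice_shape[1]]
    inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
    return inside.reshape(slice_shape)


def rasterize_myocardium(contours: ContourSet, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize LV contours to a per-slice myocardium mask.

    A pixel belongs to the myocardium iff its center is inside the epicardial
    polygon and not inside the endocardial polygon. Slices without contours
    yield empty masks.

    Parameters
    ----------
    contours
        Nested epicardial/endocardial polygons (validated on construction).
    shape
        ``(n_slices, rows, cols)`` of the target grid.
    """
    n_slices, *slice_shape = shape
    mask = np.zeros(shape, dtype=bool)
    for idx in contours:
        if idx >= n_slices:
            raise GeometryError(f"contour slice {idx} outside a {n_slices}-slice stack")
        epi, endo = contours[idx]
        mask[idx] = rasterize_polygon(epi, tuple(slice_shape)) & ~rasterize_polygon(
            endo, tuple(slice_shape)
        )
    return mask


def threshold_ksd(image: ImageStack, remote_roi: ROI, k: float) -> float:
    """SD-based scar threshold: remote mean + k * remote SD.

    With zero remote SD (a noiseless, texture-free image) the threshold
    degenerates to the remote mean; callers that need to surface this use
    :func:`quantify`, which flags the condition.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    stats = roi_stats(image, remote_roi)
    return stats.mean_si + k * stats.sd_si


def threshold_fwhm(image: ImageStack, scar_roi: ROI) -> float:
    """Full-width-at-half-maximum threshold: half the scar-ROI maximum SI."""
    m = float(np.max(scar_roi.values(image)))
    if m <= 0:
        raise UndefinedMetricError("scar ROI maximum is not positive; FWHM undefined")
    return 0.5 * m


def apply_threshold(image: ImageStack, myo_mask: np.ndarray, threshold: float) -> np.ndarray:
    """Scar mask: myocardium pixels with SI >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    myo = np.asarray(myo_mask, dtype=bool)
    if myo.shape != image.voxels.shape:
        raise GeometryError("myocardium mask shape does not match image")
    return myo & (image.voxels >= threshold)


def scar_percent(
    scar_mask: np.ndarray, myo_mask: np.ndarray, geometry: ImageStack
) -> float:
    """Scar burden as % of LV myocardial volume.

    Each slice contributes pixel_count * pixel_area * (thickness + gap); with
    uniform geometry this reduces to the plain pixel-count ratio.
    """
    scar = np.asarray(scar_mask, dtype=bool)
    myo = np.asarray(myo_mask, dtype=bool)
    if scar.shape != myo.shape:
        raise GeometryError("mask shapes differ")
    if np.any(scar & ~myo):
        raise ValueError("scar mask must be a subset of the myocardium mask")
    if not myo.any():
        raise UndefinedMetricError("empty myocardium mask")
    sr, sc = geometry.pixel_spacing_mm
    slab = geometry.slice_thickness_mm + geometry.slice_gap_mm
    w = sr * sc * slab  # identical for every slice; kept explicit for clarity
    scar_vol = float(scar.sum(axis=(1, 2)).astype(float) @ np.full(scar.shape[0], w))
    myo_vol = float(myo.sum(axis=(1, 2)).astype(float) @ np.full(myo.shape[0], w))
    return 100.0 * scar_vol / myo_vol


def quantify(
    image: ImageStack,
    ground_truth: GroundTruth,
    method: str,
    nr_level: float = 0.0,
    myo_mask: np.ndarray | None = None,
) -> QuantResult:
    """Quantify scar burden on one image with the requested method.

    Contours and ROIs come from ``ground_truth`` and are identical across
    noise-reduction levels of the same case, mirroring an analysis workflow
    where contours are drawn once and copied between reconstructions.

    Parameters
    ----------
    myo_mask
        Optional precomputed myocardium mask (to avoid re-rasterizing the
        same contours for every method and NR level of one case).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if myo_mask is None:
        myo_mask = rasterize_myocardium(ground_truth.contours, image.voxels.shape)

    if method == "manual":
        mask = ground_truth.true_scar_mask
        return QuantResult(
            method="manual",
            threshold=None,
            scar_pixels_per_slice=tuple(int(n) for n in mask.sum(axis=(1, 2))),
            scar_percent_lv=float(ground_truth.true_scar_percent),
            nr_level=nr_level,
        )

    degenerate = False
    remote_mean = remote_sd = None
    if method in METHOD_KS:
        stats = roi_stats(image, ground_truth.remote_roi)
        remote_mean, remote_sd = stats.mean_si, stats.sd_si
        degenerate = stats.sd_si == 0.0
        thr = stats.mean_si + METHOD_KS[method] * stats.sd_si
    else:  # fwhm
        thr = threshold_fwhm(image, ground_truth.scar_roi)

    mask = apply_threshold(image, myo_mask, thr)
    return QuantResult(
        method=method,
        threshold=float(thr),
        scar_pixels_per_slice=tuple(int(n) for n in mask.sum(axis=(1, 2))),
        scar_percent_lv=scar_percent(mask, myo_mask, image),
        nr_level=nr_level,
        degenerate=degenerate,
        remote_mean=remote_mean,
        remote_sd=remote_sd,
    )
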