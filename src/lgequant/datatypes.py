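"""Core containers: image stacks, regions of interest, contours, ground truth.

All image math in the package operates on :class:`ImageStack`, a multi-slice
2D short-axis volume with physical pixel spacing, slice thickness and
inter-slice gap. Regions of interest (:class:`ROI`) are explicit pixel sets
on a single slice; circular ROIs resolve to the pixels whose centers fall
within the circle. Left-ventricular contours (:class:`ContourSet`) are
per-slice epicardial/endocardial polygons in pixel coordinates, with the
endocardial contour strictly inside the epicardial one.

Coordinate convention: 0-based ``(slice, row, col)``; a polygon vertex
``(row, col)`` addresses the *center* of that pixel, and a pixel belongs to
a polygonal region iff its center lies inside the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
import shapely
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """A geometric specification does not fit the image grid."""


class GenerationError(ValueError):
    """A synthetic case cannot be generated from the given specification."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. zero noise SD)."""


@dataclass(frozen=True)
class ImageStack:
    """Multi-slice short-axis image with physical geometry.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(slice, row, col)``, arbitrary signal
        units. All values must be finite and non-negative.
    pixel_spacing_mm
        In-plane ``(row, col)`` spacing in millimetres.
    slice_thickness_mm, slice_gap_mm
        Slice thickness and inter-slice gap in millimetres.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or vox.shape[0] < 1:
            raise GeometryError(
                f"voxels must be (slice, row, col) with >= 1 slice, got shape {vox.shape}"
            )
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel intensities must be finite")
        if vox.min() < 0:
            raise ValueError("voxel intensities must be >= 0")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0 or self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise GeometryError("pixel spacing and slice thickness must be positive")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def slice_spacing_mm(self) -> float:
        """Center-to-center distance between adjacent slices."""
        return self.slice_thickness_mm + self.slice_gap_mm

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        """New stack with the same geometry but different voxel data."""
        return replace(self, voxels=voxels)


@dataclass(frozen=True, eq=False)
class ROI:
    """A region of interest: a non-empty pixel set on one slice."""

    slice_index: int
    pixels: np.ndarray  # (n, 2) integer array of (row, col)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise GeometryError("ROI pixels must be a non-empty (n, 2) array")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_circle(
        cls, slice_index: int, center: tuple[float, float], radius_px: float
    ) -> "ROI":
        """ROI of all pixels whose centers lie within the circle.

        ``center`` is ``(row, col)`` in pixel coordinates; pixels at exactly
        ``radius_px`` from the center are included.
        """
        if radius_px <= 0:
            raise GeometryError("circle radius must be positive")
        cr, cc = center
        r0, r1 = int(np.floor(cr - radius_px)), int(np.ceil(cr + radius_px))
        c0, c1 = int(np.floor(cc - radius_px)), int(np.ceil(cc + radius_px))
        rr, cc_ = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        inside = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius_px**2
        return cls(slice_index, np.column_stack([rr[inside], cc_[inside]]))

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def check_bounds(self, slice_shape: tuple[int, int], n_slices: int) -> None:
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        if not (0 <= self.slice_index < n_slices):
            raise GeometryError(f"ROI slice {self.slice_index} outside stack")
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= slice_shape[0] or cols.max() >= slice_shape[1]:
            raise GeometryError("ROI pixels fall outside the image bounds")

    def values(self, stack: ImageStack) -> np.ndarray:
        """Voxel intensities at the ROI pixels."""
        self.check_bounds(stack.slice_shape, stack.n_slices)
        return stack.voxels[self.slice_index, self.pixels[:, 0], self.pixels[:, 1]]

    def mask(self, slice_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(slice_shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    def intersects(self, other: "ROI") -> bool:
        if self.slice_index != other.slice_index:
            return False
        a = {tuple(p) for p in self.pixels}
        return any(tuple(p) in a for p in other.pixels)


def _polygon(vertices_rc: np.ndarray) -> Polygon:
    """Shapely polygon from an (n, 2) array of (row, col) vertices."""
    v = np.asarray(vertices_rc, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs >= 3 (row, col) vertices")
    poly = Polygon(np.column_stack([v[:, 1], v[:, 0]]))  # shapely is (x=col, y=row)
    if not poly.is_valid:
        raise GeometryError("polygon is self-intersecting or degenerate")
    return poly


@dataclass(frozen=True, eq=False)
class ContourSet:
    """Per-slice epicardial and endocardial LV contours.

    ``contours`` maps slice index to ``(epi, endo)``, each an (n, 2) array of
    (row, col) vertices of a closed, non-self-intersecting polygon. On every
    slice the endocardial polygon must lie strictly inside the epicardial
    polygon. Slices without contours simply have no entry.
    """

    contours: Mapping[int, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for idx, (epi, endo) in dict(self.contours).items():
            epi = np.asarray(epi, dtype=float)
            endo = np.asarray(endo, dtype=float)
            p_epi, p_endo = _polygon(epi), _polygon(endo)
            if not p_endo.within(p_epi) or p_endo.boundary.intersects(p_epi.boundary):
                raise GeometryError(
                    f"slice {idx}: endocardial contour not strictly inside epicardial"
                )
            store[int(idx)] = (epi, endo)
        object.__setattr__(self, "contours", store)

    @property
    def slices(self) -> list[int]:
        return sorted(self.contours)

    def __getitem__(self, idx: int) -> tuple[np.ndarray, np.ndarray]:
        return self.contours[idx]

    def __contains__(self, idx: int) -> bool:
        return idx in self.contours

    def __iter__(self) -> Iterator[int]:
        return iter(self.slices)

    def translated(self, d_row: float, d_col: float) -> "ContourSet":
        shift = np.array([d_row, d_col])
        return ContourSet(
            {i: (epi + shift, endo + shift) for i, (epi, endo) in self.contours.items()}
        )


@dataclass(frozen=True, eq=False)
class NoiseField:
    """A stored per-pixel noise realization with its generating SD and seed.

    Keeping the exact realization (rather than only its SD) is what makes the
    noise-reduction emulator exact: the denoiser can subtract a known fraction
    of precisely this field.
    """

    values: np.ndarray
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """Generator-side reference standard for one synthetic case.

    ``true_scar_mask`` is the pre-blur, pre-noise scar pixel set; it is a
    subset of the myocardium mask implied by ``contours``. The ``manual``
    quantification method returns ``true_scar_percent`` unchanged, standing in
    for a human reader.
    """

    contours: ContourSet
    remote_roi: ROI
    scar_roi: ROI
    air_roi: ROI
    true_scar_mask: np.ndarray  # bool, (slice, row, col)
    true_scar_percent: float

    def __post_init__(self) -> None:
        m = np.asarray(self.true_scar_mask, dtype=bool)
        if m.ndim != 3:
            raise GeometryError("true_scar_mask must be (slice, row, col)")
        if not 0.0 <= self.true_scar_percent <= 100.0:
            raise ValueError("true_scar_percent must be in [0, 100]")
        object.__setattr__(self, "true_scar_mask", m)
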