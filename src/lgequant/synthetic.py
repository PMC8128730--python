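"""Synthetic LGE phantoms: static SNR phantom, short-axis scar cases, cohorts.

The generator emulates the two kinds of acquisition the analysis needs:

* a **static uniform phantom** — a doped disk on an air background with one
  signal ROI inside and three background ROIs outside, used for SNR-vs-NEX
  and SNR-vs-NR experiments;
* **short-axis LGE cases** — a left-ventricular myocardial ring with bright
  blood pool, nulled (dark) remote myocardium and hyperenhanced scar, in
  either an ischemic pattern (subendocardial wedge within one coronary-like
  angular territory) or a non-ischemic pattern (patchy mid-wall foci).
  Partial-volume blur (Gaussian PSF) gives tissue borders intermediate
  intensities, and a small smooth multiplicative texture keeps tissue ROIs
  from being exactly constant. Geometry defaults: 256 x 256 grid, 1.5 mm
  pixels, 8 mm slices with a 2 mm gap.

Every generator output is a pure function of its specification and seed.
Ground truth (contours, ROIs, the pre-blur scar mask and the true scar
percentage) is recorded alongside each clean image so that quantification
results can be judged against a known reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .datatypes import (
    ContourSet,
    GenerationError,
    GeometryError,
    GroundTruth,
    ImageStack,
    NoiseField,
    ROI,
)
from .denoise import sample_noise  # re-exported: noise is generator output too
from .quantify import rasterize_myocardium, rasterize_polygon, scar_percent

__all__ = [
    "PhantomSpec",
    "GridSpec",
    "ScarSpec",
    "CohortRanges",
    "make_static_phantom",
    "make_sa_case",
    "make_cohort",
    "draw_cohort_specs",
    "sample_noise",
]

_CIRCLE_VERTICES = 180


def _circle_polygon(center: tuple[float, float], radius: float) -> np.ndarray:
    """(n, 2) array of (row, col) vertices approximating a circle."""
    th = np.linspace(0.0, 2.0 * np.pi, _CIRCLE_VERTICES, endpoint=False)
    cr, cc = center
    return np.column_stack([cr + radius * np.sin(th), cc + radius * np.cos(th)])


# ---------------------------------------------------------------------------
# static phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Static uniform phantom: a doped disk in air.

    The defaults give ~11000 air pixels across the three background ROIs, so
    background-SD estimates are stable to well under 5%.
    """

    image_size: tuple[int, int] = (256, 256)
    disk_center: tuple[float, float] | None = None
    disk_radius_px: float = 60.0
    signal_level: float = 100.0
    signal_roi_radius_px: float | None = None  # default: half the disk radius
    bg_roi_radius_px: float | None = None  # default: largest corner fit, <= 35
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)

    def build(self) -> tuple[ImageStack, ROI, list[ROI]]:
        return make_static_phantom(
            image_size=self.image_size,
            disk_center=self.disk_center,
            disk_radius_px=self.disk_radius_px,
            signal_level=self.signal_level,
            signal_roi_radius_px=self.signal_roi_radius_px,
            bg_roi_radius_px=self.bg_roi_radius_px,
            pixel_spacing_mm=self.pixel_spacing_mm,
        )


def make_static_phantom(
    image_size: tuple[int, int] = (256, 256),
    disk_center: tuple[float, float] | None = None,
    disk_radius_px: float = 60.0,
    signal_level: float = 100.0,
    signal_roi_radius_px: float | None = None,
    bg_roi_radius_px: float | None = None,
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5),
) -> tuple[ImageStack, ROI, list[ROI]]:
    """Noiseless static phantom with one signal ROI and three background ROIs.

    The disk is uniform at ``signal_level`` on a zero (air) background and
    must fit with at least a 10-pixel air margin. The three circular
    background ROIs sit in image corners, pairwise disjoint and disjoint
    from the disk; by default their radius is the largest (up to 35 px) that
    fits the corners.
    """
    nrow, ncol = image_size
    if disk_center is None:
        disk_center = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    cr, cc = disk_center
    if disk_radius_px <= 0 or signal_level <= 0:
        raise GeometryError("disk radius and signal level must be positive")
    margin = 10.0
    if (
        cr - disk_radius_px < margin
        or cc - disk_radius_px < margin
        or cr + disk_radius_px > nrow - 1 - margin
        or cc + disk_radius_px > ncol - 1 - margin
    ):
        raise GeometryError("disk must fit inside the image with a >= 10 px air margin")

    rows, cols = np.mgrid[0:nrow, 0:ncol]
    disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= disk_radius_px**2
    voxels = np.where(disk, float(signal_level), 0.0)[None, :, :]
    stack = ImageStack(voxels=voxels, pixel_spacing_mm=pixel_spacing_mm)

    sig_r = signal_roi_radius_px if signal_roi_radius_px is not None else disk_radius_px / 2.0
    if sig_r >= disk_radius_px:
        raise GeometryError("signal ROI must fit inside the disk")
    signal_roi = ROI.from_circle(0, disk_center, sig_r)

    if bg_roi_radius_px is None:
        # largest corner ROI (up to 35 px) clear of the disk by > 1 px
        fits = [
            r
            for r in range(35, 2, -1)
            if math.hypot(r + 4.0 - cr, r + 4.0 - cc) > disk_radius_px + r + 1.0
        ]
        if not fits:
            raise GeometryError("no corner background ROI fits clear of the disk")
        bg_roi_radius_px = float(fits[0])
    off = bg_roi_radius_px + 4.0
    corners = [(off, off), (off, ncol - 1 - off), (nrow - 1 - off, off)]
    bg_rois = []
    for ctr in corners:
        dist = math.hypot(ctr[0] - cr, ctr[1] - cc)
        if dist <= disk_radius_px + bg_roi_radius_px + 1.0:
            raise GeometryError("background ROIs overlap the phantom disk")
        bg_rois.append(ROI.from_circle(0, ctr, bg_roi_radius_px))
    for roi in bg_rois:
        roi.check_bounds(stack.slice_shape, 1)
    return stack, signal_roi, bg_rois


# ---------------------------------------------------------------------------
# short-axis LGE cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Short-axis acquisition grid and LV ring geometry (pixels / mm)."""

    n_slices: int = 6
    shape: tuple[int, int] = (256, 256)
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0
    endo_radius_px: float = 18.0
    epi_radius_px: float = 27.0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise GeometryError("need >= 1 slice")
        if not 0 < self.endo_radius_px < self.epi_radius_px:
            raise GeometryError("need 0 < endo radius < epi radius")
        cr, cc = self.resolved_center
        nrow, ncol = self.shape
        if (
            cr - self.epi_radius_px < 1
            or cc - self.epi_radius_px < 1
            or cr + self.epi_radius_px > nrow - 2
            or cc + self.epi_radius_px > ncol - 2
        ):
            raise GeometryError("LV ring does not fit inside the grid")

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    @property
    def wall_px(self) -> float:
        return self.epi_radius_px - self.endo_radius_px


@dataclass(frozen=True)
class ScarSpec:
    """Scar pattern and tissue-signal parameters for one synthetic case.

    ``ischemic_wedge`` is a subendocardial wedge: an angular sector starting
    at ``angular_start_deg`` spanning ``angular_extent_deg``, extending from
    the endocardium through ``transmurality_fraction`` of the wall.
    ``nonischemic_patchy`` scatters ``n_patches`` mid-wall circular foci of
    radius ``patch_radius_px`` inside the same angular window on each
    involved slice.

    Signal levels are arbitrary units; defaults emulate a well-nulled LGE
    acquisition: suppressed remote myocardium near the noise floor, bright
    scar at ~3.7x remote, blood pool slightly below scar. ``psf_sigma_px``
    is the partial-volume blur applied to the whole clean image;
    ``texture_sigma`` is the relative SD of the smooth multiplicative
    heterogeneity of all tissue, and ``scar_texture_sigma`` the additional
    fine-grained heterogeneity of the scar itself (core vs gray-zone
    structure), which keeps the within-scar maximum signal-dominated rather
    than noise-dominated.
    """

    pattern: str = "ischemic_wedge"
    angular_start_deg: float = 0.0
    angular_extent_deg: float = 70.0
    transmurality_fraction: float = 0.7
    n_patches: int = 5
    patch_radius_px: float = 3.0
    slices_involved: tuple[int, ...] = (2, 3, 4)
    scar_intensity: float = 220.0
    remote_intensity: float = 60.0
    blood_intensity: float = 190.0
    psf_sigma_px: float = 1.0
    texture_sigma: float = 0.02
    scar_texture_sigma: float = 0.08
    shading_amplitude: float = 0.06

    def __post_init__(self) -> None:
        if self.pattern not in ("ischemic_wedge", "nonischemic_patchy"):
            raise GenerationError(f"unknown scar pattern {self.pattern!r}")
        if not self.scar_intensity > self.remote_intensity >= 0:
            raise GenerationError(
                "scar intensity must exceed remote intensity (no contrast otherwise)"
            )
        if self.blood_intensity < 0:
            raise GenerationError("blood intensity must be >= 0")
        if not 0.0 < self.transmurality_fraction <= 1.0:
            raise GenerationError("transmurality must be in (0, 1]")
        if not 0.0 < self.angular_extent_deg <= 360.0:
            raise GenerationError("angular extent must be in (0, 360] degrees")
        if self.psf_sigma_px < 0 or self.texture_sigma < 0 or self.scar_texture_sigma < 0:
            raise GenerationError("psf_sigma_px and texture SDs must be >= 0")
        if not 0.0 <= self.shading_amplitude < 1.0:
            raise GenerationError("shading_amplitude must be in [0, 1)")
        if len(self.slices_involved) == 0:
            raise GenerationError("scar must involve at least one slice")
        if self.pattern == "nonischemic_patchy" and (
            self.n_patches < 1 or self.patch_radius_px <= 0
        ):
            raise GenerationError("patchy pattern needs n_patches >= 1 and positive radius")


def _angles_deg(rows: np.ndarray, cols: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Pixel angles in [0, 360) measured from the +col axis around the center."""
    return np.degrees(np.arctan2(rows - center[0], cols - center[1])) % 360.0


def _in_sector(ang: np.ndarray, start_deg: float, extent_deg: float) -> np.ndarray:
    rel = (ang - start_deg) % 360.0
    return rel <= extent_deg


def _smooth_texture(shape: tuple[int, int], rng: np.random.Generator, corr_px: float = 8.0) -> np.ndarray:
    """Smooth zero-mean random field normalized to unit SD."""
    f = gaussian_filter(rng.standard_normal(shape), corr_px)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _scar_mask_for_slice(
    spec: ScarSpec,
    grid: GridSpec,
    ring: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pre-blur scar pixel set on one slice, constrained to the myocardial ring."""
    nrow, ncol = grid.shape
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    cr, cc = grid.resolved_center
    dist = np.hypot(rows - cr, cols - cc)
    ang = _angles_deg(rows, cols, (cr, cc))

    if spec.pattern == "ischemic_wedge":
        outer = grid.endo_radius_px + spec.transmurality_fraction * grid.wall_px
        return ring & _in_sector(ang, spec.angular_start_deg, spec.angular_extent_deg) & (
            dist <= outer
        )

    # non-ischemic: mid-wall patches within the angular window
    mask = np.zeros(grid.shape, dtype=bool)
    mid_lo = grid.endo_radius_px + 0.25 * grid.wall_px
    mid_hi = grid.endo_radius_px + 0.75 * grid.wall_px
    for _ in range(spec.n_patches):
        a = np.radians(
            spec.angular_start_deg + rng.uniform(0.0, spec.angular_extent_deg)
        )
        r = rng.uniform(mid_lo, mid_hi)
        pr, pc = cr + r * np.sin(a), cc + r * np.cos(a)
        mask |= (rows - pr) ** 2 + (cols - pc) ** 2 <= spec.patch_radius_px**2
    return mask & ring


def _place_remote_roi(
    spec: ScarSpec,
    grid: GridSpec,
    slice_idx: int,
    myo_slice: np.ndarray,
    scar_slice: np.ndarray,
) -> ROI:
    """Remote ROI at mid-wall, opposite the scar territory, clear of the scar."""
    cr, cc = grid.resolved_center
    a = np.radians(spec.angular_start_deg + spec.angular_extent_deg / 2.0 + 180.0)
    r = (grid.endo_radius_px + grid.epi_radius_px) / 2.0
    roi = ROI.from_circle(slice_idx, (cr + r * np.sin(a), cc + r * np.cos(a)), 4.0)
    inside = myo_slice[roi.pixels[:, 0], roi.pixels[:, 1]]
    if not inside.all():
        raise GenerationError("remote ROI does not fit inside the myocardium")
    min_clearance = max(2.0 * spec.psf_sigma_px, 2.0)
    dist_to_scar = distance_transform_edt(~scar_slice)
    if dist_to_scar[roi.pixels[:, 0], roi.pixels[:, 1]].min() < min_clearance:
        raise GenerationError("remote ROI cannot be placed clear of the scar")
    return roi


def _place_scar_roi(slice_idx: int, scar_slice: np.ndarray, max_pixels: int = 20) -> ROI:
    """Scar ROI: pixels deepest inside the scar on the given slice."""
    if scar_slice.sum() < 4:
        raise GenerationError("scar too small to place a scar ROI")
    depth = distance_transform_edt(scar_slice)
    rows, cols = np.nonzero(scar_slice)
    order = np.argsort(-depth[rows, cols], kind="stable")[:max_pixels]
    return ROI(slice_idx, np.column_stack([rows[order], cols[order]]))


def make_sa_case(
    grid: GridSpec, scar_spec: ScarSpec, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Generate one clean short-axis LGE case with its ground truth.

    The clean image is built as piecewise-constant tissue (blood pool,
    remote myocardium, scar), optionally modulated by smooth multiplicative
    texture, then blurred with the Gaussian PSF. Ground truth records the
    pre-blur, pre-texture scar mask, the LV contours, and generator-placed
    remote / scar / air ROIs on the central scarred slice.
    """
    for s in scar_spec.slices_involved:
        if not 0 <= s < grid.n_slices:
            raise GenerationError(f"scar slice {s} outside a {grid.n_slices}-slice stack")
    rng = np.random.default_rng(seed)
    nrow, ncol = grid.shape
    center = grid.resolved_center

    contours = ContourSet(
        {
            i: (
                _circle_polygon(center, grid.epi_radius_px),
                _circle_polygon(center, grid.endo_radius_px),
            )
            for i in range(grid.n_slices)
        }
    )
    shape3 = (grid.n_slices, nrow, ncol)
    myo = rasterize_myocardium(contours, shape3)
    endo_interior = rasterize_polygon(_circle_polygon(center, grid.endo_radius_px), (nrow, ncol))
    inside_endo = np.broadcast_to(endo_interior, shape3).copy()

    scar = np.zeros(shape3, dtype=bool)
    for s in scar_spec.slices_involved:
        scar[s] = _scar_mask_for_slice(scar_spec, grid, myo[s], rng)
    if not scar.any():
        raise GenerationError("scar specification produced an empty scar mask")

    clean = np.zeros(shape3, dtype=float)
    clean[inside_endo] = scar_spec.blood_intensity
    clean[myo] = scar_spec.remote_intensity
    clean[scar] = scar_spec.scar_intensity

    if scar_spec.texture_sigma > 0:
        tissue = myo | inside_endo
        for i in range(grid.n_slices):
            tex = _smooth_texture((nrow, ncol), rng)
            sl = clean[i]
            sl[tissue[i]] *= 1.0 + scar_spec.texture_sigma * tex[tissue[i]]
    if scar_spec.scar_texture_sigma > 0:
        # core/gray-zone structure within the scar only; correlation length
        # chosen to survive the PSF blur
        for i in scar_spec.slices_involved:
            tex = _smooth_texture((nrow, ncol), rng, corr_px=4.0)
            sl = clean[i]
            sl[scar[i]] *= np.clip(1.0 + scar_spec.scar_texture_sigma * tex[scar[i]], 0.0, None)
    if scar_spec.shading_amplitude > 0:
        # low-order multiplicative shading (coil sensitivity / nulling drift):
        # a planar gradient in a random direction, spanning +-amplitude
        # across the LV ring radius
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rows_g, cols_g = np.mgrid[0:nrow, 0:ncol].astype(float)
        g = (
            (rows_g - center[0]) * np.sin(phi) + (cols_g - center[1]) * np.cos(phi)
        ) / grid.epi_radius_px
        clean *= 1.0 + scar_spec.shading_amplitude * np.clip(g, -2.5, 2.5)[None, :, :]
    if scar_spec.psf_sigma_px > 0:
        for i in range(grid.n_slices):
            clean[i] = gaussian_filter(clean[i], scar_spec.psf_sigma_px)
    np.clip(clean, 0.0, None, out=clean)

    stack = ImageStack(
        voxels=clean,
        pixel_spacing_mm=grid.pixel_spacing_mm,
        slice_thickness_mm=grid.slice_thickness_mm,
        slice_gap_mm=grid.slice_gap_mm,
    )

    # ROIs on the central involved slice (most pronounced hyperenhancement)
    involved = sorted(scar_spec.slices_involved)
    ref_slice = involved[len(involved) // 2]
    remote_roi = _place_remote_roi(scar_spec, grid, ref_slice, myo[ref_slice], scar[ref_slice])
    scar_roi = _place_scar_roi(ref_slice, scar[ref_slice])
    air_roi = ROI.from_circle(ref_slice, (14.0, 14.0), 8.0)
    air_roi.check_bounds((nrow, ncol), grid.n_slices)
    air_dist = np.hypot(air_roi.pixels[:, 0] - center[0], air_roi.pixels[:, 1] - center[1])
    if air_dist.min() <= grid.epi_radius_px + 4.0 * max(scar_spec.psf_sigma_px, 1.0):
        raise GenerationError("air ROI overlaps the body")

    truth = GroundTruth(
        contours=contours,
        remote_roi=remote_roi,
        scar_roi=scar_roi,
        air_roi=air_roi,
        true_scar_mask=scar,
        true_scar_percent=scar_percent(scar, myo, stack),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortRanges:
    """Per-case sampling ranges for cohort generation (inclusive bounds).

    Defaults are calibrated so the default 30-case cohort has a median true
    scar burden near 6% of LV myocardium, in the 5-11% range typical of a
    mixed ischemic / non-ischemic scar-positive population.
    """

    n_slices: tuple[int, int] = (4, 8)
    scar_slice_fraction: tuple[float, float] = (0.35, 0.75)
    wedge_extent_deg: tuple[float, float] = (45.0, 95.0)
    transmurality: tuple[float, float] = (0.35, 0.85)
    patches_per_slice: tuple[int, int] = (3, 6)
    patch_radius_px: tuple[float, float] = (1.8, 3.5)
    patch_window_deg: float = 240.0

    def __post_init__(self) -> None:
        for name in (
            "n_slices",
            "scar_slice_fraction",
            "wedge_extent_deg",
            "transmurality",
            "patches_per_slice",
            "patch_radius_px",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GenerationError(f"empty range for {name}: ({lo}, {hi})")


def draw_cohort_specs(
    n_cases: int = 30,
    ischemic_fraction: float = 0.27,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
) -> list[tuple[GridSpec, ScarSpec, int]]:
    """Draw the per-case (grid, scar spec, case seed) triples of a cohort.

    The number of ischemic-pattern cases is ``round(n_cases *
    ischemic_fraction)`` (the default 30 cases at fraction 0.27 gives 8
    ischemic, 22 patchy non-ischemic); pattern order is shuffled. Per-case
    seeds are ``seed + index`` so individual cases can be regenerated in
    isolation.
    """
    if n_cases < 1:
        raise GenerationError("n_cases must be >= 1")
    if not 0.0 <= ischemic_fraction <= 1.0:
        raise GenerationError("ischemic_fraction must be in [0, 1]")
    ranges = ranges if ranges is not None else CohortRanges()
    base_grid = grid if grid is not None else GridSpec()

    n_ischemic = int(round(n_cases * ischemic_fraction))
    patterns = ["ischemic_wedge"] * n_ischemic + ["nonischemic_patchy"] * (n_cases - n_ischemic)
    draw = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10D]))
    draw.shuffle(patterns)

    out = []
    for i in range(n_cases):
        n_slices = int(draw.integers(ranges.n_slices[0], ranges.n_slices[1] + 1))
        n_scar = max(1, int(round(draw.uniform(*ranges.scar_slice_fraction) * n_slices)))
        n_scar = min(n_scar, n_slices)
        start = int(draw.integers(0, n_slices - n_scar + 1))
        slices_involved = tuple(range(start, start + n_scar))
        ang0 = float(draw.uniform(0.0, 360.0))
        if patterns[i] == "ischemic_wedge":
            spec = ScarSpec(
                pattern="ischemic_wedge",
                angular_start_deg=ang0,
                angular_extent_deg=float(draw.uniform(*ranges.wedge_extent_deg)),
                transmurality_fraction=float(draw.uniform(*ranges.transmurality)),
                slices_involved=slices_involved,
            )
        else:
            spec = ScarSpec(
                pattern="nonischemic_patchy",
                angular_start_deg=ang0,
                angular_extent_deg=ranges.patch_window_deg,
                n_patches=int(draw.integers(ranges.patches_per_slice[0], ranges.patches_per_slice[1] + 1)),
                patch_radius_px=float(draw.uniform(*ranges.patch_radius_px)),
                slices_involved=slices_involved,
            )
        out.append((replace(base_grid, n_slices=n_slices), spec, int(seed) + i))
    return out


def make_cohort(
    n_cases: int = 30,
    ischemic_fraction: float = 0.27,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    spec_overrides: dict | None = None,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate a cohort of scar-positive short-axis cases.

    See :func:`draw_cohort_specs` for how per-case parameters are drawn.
    ``spec_overrides`` forwards fixed :class:`ScarSpec` fields (intensities,
    blur, texture) to every case, overriding the drawn specs.
    """
    cohort = []
    for case_grid, spec, case_seed in draw_cohort_specs(
        n_cases, ischemic_fraction, ranges, seed, grid
    ):
        if spec_overrides:
            spec = replace(spec, **spec_overrides)
        cohort.append(make_sa_case(case_grid, spec, seed=case_seed))
    return cohort
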