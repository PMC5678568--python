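"""Two-path stomatal pore measurement.

Every cropped ROI first goes through binary segmentation: sharpen, global
threshold (dark structures become foreground), connected components, then
pick the solid region near the ROI center that is plausibly a pore and read
its morphology off the region moments.  When no such region exists — the
classic symptom of a degraded stoma whose boundary ring is incomplete and
whose interior has washed out — the ROI falls through to the skeleton path:
thin the dark structures to 1-px skeletal remnants, pick the remnant whose
length and position match a pore boundary, fit an ellipse to its pixels by
direct least squares, and use that ellipse as a mask within which the pore
is re-segmented and measured.

Axis lengths are derived from area ``A`` and eccentricity ``E``::

    a = sqrt(A / (π sqrt(1 - E²)))        b = sqrt(A sqrt(1 - E²) / π)

so that ``π a b = A`` and ``b / a = sqrt(1 - E²)`` hold exactly.  ``a`` and
``b`` are therefore SEMI-axis lengths under the area identity; the CSV
columns keep the conventional major/minor naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, unsharp_mask
from skimage.measure import EllipseModel, label, regionprops
from skimage.morphology import skeletonize

from .geometry import EllipseParams, ellipse_mask, parametric_angle, radial_coordinate
from .io import to_grayscale

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseParams",
    "Region",
    "Skeleton",
    "PoreMeasurement",
    "PoreConfig",
    "EllipseFitError",
    "binarize_roi",
    "find_regions",
    "select_pore_region",
    "measure_region",
    "axes_from_area_ecc",
    "skeletonize_regions",
    "prune_spurs",
    "select_skeleton",
    "fit_ellipse",
    "mask_and_measure",
    "measure_pore",
]


class EllipseFitError(ValueError):
    """The skeletal remnant does not support a confident ellipse."""


@dataclass(frozen=True)
class Region:
    """A connected foreground component with its moment summary."""

    coords: np.ndarray  # (N, 2) pixel coordinates, (row, col)
    area_px: int
    centroid: tuple[float, float]
    central_moments: tuple[float, float, float]  # (mu20, mu11, mu02), row/col
    eccentricity: float
    semi_major_px: float  # of the moment-equivalent ellipse
    semi_minor_px: float

    @property
    def fill_ratio(self) -> float:
        """Area relative to the moment-equivalent ellipse; ~1 for solid blobs,
        small for thin curves and rings."""
        denom = np.pi * self.semi_major_px * self.semi_minor_px
        return self.area_px / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class Skeleton:
    """A 1-px-wide skeletal remnant of one connected component."""

    coords: np.ndarray  # (N, 2) int
    length_px: int

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean()))


@dataclass(frozen=True)
class PoreMeasurement:
    """Morphology of one stomatal pore (or a discard record).

    ``major_axis_px``/``minor_axis_px`` are the semi-axis lengths a, b
    satisfying ``π a b = area_px2`` and ``b/a = sqrt(1 - E²)``.
    """

    status: Literal["measured", "discarded"]
    method: Optional[Literal["segmentation", "skeleton"]] = None
    area_px2: Optional[float] = None
    area_um2: Optional[float] = None
    eccentricity: Optional[float] = None
    major_axis_px: Optional[float] = None
    minor_axis_px: Optional[float] = None
    boundary: Optional[np.ndarray] = None  # (N, 2) outline pixels
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "discarded" and self.area_px2 is not None:
            raise ValueError("discarded measurements carry no numeric fields")


@dataclass(frozen=True)
class PoreConfig:
    """Tunables of the measurement engine.

    ``area_max_px`` and ``skeleton_length_bounds`` default to ``None`` and
    are resolved against the ROI size (20% of the ROI area; 0.4–2.2 of the
    ROI side) — pick them from the expected pore size in pixels whenever
    that is known, as one would after glancing at real images.
    """

    area_max_px: Optional[int] = None
    area_min_px: int = 30
    skeleton_length_bounds: Optional[tuple[float, float]] = None
    min_completeness: float = 0.6
    max_fit_residual: float = 0.1
    connectivity: Literal[4, 8] = 8
    threshold_method: str = "otsu"
    sharpen_amount: float = 1.0
    min_fill_ratio: float = 0.85
    mask_dilation_px: float = 3.0
    spur_length_px: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_completeness < 1.0:
            raise ValueError("min_completeness must lie in (0, 1)")
        if self.max_fit_residual <= 0.0:
            raise ValueError("max_fit_residual must be positive")
        if self.skeleton_length_bounds is not None:
            lo, hi = self.skeleton_length_bounds
            if not lo < hi:
                raise ValueError("skeleton_length_bounds must satisfy L_min < L_max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def resolved_for(self, roi_shape: tuple[int, int]) -> "PoreConfig":
        """Fill size-dependent defaults from the ROI dimensions."""
        updates = {}
        if self.area_max_px is None:
            updates["area_max_px"] = int(0.2 * roi_shape[0] * roi_shape[1])
        if self.skeleton_length_bounds is None:
            updates["skeleton_length_bounds"] = (
                0.4 * min(roi_shape),
                2.2 * max(roi_shape),
            )
        return replace(self, **updates) if updates else self


def binarize_roi(roi_image: np.ndarray, config: PoreConfig = PoreConfig()) -> np.ndarray:
    """Sharpen, convert to grayscale and threshold; dark structures = True.

    A constant image yields an all-background result rather than a
    degenerate threshold.
    """
    gray = to_grayscale(roi_image)
    if config.sharpen_amount > 0:
        gray = unsharp_mask(gray, radius=2.0, amount=config.sharpen_amount)
    if np.ptp(gray) < 1e-9:
        return np.zeros(gray.shape, dtype=bool)
    if config.threshold_method == "otsu":
        t = threshold_otsu(gray)
    else:
        t = float(config.threshold_method)
    return gray < t


def find_regions(binary: np.ndarray, connectivity: Literal[4, 8] = 8) -> list[Region]:
    """Connected-component labeling with moment summaries per region."""
    labeled = label(binary, connectivity=1 if connectivity == 4 else 2)
    regions = []
    for props in regionprops(labeled):
        mu = props.moments_central
        regions.append(
            Region(
                coords=props.coords,
                area_px=int(props.area),
                centroid=tuple(map(float, props.centroid)),
                central_moments=(float(mu[2, 0]), float(mu[1, 1]), float(mu[0, 2])),
                eccentricity=float(props.eccentricity),
                semi_major_px=float(props.axis_major_length) / 2.0,
                semi_minor_px=float(props.axis_minor_length) / 2.0,
            )
        )
    return regions


def select_pore_region(
    regions: list[Region],
    roi_center: tuple[float, float],
    config: PoreConfig,
) -> Optional[Region]:
    """Pick the region that looks like the pore: bounded area, solid shape,
    nearest to the ROI center.  ``None`` routes the ROI to the skeleton path.
    """
    if config.area_max_px is None:
        raise ValueError("config.area_max_px unresolved; call resolved_for(roi_shape)")
    candidates = [
        r
        for r in regions
        if config.area_min_px <= r.area_px <= config.area_max_px
        and r.fill_ratio >= config.min_fill_ratio
    ]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: np.hypot(r.centroid[0] - roi_center[0], r.centroid[1] - roi_center[1]),
    )


def axes_from_area_ecc(A: float, E: float) -> tuple[float, float]:
    """Semi-axis lengths (a, b) of the ellipse with area A and eccentricity E."""
    if A <= 0:
        raise ValueError("area must be positive")
    if not 0.0 <= E < 1.0:
        raise ValueError("eccentricity must lie in [0, 1)")
    root = np.sqrt(1.0 - E * E)
    a = float(np.sqrt(A / (np.pi * root)))
    b = float(np.sqrt(A * root / np.pi))
    return a, b


def _outline(coords: np.ndarray) -> np.ndarray:
    """Pixels of a region that touch the outside (8-neighbour sense)."""
    r0, c0 = coords.min(axis=0)
    mask = np.zeros(tuple(coords.max(axis=0) - (r0, c0) + 3), dtype=bool)
    mask[coords[:, 0] - r0 + 1, coords[:, 1] - c0 + 1] = True
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3)))
    rim = mask & ~interior
    rr, cc = np.nonzero(rim)
    return np.column_stack([rr + r0 - 1, cc + c0 - 1])


def measure_region(region: Region, pixel_scale: float) -> PoreMeasurement:
    """Morphology of one region: pixel area, moment eccentricity, and axis
    lengths recomputed from (A, E) so the area identity holds exactly."""
    if region.area_px < 1:
        raise ValueError("region must contain at least one pixel")
    A = float(region.area_px)
    E = 0.0 if region.area_px == 1 else region.eccentricity
    a, b = axes_from_area_ecc(A, E)
    return PoreMeasurement(
        status="measured",
        method="segmentation",
        area_px2=A,
        area_um2=A / pixel_scale**2,
        eccentricity=E,
        major_axis_px=a,
        minor_axis_px=b,
        boundary=_outline(region.coords),
    )


def skeletonize_regions(binary: np.ndarray) -> list[Skeleton]:
    """Thin foreground components to 1-px skeletal remnants.

    Thinning is homotopy-preserving, so a curve that is already 1 px wide is
    returned unchanged; each connected remnant becomes one Skeleton.
    """
    if not binary.any():
        return []
    skel = skeletonize(binary)
    labeled = label(skel, connectivity=2)
    out = []
    for props in regionprops(labeled):
        out.append(Skeleton(coords=props.coords, length_px=int(props.area)))
    return out


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def prune_spurs(skeleton: Skeleton, min_branch_px: int = 5) -> Skeleton:
    """Remove short side branches produced by thinning.

    An endpoint whose path reaches a branch point within ``min_branch_px``
    steps is a spur and is deleted; a plain open curve (no branch points) is
    returned untouched.
    """
    pixels = {tuple(p) for p in skeleton.coords}

    def neighbours(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGHBOURS if (p[0] + dr, p[1] + dc) in pixels]

    changed = True
    while changed:
        changed = False
        degree = {p: len(neighbours(p)) for p in pixels}
        if not any(d >= 3 for d in degree.values()):
            break
        endpoints = [p for p, d in degree.items() if d <= 1]
        for end in endpoints:
            if end not in pixels:
                continue
            path = [end]
            prev, cur = None, end
            while len(path) <= min_branch_px:
                nxt = [q for q in neighbours(cur) if q != prev]
                if not nxt:
                    path = None  # isolated segment, not a spur
                    break
                if degree.get(cur, 0) >= 3 or len(nxt) > 1:
                    path.pop()  # stop before the branch point
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            else:
                path = None  # longer than min_branch_px: a real branch
            if path and degree.get(cur, 0) >= 3 and 0 < len(path) <= min_branch_px:
                for p in path:
                    if p != cur:
                        pixels.discard(p)
                        changed = True
    coords = np.array(sorted(pixels), dtype=int).reshape(-1, 2)
    return Skeleton(coords=coords, length_px=len(coords))


def select_skeleton(
    skeletons: list[Skeleton],
    roi_center: tuple[float, float],
    config: PoreConfig,
) -> Optional[Skeleton]:
    """Pick the remnant with pore-like length nearest the ROI center."""
    if config.skeleton_length_bounds is None:
        raise ValueError("config.skeleton_length_bounds unresolved; call resolved_for")
    lo, hi = config.skeleton_length_bounds
    candidates = [s for s in skeletons if lo <= s.length_px <= hi]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda s: np.hypot(s.centroid[0] - roi_center[0], s.centroid[1] - roi_center[1]),
    )


def fit_ellipse(
    points: np.ndarray,
    min_arc_fraction: Optional[float] = None,
    max_radial_deviation: Optional[float] = None,
) -> EllipseParams:
    """Direct least-squares ellipse fit to (row, col) points.

    Raises :class:`EllipseFitError` for under-determined or degenerate
    input.  Two optional confidence gates also raise: ``min_arc_fraction``
    rejects point sets whose angular coverage around the fitted center
    falls below that fraction of the full turn (badly incomplete
    boundaries), and ``max_radial_deviation`` rejects fits whose points do
    not actually lie on the fitted ellipse (mean |normalized radial
    coordinate − 1| above the bound) — a remnant that is not a boundary
    arc at all, such as the tangled skeleton of a washed-out interior, can
    otherwise satisfy the coverage gate around a shrunken fit.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(np.unique(points, axis=0)) < 5:
        raise EllipseFitError("need at least 5 distinct points to fit an ellipse")
    xy = points[:, ::-1]  # EllipseModel works in (x, y) = (col, row)
    model = EllipseModel.from_estimate(xy)
    if not model:
        raise EllipseFitError("degenerate point set: best-fit conic is not an ellipse")
    params = [*model.center, *model.axis_lengths, model.theta]
    if not np.all(np.isfinite(params)):
        raise EllipseFitError("degenerate point set: best-fit conic is not an ellipse")
    xc, yc, a, b, theta = map(float, params)
    if a <= 0 or b <= 0:
        raise EllipseFitError("degenerate point set: non-positive axis")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    ellipse = EllipseParams(
        center=(yc, xc),
        semi_major_px=a,
        semi_minor_px=b,
        orientation_deg=float(np.rad2deg(theta) % 180.0),
    )
    if max_radial_deviation is not None:
        rho = radial_coordinate(ellipse, points[:, 0], points[:, 1])
        deviation = float(np.mean(np.abs(rho - 1.0)))
        if deviation > max_radial_deviation:
            raise EllipseFitError(
                f"points deviate from the fitted ellipse by {deviation:.2f} "
                f"(mean normalized radius), above the "
                f"{max_radial_deviation:.2f} confidence gate"
            )
    if min_arc_fraction is not None:
        t = np.sort(parametric_angle(ellipse, points[:, 0], points[:, 1]))
        gaps = np.diff(np.concatenate([t, [t[0] + 2.0 * np.pi]]))
        coverage = 1.0 - gaps.max() / (2.0 * np.pi)
        if coverage < min_arc_fraction:
            raise EllipseFitError(
                f"boundary arc covers {coverage:.0%} of the fitted ellipse, "
                f"below the {min_arc_fraction:.0%} confidence gate"
            )
    return ellipse


def mask_and_measure(
    ellipse: EllipseParams,
    roi_image: np.ndarray,
    binary: np.ndarray,
    pixel_scale: float,
    config: PoreConfig,
) -> PoreMeasurement:
    """Measure the pore region inside the fitted ellipse.

    The ellipse (grown by ``mask_dilation_px`` to tolerate the inward bias
    of a boundary-ring skeleton) masks the ROI; within it, pixels already
    dark in the global binary are kept and the remaining pixels are
    re-thresholded locally, which recovers washed-out pore interiors that
    the global threshold missed.  The largest resulting region inside the
    mask, if any survives the area bounds, is the pore.
    """
    if config.area_max_px is None:
        raise ValueError("config.area_max_px unresolved; call resolved_for(roi_shape)")
    grown = EllipseParams(
        ellipse.center,
        ellipse.semi_major_px + config.mask_dilation_px,
        ellipse.semi_minor_px + config.mask_dilation_px,
        ellipse.orientation_deg,
    )
    mask = ellipse_mask(grown, binary.shape)
    if not mask.any():
        return PoreMeasurement(status="discarded", method="skeleton", reason="mask outside ROI")
    gray = to_grayscale(roi_image)
    fg = np.zeros_like(mask)
    fg[mask] = binary[mask]
    rest = mask & ~binary
    if rest.any() and np.ptp(gray[rest]) > 1e-9:
        t_local = threshold_otsu(gray[rest])
        local_dark = rest & (gray < t_local)
        fg |= local_dark
    regions = find_regions(fg, config.connectivity)
    candidates = [r for r in regions if config.area_min_px <= r.area_px <= config.area_max_px]
    if not candidates:
        return PoreMeasurement(
            status="discarded", method="skeleton", reason="no region inside ellipse mask"
        )
    best = max(
        candidates,
        key=lambda r: (
            r.area_px,
            -np.hypot(r.centroid[0] - ellipse.center[0], r.centroid[1] - ellipse.center[1]),
        ),
    )
    measurement = measure_region(best, pixel_scale)
    return replace(measurement, method="skeleton")


def measure_pore(
    roi_image: np.ndarray,
    config: PoreConfig = PoreConfig(),
    pixel_scale: float = 1.0,
) -> PoreMeasurement:
    """Run one ROI through both measurement paths.

    Segmentation first; the skeleton path only runs when segmentation finds
    no acceptable pore region, so ``method='skeleton'`` implies the
    segmentation path declined the ROI.  All failures fold into a discarded
    record with a reason code.
    """
    gray = to_grayscale(roi_image)
    config = config.resolved_for(gray.shape)
    roi_center = ((gray.shape[0] - 1) / 2.0, (gray.shape[1] - 1) / 2.0)

    binary = binarize_roi(gray, config)
    regions = find_regions(binary, config.connectivity)
    region = select_pore_region(regions, roi_center, config)
    if region is not None:
        return measure_region(region, pixel_scale)

    skeletons = [
        prune_spurs(s, config.spur_length_px) for s in skeletonize_regions(binary)
    ]
    skeletons = [s for s in skeletons if s.length_px > 0]
    remnant = select_skeleton(skeletons, roi_center, config)
    if remnant is None:
        return PoreMeasurement(
            status="discarded", method=None, reason="no pore-like region or skeletal remnant"
        )
    try:
        ellipse = fit_ellipse(
            remnant.coords,
            min_arc_fraction=config.min_completeness,
            max_radial_deviation=config.max_fit_residual,
        )
    except EllipseFitError as err:
        logger.debug("ellipse fit rejected: %s", err)
        return PoreMeasurement(status="discarded", method="skeleton", reason=str(err))
    return mask_and_measure(ellipse, gray, binary, pixel_scale, config)
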