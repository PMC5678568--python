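"""Seeded generator of epidermis-like micrographs with per-stoma ground truth.

A rendered scene emulates a light-microscope imprint of a leaf epidermis:
elliptical stomatal pores bounded by a dark boundary ring and a brighter
guard-cell annulus, on a textured background of cell walls, with vein-like
curvilinear ridges and dust blobs as distractors, finished with Gaussian blur
and additive noise.  Every stochastic draw flows from the single seed in
:class:`SceneSpec`, so identical specs give byte-identical scenes.

Image quality is modelled as bimodal, mirroring what imprint micrographs look
like in practice: a ``complete_fraction`` share of stomata are rendered
in-focus (completeness 1.0, dark pore interior), while the remainder are
degraded — the boundary ring is drawn only over a contiguous arc whose
angular fraction equals the drawn ``completeness`` and the pore interior
washes out toward the background.  The washed-out interior is what defeats a
global threshold and routes these stomata to the skeleton measurement path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .geometry import EllipseParams, parametric_angle, radial_coordinate
from .io import Micrograph, DEFAULT_PIXEL_SCALE


@dataclass(frozen=True)
class RenderPalette:
    """Gray levels of the rendered structures (dark features on a light field).

    The convention is dark pore boundaries on a light background; flip or
    rescale these levels to model other stains.
    """

    background: float = 0.72
    cell_wall: float = 0.60
    guard_cell: float = 0.84
    guard_wall: float = 0.64
    pore_ring: float = 0.10
    pore_interior_sharp: float = 0.20
    pore_interior_faded: float = 0.58
    vein: float = 0.20
    dust: float = 0.18


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; the seed makes it reproducible."""

    width_px: int = 768
    height_px: int = 768
    n_stomata: int = 8
    pore_semi_axis_range: tuple[float, float] = (12.0, 35.0)
    aspect_range: tuple[float, float] = (0.55, 0.90)
    completeness_range: tuple[float, float] = (0.65, 0.90)
    complete_fraction: float = 0.5
    n_veins: int = 3
    n_dust: int = 10
    blur_sigma_px: float = 0.9
    noise_sd: float = 0.025
    min_separation_px: float = 110.0
    seed: int = 0
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    palette: RenderPalette = field(default_factory=RenderPalette)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_stomata < 0 or self.n_veins < 0 or self.n_dust < 0:
            raise ValueError("object counts must be non-negative")
        for lo, hi, name in [
            (*self.pore_semi_axis_range, "pore_semi_axis_range"),
            (*self.aspect_range, "aspect_range"),
            (*self.completeness_range, "completeness_range"),
        ]:
            if not lo <= hi:
                raise ValueError(f"{name} must satisfy min <= max")
        if not (0.0 < self.completeness_range[0] and self.completeness_range[1] <= 1.0):
            raise ValueError("completeness_range must lie in (0, 1]")
        if not (0.0 < self.aspect_range[0] and self.aspect_range[1] <= 1.0):
            raise ValueError("aspect_range must lie in (0, 1]")
        if not 0.0 <= self.complete_fraction <= 1.0:
            raise ValueError("complete_fraction must lie in [0, 1]")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_px and noise_sd must be non-negative")
        if self.min_separation_px <= 0:
            raise ValueError("min_separation_px must be positive")


@dataclass(frozen=True)
class GroundTruthStoma:
    """A planted stoma: pore ellipse plus rendered boundary completeness."""

    center: tuple[float, float]
    pore: EllipseParams
    completeness: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0, 1]")


#: Width of the dark pore-boundary ring, drawn inside the pore ellipse so a
#: complete stoma thresholds to exactly the filled pore ellipse.
RING_WIDTH_PX = 3.0
#: The guard-cell annulus extends to this multiple of the pore semi-axes.
GUARD_EXTENT = 1.5
#: Pore interiors of degraded stomata are washed out; a stoma rendered with
#: completeness at or above this value is treated as in-focus.
SHARP_COMPLETENESS = 0.98


def stoma_extent_px(semi_major: float) -> float:
    """Radius (px) of the full rendered stoma footprint around its center."""
    return GUARD_EXTENT * semi_major + 4.0


def render_stoma(
    gt: GroundTruthStoma,
    canvas: np.ndarray,
    palette: RenderPalette = RenderPalette(),
    gap_start_rad: float = 0.0,
) -> np.ndarray:
    """Draw one stoma onto a copy of ``canvas`` and return it.

    The pore boundary is a dark elliptical ring drawn over a contiguous
    parametric arc of angular fraction ``gt.completeness``; the gap (if any)
    starts at ``gap_start_rad``.  A brighter guard-cell annulus surrounds the
    pore.  In-focus stomata (completeness >= 0.98) get a dark pore interior;
    degraded ones get a washed-out interior near the background level.
    """
    pore = gt.pore
    extent = stoma_extent_px(pore.semi_major_px)
    r0, c0 = gt.center
    if (
        r0 - pore.semi_major_px < 0
        or c0 - pore.semi_major_px < 0
        or r0 + pore.semi_major_px > canvas.shape[0]
        or c0 + pore.semi_major_px > canvas.shape[1]
    ):
        raise ValueError("pore ellipse does not fit inside the canvas")

    out = canvas.copy()
    lo_r = max(0, int(math.floor(r0 - extent)))
    hi_r = min(canvas.shape[0], int(math.ceil(r0 + extent)) + 1)
    lo_c = max(0, int(math.floor(c0 - extent)))
    hi_c = min(canvas.shape[1], int(math.ceil(c0 + extent)) + 1)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]

    guard = EllipseParams(
        gt.center,
        GUARD_EXTENT * pore.semi_major_px + 2.0,
        GUARD_EXTENT * pore.semi_minor_px + 2.0,
        pore.orientation_deg,
    )
    inner_ring = EllipseParams(
        gt.center,
        max(pore.semi_major_px - RING_WIDTH_PX, 1.0),
        max(pore.semi_minor_px - RING_WIDTH_PX, 0.5),
        pore.orientation_deg,
    )

    rho_pore = radial_coordinate(pore, rr, cc)
    rho_inner = radial_coordinate(inner_ring, rr, cc)
    rho_guard = radial_coordinate(guard, rr, cc)

    patch = out[lo_r:hi_r, lo_c:hi_c]

    # Guard-cell annulus with a subtle outer wall edge.
    annulus = (rho_pore > 1.0) & (rho_guard <= 1.0)
    patch[annulus] = palette.guard_cell
    patch[annulus & (rho_guard > 0.93)] = palette.guard_wall

    # Pore interior.
    interior = rho_pore <= 1.0
    sharp = gt.completeness >= SHARP_COMPLETENESS
    patch[interior] = (
        palette.pore_interior_sharp if sharp else palette.pore_interior_faded
    )

    # Boundary ring: the band between the shrunken ellipse and the pore
    # ellipse, restricted to a contiguous parametric arc.
    ring = interior & (rho_inner > 1.0)
    if gt.completeness < 1.0:
        t = parametric_angle(pore, rr, cc)
        gap = 2.0 * np.pi * (1.0 - gt.completeness)
        rel = np.mod(t - gap_start_rad, 2.0 * np.pi)
        ring &= rel >= gap
    patch[ring] = palette.pore_ring
    return out


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Cell-mosaic texture: smoothed low-frequency shading + wall segments."""
    h, w = spec.height_px, spec.width_px
    img = np.full((h, w), spec.palette.background)
    shading = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=24.0)
    sd = shading.std()
    if sd > 0:
        img += 0.035 * shading / sd

    # Polygonal cell walls: jittered grid nodes joined by their neighbors.
    step = 56
    nr, nc = h // step + 2, w // step + 2
    nodes_r = (np.arange(nr)[:, None] * step + rng.uniform(-18, 18, (nr, nc))).ravel()
    nodes_c = (np.arange(nc)[None, :] * step + rng.uniform(-18, 18, (nr, nc))).ravel()
    idx = np.arange(nr * nc).reshape(nr, nc)
    pairs = []
    pairs += [(idx[i, j], idx[i + 1, j]) for i in range(nr - 1) for j in range(nc)]
    pairs += [(idx[i, j], idx[i, j + 1]) for i in range(nr) for j in range(nc - 1)]
    wall = np.zeros((h, w), dtype=bool)
    for a, b in pairs:
        n = int(max(abs(nodes_r[a] - nodes_r[b]), abs(nodes_c[a] - nodes_c[b]))) + 1
        rows = np.linspace(nodes_r[a], nodes_r[b], n).round().astype(int)
        cols = np.linspace(nodes_c[a], nodes_c[b], n).round().astype(int)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        wall[rows[ok], cols[ok]] = True
    img[wall] = spec.palette.cell_wall
    return img


def _draw_vein(
    img: np.ndarray,
    spec: SceneSpec,
    rng: np.random.Generator,
    keepout_centers: np.ndarray,
    keepout_radii: np.ndarray,
) -> None:
    """Paint one curvilinear dark ridge, skipping stoma keep-out zones."""
    h, w = img.shape
    p0 = rng.uniform([0, 0], [h, w])
    p2 = rng.uniform([0, 0], [h, w])
    mid = 0.5 * (p0 + p2) + rng.uniform(-0.35, 0.35) * (p2 - p0)[::-1] * [1, -1]
    t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p2
    if keepout_centers.size:
        d = np.hypot(
            pts[:, 0, None] - keepout_centers[None, :, 0],
            pts[:, 1, None] - keepout_centers[None, :, 1],
        )
        pts = pts[(d > keepout_radii[None, :]).all(axis=1)]
    half = 2
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if dr * dr + dc * dc > half * half + 1:
                continue
            rows = np.clip(pts[:, 0].round().astype(int) + dr, 0, h - 1)
            cols = np.clip(pts[:, 1].round().astype(int) + dc, 0, w - 1)
            img[rows, cols] = spec.palette.vein


def render_scene(spec: SceneSpec) -> tuple[Micrograph, list[GroundTruthStoma]]:
    """Render a full scene and its ground-truth stoma list.

    Stomata are placed by rejection sampling so all pairwise center distances
    are at least ``min_separation_px``; placement failure after bounded
    retries raises a ``RuntimeError`` naming the constraint.
    """
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    h, w = img.shape

    stomata: list[GroundTruthStoma] = []
    gap_starts: list[float] = []
    centers = np.empty((0, 2))
    max_attempts = 200 * max(1, spec.n_stomata)
    attempts = 0
    while len(stomata) < spec.n_stomata:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_stomata} stomata with "
                f"min_separation_px={spec.min_separation_px} in a "
                f"{w}x{h} scene after {max_attempts} attempts"
            )
        attempts += 1
        sa = rng.uniform(*spec.pore_semi_axis_range)
        aspect = rng.uniform(*spec.aspect_range)
        sb = max(sa * aspect, 1.0)
        margin = stoma_extent_px(sa) + 2.0
        if 2 * margin >= min(h, w):
            raise RuntimeError("scene too small for the requested stoma size")
        center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        orientation = rng.uniform(0.0, 180.0)
        if rng.uniform() < spec.complete_fraction:
            completeness = 1.0
        else:
            completeness = rng.uniform(*spec.completeness_range)
        gap_start = rng.uniform(0.0, 2.0 * np.pi)
        if centers.size and (
            np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1]).min()
            < spec.min_separation_px
        ):
            continue
        stomata.append(
            GroundTruthStoma(
                center=center,
                pore=EllipseParams(center, sa, sb, orientation),
                completeness=completeness,
                orientation_deg=orientation,
            )
        )
        gap_starts.append(gap_start)
        centers = np.vstack([centers, center])

    keepout_r = np.array([stoma_extent_px(s.pore.semi_major_px) + 4 for s in stomata])
    for _ in range(spec.n_veins):
        _draw_vein(img, spec, rng, centers, keepout_r)

    for _ in range(spec.n_dust):
        for _attempt in range(50):
            pos = rng.uniform([0, 0], [h, w])
            radius = rng.uniform(2.0, 5.0)
            if not centers.size or (
                np.hypot(centers[:, 0] - pos[0], centers[:, 1] - pos[1]) > keepout_r + radius
            ).all():
                r_lo = max(0, int(pos[0] - radius - 1))
                r_hi = min(h, int(pos[0] + radius + 2))
                c_lo = max(0, int(pos[1] - radius - 1))
                c_hi = min(w, int(pos[1] + radius + 2))
                rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
                sub = img[r_lo:r_hi, c_lo:c_hi]
                sub[np.hypot(rr - pos[0], cc - pos[1]) <= radius] = spec.palette.dust
                break

    for gt, gap_start in zip(stomata, gap_starts):
        img = render_stoma(gt, img, spec.palette, gap_start)

    if spec.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return Micrograph(img, spec.pixel_scale, f"synthetic-{spec.seed}"), stomata


#: Positive training crops span this multiple of the pore semi-major axis on
#: each side of the center, so every stoma lands at the same relative size
#: once resampled to the detector window.
POSITIVE_CROP_FACTOR = 1.6
#: Side of negative training patches; larger than the detector window so the
#: cascade can bootstrap many negative sub-windows from each patch.
NEGATIVE_PATCH_PX = 192


def ground_truth_frame(stomata: list[GroundTruthStoma], scene_id: str) -> pd.DataFrame:
    """Tabulate ground truth with the documented CSV columns."""
    return pd.DataFrame(
        [
            {
                "scene_id": scene_id,
                "stoma_id": i,
                "row": s.center[0],
                "col": s.center[1],
                "semi_major_px": s.pore.semi_major_px,
                "semi_minor_px": s.pore.semi_minor_px,
                "orientation_deg": s.orientation_deg,
                "completeness": s.completeness,
            }
            for i, s in enumerate(stomata)
        ]
    )


def positive_crop(image: np.ndarray, gt: GroundTruthStoma) -> np.ndarray:
    """Square crop around one stoma, side proportional to its semi-major axis."""
    half = int(round(POSITIVE_CROP_FACTOR * gt.pore.semi_major_px))
    r, c = int(round(gt.center[0])), int(round(gt.center[1]))
    r_lo, r_hi = max(0, r - half), min(image.shape[0], r + half)
    c_lo, c_hi = max(0, c - half), min(image.shape[1], c + half)
    return image[r_lo:r_hi, c_lo:c_hi].copy()


def make_training_set(
    spec: SceneSpec, n_pos: int = 550, n_neg: int = 210
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Build detector training patches from freshly rendered scenes.

    Positives each contain exactly one centered stoma (crop side proportional
    to the stoma size); negatives are larger stoma-free patches of
    background, veins and dust.  Defaults mirror a 550/210 split.

    Negative sampling prefers patches that actually contain dark distractor
    features (veins, dust): at most ~30% plain-background patches are kept,
    so the detector trains against the structures it must reject rather
    than against empty texture.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    max_plain = max(1, int(0.3 * n_neg))
    seeds = np.random.SeedSequence(spec.seed).generate_state(10_000)
    positives: list[np.ndarray] = []
    negatives: list[np.ndarray] = []
    n_plain = 0
    scene_idx = 0
    neg_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA5]).generate_state(1)[0])
    while len(positives) < n_pos or len(negatives) < n_neg:
        scene_spec = replace(spec, seed=int(seeds[scene_idx] % (2**31 - 1)))
        scene_idx += 1
        micrograph, stomata = render_scene(scene_spec)
        img = micrograph.pixels
        for gt in stomata:
            if len(positives) < n_pos:
                positives.append(positive_crop(img, gt))
        # Stoma-free patches for the negative set.
        centers = np.array([s.center for s in stomata]).reshape(-1, 2)
        radii = np.array([stoma_extent_px(s.pore.semi_major_px) for s in stomata])
        side = NEGATIVE_PATCH_PX
        per_scene = 0
        for _ in range(200):
            if len(negatives) >= n_neg or per_scene >= max(2, n_neg // 8):
                break
            r = neg_rng.integers(0, img.shape[0] - side + 1)
            c = neg_rng.integers(0, img.shape[1] - side + 1)
            if centers.size:
                # Distance from each stoma center to the patch rectangle.
                dr = np.maximum(0, np.maximum(r - centers[:, 0], centers[:, 0] - (r + side)))
                dc = np.maximum(0, np.maximum(c - centers[:, 1], centers[:, 1] - (c + side)))
                if (np.hypot(dr, dc) < radii).any():
                    continue
            patch = img[r : r + side, c : c + side]
            feature_rich = (patch < 0.4).mean() > 0.002
            if not feature_rich:
                if n_plain >= max_plain:
                    continue
                n_plain += 1
            negatives.append(patch.copy())
            per_scene += 1
    return positives, negatives
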