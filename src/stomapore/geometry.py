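"""Ellipse primitives shared by the renderer and the morphometry engine."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EllipseParams:
    """An ellipse in image coordinates.

    ``center`` is ``(row, col)``; ``orientation_deg`` is the angle of the
    major axis measured from the column (x) axis toward the row (y) axis.
    """

    center: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_major_px >= self.semi_minor_px > 0):
            raise ValueError("require semi_major_px >= semi_minor_px > 0")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major_px * self.semi_minor_px)

    @property
    def eccentricity(self) -> float:
        ratio = self.semi_minor_px / self.semi_major_px
        return float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))


def ellipse_frame(ellipse: EllipseParams, rows: np.ndarray, cols: np.ndarray):
    """Map image coordinates into the ellipse-aligned frame.

    Returns ``(u, v)`` where ``u`` runs along the major axis and ``v`` along
    the minor axis, both in pixels.
    """
    theta = np.deg2rad(ellipse.orientation_deg)
    dr = rows - ellipse.center[0]
    dc = cols - ellipse.center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return u, v


def radial_coordinate(ellipse: EllipseParams, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Normalized elliptical radius: 1.0 on the ellipse, <1 inside."""
    u, v = ellipse_frame(ellipse, rows, cols)
    return np.sqrt((u / ellipse.semi_major_px) ** 2 + (v / ellipse.semi_minor_px) ** 2)


def parametric_angle(ellipse: EllipseParams, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Parametric angle t of the nearest ray, in [0, 2π)."""
    u, v = ellipse_frame(ellipse, rows, cols)
    t = np.arctan2(v / ellipse.semi_minor_px, u / ellipse.semi_major_px)
    return np.mod(t, 2.0 * np.pi)


def ellipse_mask(ellipse: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the ellipse interior on an image of ``shape``."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return radial_coordinate(ellipse, rr, cc) <= 1.0


def ellipse_points(ellipse: EllipseParams, n: int, t0: float = 0.0, t1: float = 2.0 * np.pi) -> np.ndarray:
    """Sample ``n`` (row, col) points on the arc with parameter t ∈ [t0, t1]."""
    t = np.linspace(t0, t1, n)
    theta = np.deg2rad(ellipse.orientation_deg)
    u = ellipse.semi_major_px * np.cos(t)
    v = ellipse.semi_minor_px * np.sin(t)
    rows = ellipse.center[0] + u * np.sin(theta) + v * np.cos(theta)
    cols = ellipse.center[1] + u * np.cos(theta) - v * np.sin(theta)
    return np.column_stack([rows, cols])
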