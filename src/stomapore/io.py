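"""File formats and the in-memory image container.

All tabular outputs are plain CSV with documented headers; coordinates are
0-based ``(row, col)`` and boxes are half-open ``(row0, col0, row1, col1)``.
Images are 8-bit grayscale PNG (or TIFF) on disk and ``float64`` arrays in
``[0, 1]`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

#: Default magnification of the target micrographs, in pixels per micrometre.
DEFAULT_PIXEL_SCALE = 8.6

GROUND_TRUTH_COLUMNS = [
    "scene_id",
    "stoma_id",
    "row",
    "col",
    "semi_major_px",
    "semi_minor_px",
    "orientation_deg",
    "completeness",
]

DETECTION_COLUMNS = ["image_id", "row0", "col0", "row1", "col1", "score"]

MEASUREMENT_COLUMNS = [
    "image_id",
    "roi_id",
    "status",
    "method",
    "area_px2",
    "area_um2",
    "major_axis_px",
    "minor_axis_px",
    "eccentricity",
]


@dataclass
class Micrograph:
    """A grayscale micrograph plus its physical pixel scale.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with intensities in ``[0, 1]``.
    pixel_scale : float
        Magnification in pixels per micrometre (px/µm).
    image_id : str
        Identifier used in output tables.
    """

    pixels: np.ndarray
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    image_id: str = "image"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be a 2-D grayscale array")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive (px/µm)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an image array to float64 grayscale in [0, 1].

    RGB(A) input is reduced with the Rec. 601 luminance weights; integer
    input is rescaled by its dtype maximum.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(pixels).dtype, np.integer):
        arr = arr / np.iinfo(np.asarray(pixels).dtype).max
    return np.clip(arr, 0.0, 1.0)


def load_micrograph(
    path: str | Path,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
    image_id: str | None = None,
) -> Micrograph:
    """Read a PNG/TIFF micrograph from disk (RGB collapsed to luminance)."""
    path = Path(path)
    pixels = to_grayscale(iio.imread(path))
    return Micrograph(pixels, pixel_scale, image_id or path.stem)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a float [0, 1] image as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_ground_truth_csv(path: str | Path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False, columns=GROUND_TRUTH_COLUMNS)


def read_ground_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections_csv(path: str | Path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False, columns=DETECTION_COLUMNS)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measurements_csv(path: str | Path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
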