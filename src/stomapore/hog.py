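"""Histogram-of-oriented-gradients descriptor on a cell grid.

The descriptor follows the classic construction: per-pixel gradients
(centred differences), unsigned orientation binned over [0°, 180°) with hard
assignment, magnitude-weighted cell histograms, and L2 block normalization
over ``block_cells x block_cells`` neighbourhoods with an epsilon guard.

The grid form (:class:`CellHogGrid`) computes cell histograms and block
norms once for a whole image; a window descriptor is then just a slice, and
single features can be gathered for thousands of windows at once.  This is
what makes cascade sliding-window detection cheap: each boosted stump needs
one feature per window, not the full vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HOGParams:
    """Descriptor geometry; the feature length is fixed by these fields."""

    window_px: tuple[int, int] = (96, 96)
    cell_px: int = 8
    block_cells: int = 2
    n_orientation_bins: int = 9
    normalization_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.window_px[0] % self.cell_px or self.window_px[1] % self.cell_px:
            raise ValueError("window dimensions must be divisible by cell_px")
        if self.block_cells < 1 or self.n_orientation_bins < 1:
            raise ValueError("block_cells and n_orientation_bins must be >= 1")
        if self.normalization_epsilon <= 0:
            raise ValueError("normalization_epsilon must be positive")

    @property
    def cells_per_window(self) -> tuple[int, int]:
        return (self.window_px[0] // self.cell_px, self.window_px[1] // self.cell_px)

    @property
    def blocks_per_window(self) -> tuple[int, int]:
        cr, cc = self.cells_per_window
        return (cr - self.block_cells + 1, cc - self.block_cells + 1)

    @property
    def n_features(self) -> int:
        br, bc = self.blocks_per_window
        return br * bc * self.block_cells**2 * self.n_orientation_bins

    def feature_components(self, index: np.ndarray | int):
        """Decompose feature indices into (block_r, block_c, cell_r, cell_c, bin)."""
        index = np.asarray(index)
        nb = self.n_orientation_bins
        k = self.block_cells
        _, bc_n = self.blocks_per_window
        o_bin = index % nb
        rest = index // nb
        cj = rest % k
        rest = rest // k
        ci = rest % k
        rest = rest // k
        bcol = rest % bc_n
        brow = rest // bc_n
        return brow, bcol, ci, cj, o_bin


class CellHogGrid:
    """Cell histograms and block norms for one image at one scale."""

    def __init__(self, image: np.ndarray, params: HOGParams):
        self.params = params
        image = np.asarray(image, dtype=np.float64)
        cell = params.cell_px
        n_cr, n_cc = image.shape[0] // cell, image.shape[1] // cell
        if n_cr < 1 or n_cc < 1:
            raise ValueError("image smaller than one cell")
        image = image[: n_cr * cell, : n_cc * cell]

        gr, gc = np.gradient(image)
        magnitude = np.hypot(gr, gc)
        angle = np.mod(np.rad2deg(np.arctan2(gr, gc)), 180.0)
        bins = np.minimum(
            (angle / 180.0 * params.n_orientation_bins).astype(np.intp),
            params.n_orientation_bins - 1,
        )

        cell_r = (np.arange(image.shape[0]) // cell)[:, None]
        cell_c = (np.arange(image.shape[1]) // cell)[None, :]
        flat = (cell_r * n_cc + cell_c) * params.n_orientation_bins + bins
        hist = np.bincount(
            flat.ravel(), weights=magnitude.ravel(), minlength=n_cr * n_cc * params.n_orientation_bins
        )
        self.hist = hist.reshape(n_cr, n_cc, params.n_orientation_bins)
        self.n_cells = (n_cr, n_cc)

        k = params.block_cells
        sq = (self.hist**2).sum(axis=2)
        nbr, nbc = n_cr - k + 1, n_cc - k + 1
        if nbr < 1 or nbc < 1:
            raise ValueError("image smaller than one block")
        block_sq = np.zeros((nbr, nbc))
        for i in range(k):
            for j in range(k):
                block_sq += sq[i : i + nbr, j : j + nbc]
        self.block_norms = np.sqrt(block_sq + params.normalization_epsilon**2)

    def window_positions(self, stride_cells: int = 1) -> np.ndarray:
        """All (cell_row, cell_col) positions where a full window fits."""
        wr, wc = self.params.cells_per_window
        rows = np.arange(0, self.n_cells[0] - wr + 1, stride_cells)
        cols = np.arange(0, self.n_cells[1] - wc + 1, stride_cells)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def window_vector(self, cell_row: int, cell_col: int) -> np.ndarray:
        """Full block-normalized descriptor of the window at a cell position."""
        p = self.params
        k = p.block_cells
        nbr, nbc = p.blocks_per_window
        out = np.empty((nbr, nbc, k, k, p.n_orientation_bins))
        for i in range(nbr):
            for j in range(nbc):
                block = self.hist[cell_row + i : cell_row + i + k, cell_col + j : cell_col + j + k]
                out[i, j] = block / self.block_norms[cell_row + i, cell_col + j]
        return out.ravel()

    def window_energies(self, positions: np.ndarray) -> np.ndarray:
        """Total gradient magnitude inside each window (summed-area lookup)."""
        wr, wc = self.params.cells_per_window
        energy = self.hist.sum(axis=2)
        sat = np.zeros((energy.shape[0] + 1, energy.shape[1] + 1))
        sat[1:, 1:] = energy.cumsum(axis=0).cumsum(axis=1)
        r = positions[:, 0]
        c = positions[:, 1]
        return sat[r + wr, c + wc] - sat[r, c + wc] - sat[r + wr, c] + sat[r, c]

    def gather_feature(self, positions: np.ndarray, feature_index: int) -> np.ndarray:
        """Value of one feature for many windows; positions is (N, 2) cells."""
        brow, bcol, ci, cj, o_bin = self.params.feature_components(feature_index)
        rows = positions[:, 0]
        cols = positions[:, 1]
        values = self.hist[rows + brow + ci, cols + bcol + cj, o_bin]
        norms = self.block_norms[rows + brow, cols + bcol]
        return values / norms


def compute_hog(patch: np.ndarray, params: HOGParams) -> np.ndarray:
    """Descriptor of a single window-sized patch.

    Raises ``ValueError`` when the patch does not match ``params.window_px``.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != tuple(params.window_px):
        raise ValueError(f"patch shape {patch.shape} != window {params.window_px}")
    return CellHogGrid(patch, params).window_vector(0, 0)
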