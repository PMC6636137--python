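"""Sorting-sheet geometry.

The physical unit of the cell-based subsampling methods is one rectangle
of a 5 x 5 grid printed on an A4 sheet (210 x 297 mm).  Cells are exact
fifths of the sheet, 42.0 x 59.4 mm, numbered 1-25 in files (row-major,
left to right, top to bottom) and 0-24 internally; the conversion is
confined to the I/O layer.
"""

from __future__ import annotations

import numpy as np

SHEET_WIDTH_MM: float = 210.0
SHEET_HEIGHT_MM: float = 297.0
GRID_ROWS: int = 5
GRID_COLS: int = 5
N_CELLS: int = GRID_ROWS * GRID_COLS
CELL_WIDTH_MM: float = SHEET_WIDTH_MM / GRID_COLS  # 42.0
CELL_HEIGHT_MM: float = SHEET_HEIGHT_MM / GRID_ROWS  # 59.4

__all__ = [
    "SHEET_WIDTH_MM",
    "SHEET_HEIGHT_MM",
    "GRID_ROWS",
    "GRID_COLS",
    "N_CELLS",
    "CELL_WIDTH_MM",
    "CELL_HEIGHT_MM",
    "cell_rect",
    "cell_of",
    "peripheral_cells",
    "place_points",
]


def cell_rect(cell: int) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) in mm of 0-based ``cell``."""
    if not 0 <= cell < N_CELLS:
        raise ValueError(f"cell must be in 0..{N_CELLS - 1}, got {cell}")
    row, col = divmod(cell, GRID_COLS)
    x0 = col * CELL_WIDTH_MM
    y0 = row * CELL_HEIGHT_MM
    return x0, y0, x0 + CELL_WIDTH_MM, y0 + CELL_HEIGHT_MM


def cell_of(x, y):
    """0-based cell id(s) containing sheet coordinates (mm); vectorised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x < 0) | (x > SHEET_WIDTH_MM) | (y < 0) | (y > SHEET_HEIGHT_MM)):
        raise ValueError("coordinates outside the sheet")
    col = np.minimum((x / CELL_WIDTH_MM).astype(int), GRID_COLS - 1)
    row = np.minimum((y / CELL_HEIGHT_MM).astype(int), GRID_ROWS - 1)
    out = row * GRID_COLS + col
    return int(out) if out.ndim == 0 else out


def peripheral_cells() -> np.ndarray:
    """The 16 border cells of the 5 x 5 grid (0-based ids)."""
    ids = []
    for cell in range(N_CELLS):
        row, col = divmod(cell, GRID_COLS)
        if row in (0, GRID_ROWS - 1) or col in (0, GRID_COLS - 1):
            ids.append(cell)
    return np.array(ids, dtype=int)


def place_points(n_points: int, seed: int) -> np.ndarray:
    """Uniform random points on the sheet, as an (n, 2) array of (x, y) mm.

    Emulates the printed sheet's 200 randomly distributed selection points.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.0, 0.0], [SHEET_WIDTH_MM, SHEET_HEIGHT_MM], size=(n_points, 2))
    return pts
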