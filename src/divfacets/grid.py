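"""Regular analysis grid in projected planar coordinates.

Cells are squares of side ``cell_size_km`` laid out row-major with row 0 the
northernmost row.  Cell ids run 0 .. n_rows*n_cols - 1.  Coordinates are
planar kilometres; ``origin`` is the lower-left (south-west) corner of the
whole extent.  Cell squares are half-open, [x0, x0+s) x [y0, y0+s), so every
boundary point belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    n_rows: int
    n_cols: int
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the whole grid, km."""
        x0, y0 = self.origin
        s = self.cell_size_km
        return (x0, y0, x0 + self.n_cols * s, y0 + self.n_rows * s)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def row_col(self, cell_id: int) -> tuple[int, int]:
        if not (0 <= cell_id < self.n_cells):
            raise IndexError(f"cell id {cell_id} outside grid")
        return divmod(cell_id, self.n_cols)

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of one cell square; row 0 is the northern edge."""
        row, col = self.row_col(cell_id)
        x0, y0 = self.origin
        s = self.cell_size_km
        cx0 = x0 + col * s
        cy0 = y0 + (self.n_rows - 1 - row) * s
        return (cx0, cy0, cx0 + s, cy0 + s)

    def centroid(self, cell_id: int) -> tuple[float, float]:
        cx0, cy0, cx1, cy1 = self.cell_bounds(cell_id)
        return ((cx0 + cx1) / 2.0, (cy0 + cy1) / 2.0)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell centroids in id order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x0, y0 = self.origin
        s = self.cell_size_km
        x = x0 + (cols + 0.5) * s
        y = y0 + (self.n_rows - rows - 0.5) * s
        return np.column_stack([x, y])

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size_km": self.cell_size_km,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size_km=float(d["cell_size_km"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
        )
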