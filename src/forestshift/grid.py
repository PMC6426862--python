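"""Planar analysis grid of square cells (default 5 km, i.e. 25 km^2)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class Grid:
    """Regular grid in a planar km coordinate system.

    The origin is the southwest corner; cell ids run row-major from the
    southwest cell (id = iy * n_x + ix).
    """

    n_x: int
    n_y: int
    cell_size_km: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1 or self.cell_size_km <= 0:
            raise ValueError("grid dimensions and cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def cell_id(self, x, y):
        """Cell containing each (x, y) point; -1 for points off the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.cell_size_km).astype(int)
        iy = np.floor((y - self.origin[1]) / self.cell_size_km).astype(int)
        # points exactly on the north/east boundary belong to the last cell
        ix = np.where((x - self.origin[0]) == self.n_x * self.cell_size_km, self.n_x - 1, ix)
        iy = np.where((y - self.origin[1]) == self.n_y * self.cell_size_km, self.n_y - 1, iy)
        inside = (ix >= 0) & (ix < self.n_x) & (iy >= 0) & (iy < self.n_y)
        return np.where(inside, iy * self.n_x + ix, -1)

    def centroids(self) -> pd.DataFrame:
        """Cell centroid coordinates (km), indexed by cell id."""
        ids = np.arange(self.n_cells)
        ix = ids % self.n_x
        iy = ids // self.n_x
        return pd.DataFrame(
            {
                "x": self.origin[0] + (ix + 0.5) * self.cell_size_km,
                "y": self.origin[1] + (iy + 0.5) * self.cell_size_km,
            },
            index=pd.Index(ids, name="cell"),
        )

    def adjacency(self) -> sparse.csr_matrix:
        """Rook adjacency (shared edges) between cells as a sparse matrix."""
        ids = np.arange(self.n_cells)
        ix = ids % self.n_x
        iy = ids // self.n_x
        rows, cols = [], []
        for dx, dy in ((1, 0), (0, 1)):
            ok = (ix + dx < self.n_x) & (iy + dy < self.n_y)
            a = ids[ok]
            b = (iy[ok] + dy) * self.n_x + (ix[ok] + dx)
            rows += [a, b]
            cols += [b, a]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        return sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(self.n_cells, self.n_cells)
        )
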