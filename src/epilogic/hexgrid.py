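"""Cylindrical hexagonal grid.

Cells are addressed as ``(row, col)`` in 0-based "odd-r" offset coordinates:
odd rows are shifted half a cell to the right.  Rows run along the
anterior->posterior axis (row 0 = anterior) and do not wrap; columns run
around the circumference and wrap modulo ``n_cols`` (the grid is a cylinder).
Interior cells have exactly six distance-1 neighbors; cells on the anterior
and posterior border rows have fewer.

::

      (0,0)   (0,1)   (0,2)   (0,3)        row 0 (anterior)
          (1,0)   (1,1)   (1,2)   (1,3)    row 1 (odd: shifted right)
      (2,0)   (2,1)   (2,2)   (2,3)        row 2
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

__all__ = ["HexGrid"]

# odd-r offset neighbor deltas, keyed by row parity
_DELTAS_EVEN = ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0))
_DELTAS_ODD = ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class HexGrid:
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 3:
            raise ValueError("grid needs n_rows >= 1 and n_cols >= 3")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cells(self):
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield (r, c)

    def contains(self, cell) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def _check(self, cell):
        if not self.contains(cell):
            raise ValueError(f"cell {cell} is off the {self.n_rows}x{self.n_cols} grid")

    def adjacent(self, cell) -> tuple:
        """The (up to 6) distance-1 neighbors, with column wrap-around."""
        self._check(cell)
        r, c = cell
        deltas = _DELTAS_ODD if r % 2 else _DELTAS_EVEN
        out = []
        for dr, dc in deltas:
            nr = r + dr
            if 0 <= nr < self.n_rows:
                out.append((nr, (c + dc) % self.n_cols))
        return tuple(out)

    @lru_cache(maxsize=None)
    def _rings(self, cell, k: int) -> tuple:
        """Cells at hex distance 1..k (BFS on the adjacency relation)."""
        seen = {cell}
        frontier = [cell]
        out = []
        for _ in range(k):
            nxt = []
            for x in frontier:
                for y in self.adjacent(x):
                    if y not in seen:
                        seen.add(y)
                        nxt.append(y)
            out.extend(nxt)
            frontier = nxt
        return tuple(out)

    def neighbors(self, cell, distance: int = 1) -> tuple:
        """All cells within hex distance <= ``distance``, excluding ``cell``."""
        if distance < 1:
            raise ValueError("distance must be >= 1")
        self._check(cell)
        return self._rings(cell, distance)

    def distance(self, a, b) -> int:
        """Hex distance on the cylinder (minimum over the column wrap)."""
        self._check(a)
        self._check(b)
        best = None
        for shift in (-self.n_cols, 0, self.n_cols):
            d = self._axial_distance(a, (b[0], b[1] + shift))
            best = d if best is None else min(best, d)
        return best

    @staticmethod
    def _axial_distance(a, b) -> int:
        # odd-r offset -> axial (q, r), then standard hex distance
        aq = a[1] - (a[0] - (a[0] % 2)) // 2
        bq = b[1] - (b[0] - (b[0] % 2)) // 2
        dq, dr = bq - aq, b[0] - a[0]
        return max(abs(dq), abs(dr), abs(dq + dr))
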