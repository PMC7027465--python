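"""Uniform-grid spatial index on the torus (internal).

Cell size is at least the query radius, so a fixed-radius neighbourhood
query only needs the 3x3 block of cells around the query point (with
periodic wrap).  Callers must still filter candidates by torus distance.
"""

from __future__ import annotations


class SpatialGrid:
    """Bucket grid for points on a V x V torus, for radius-limited queries."""

    __slots__ = ("V", "n", "cell", "buckets", "_neigh")

    def __init__(self, V: float, radius: float):
        self.V = V
        self.n = max(1, int(V / max(radius, 1e-12)))
        self.cell = V / self.n
        self.buckets: dict[int, list] = {}
        self._neigh: dict[int, tuple] = {}

    def _index(self, x: float, y: float) -> int:
        n = self.n
        ix = int(x / self.cell)
        iy = int(y / self.cell)
        if ix >= n:
            ix = n - 1
        if iy >= n:
            iy = n - 1
        return ix * n + iy

    def insert(self, item, x: float, y: float) -> None:
        self.buckets.setdefault(self._index(x, y), []).append(item)

    def remove(self, item, x: float, y: float) -> None:
        self.buckets[self._index(x, y)].remove(item)

    def _neighbours(self, idx: int) -> tuple:
        cached = self._neigh.get(idx)
        if cached is not None:
            return cached
        n = self.n
        ix, iy = divmod(idx, n)
        cells = set()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                cells.add(((ix + dx) % n) * n + ((iy + dy) % n))
        out = tuple(cells)
        self._neigh[idx] = out
        return out

    def query(self, x: float, y: float):
        """Iterate items in the 3x3 cell block around (x, y)."""
        buckets = self.buckets
        for c in self._neighbours(self._index(x, y)):
            b = buckets.get(c)
            if b:
                yield from b
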