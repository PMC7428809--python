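"""Axial-coordinate hexagonal grid geometry.

The tissue is a flat (non-periodic) hexagonal lattice of crypt slots laid
out as an axial-coordinate parallelogram: ``q`` runs over columns
``0..grid_cols-1`` and ``r`` over rows ``0..grid_rows-1``.  Edge slots
simply have fewer neighbors; there is no wrap-around.  The six axial
neighbor offsets are ``(+1,0), (-1,0), (0,+1), (0,-1), (+1,-1), (-1,+1)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AXIAL_OFFSETS", "grid_coordinates", "in_grid", "neighbors",
           "hex_distance", "neighbor_csr"]

#: The six axial-direction offsets of a hex lattice.
AXIAL_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1),
)

HexCoordinate = tuple[int, int]


def grid_coordinates(grid_rows: int, grid_cols: int) -> list[HexCoordinate]:
    """All slot coordinates (q, r), row-major: slot index = r*cols + q."""
    return [(q, r) for r in range(grid_rows) for q in range(grid_cols)]


def in_grid(c: HexCoordinate, grid_rows: int, grid_cols: int) -> bool:
    q, r = c
    return 0 <= q < grid_cols and 0 <= r < grid_rows


def neighbors(c: HexCoordinate, grid_rows: int, grid_cols: int) -> set[HexCoordinate]:
    """The <= 6 axial neighbors of ``c`` that lie within the grid.

    Raises ValueError if ``c`` itself is outside the grid.
    """
    if not in_grid(c, grid_rows, grid_cols):
        raise ValueError(f"coordinate {c} outside {grid_rows}x{grid_cols} grid")
    q, r = c
    return {
        (q + dq, r + dr)
        for dq, dr in AXIAL_OFFSETS
        if in_grid((q + dq, r + dr), grid_rows, grid_cols)
    }


def hex_distance(a: HexCoordinate, b: HexCoordinate) -> int:
    """Axial hex lattice distance (|dq| + |dr| + |dq+dr|) / 2."""
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def slot_index(c: HexCoordinate, grid_rows: int, grid_cols: int) -> int:
    q, r = c
    return r * grid_cols + q


def slot_coordinate(i: int, grid_rows: int, grid_cols: int) -> HexCoordinate:
    return (i % grid_cols, i // grid_cols)


def neighbor_csr(grid_rows: int, grid_cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor topology in CSR form over row-major slot indices.

    Returns ``(flat, start)`` where the neighbors of slot ``i`` are
    ``flat[start[i]:start[i+1]]``.
    """
    coords = grid_coordinates(grid_rows, grid_cols)
    flat: list[int] = []
    start = np.zeros(len(coords) + 1, dtype=np.int64)
    for i, c in enumerate(coords):
        nbrs = sorted(
            slot_index(n, grid_rows, grid_cols)
            for n in neighbors(c, grid_rows, grid_cols)
        )
        flat.extend(nbrs)
        start[i + 1] = len(flat)
    return np.asarray(flat, dtype=np.int64), start
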