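"""Reduced sensor layouts and inverse-distance-weighting reconstruction.

A layout is a set of key points in normalized mat coordinates ``(u, v)`` in
[0, 1]^2, with ``u`` running across columns and ``v`` down rows, mapped onto
the mat so that (0, 0) is the top-left cell center and (1, 1) the
bottom-right cell center.

Layouts form a nested uniform-sampling family: level 1 is the 3x3 corner/
edge-midpoint/center lattice plus the four quadrant centers (13 points, a
quincunx); each refinement adds the hypotenuse midpoints of the right
triangles formed by mutually nearest key points, so the family alternates
between quincunx lattices (odd levels: 13, 41, 145, ...) and full square
grids (even levels: 25, 81, ...).

A full-resolution map is emulated from a layout by reading, at each key
point, the pressure of the nearest original cell, then reconstructing every
cell by inverse-distance weighting (IDW) over the nearest sampled points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pressuremap import GeometryError, MatGeometry, PressureFrame


@dataclass
class SensorLayout:
    """Level-k reduced sensor point set in normalized mat coordinates."""

    level: int
    points: np.ndarray  # (m, 2) columns (u, v)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    @property
    def n_sensors(self) -> int:
        return len(self.points)


@dataclass
class SparseSample:
    """Pressure values read at a layout's key points (nearest-cell rule)."""

    layout: SensorLayout
    cell_indices: np.ndarray  # (m, 2) snapped (row, col)
    values: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        if len(self.cell_indices) != len(self.values):
            raise ValueError("cell_indices and values misaligned")


def layout_size(level: int) -> int:
    """Closed-form sensor count: odd levels n^2 + (n-1)^2 with
    n = 2^((k+1)/2) + 1; even levels (2n' - 1)^2 with n' the previous odd
    level's n.  Gives 13, 25, 41, 81, 145 for levels 1..5."""
    if level < 1:
        raise ValueError("layout level must be >= 1")
    if level % 2 == 1:
        n = 2 ** ((level + 1) // 2) + 1
        return n * n + (n - 1) * (n - 1)
    n = 2 ** (level // 2) + 1
    return (2 * n - 1) ** 2


def generate_layout(level: int) -> SensorLayout:
    """Generate the level-k layout (deterministic, sorted by (v, u))."""
    if level < 1:
        raise ValueError("layout level must be >= 1")
    if level % 2 == 1:  # quincunx: n x n grid plus the (n-1)^2 square centers
        n = 2 ** ((level + 1) // 2) + 1
        ticks = np.linspace(0.0, 1.0, n)
        uu, vv = np.meshgrid(ticks, ticks)
        grid = np.column_stack([uu.ravel(), vv.ravel()])
        half = (ticks[:-1] + ticks[1:]) / 2.0
        cu, cv = np.meshgrid(half, half)
        centers = np.column_stack([cu.ravel(), cv.ravel()])
        pts = np.vstack([grid, centers])
    else:  # full square grid at twice the density of the previous odd level
        n = 2 ** (level // 2) + 1
        m = 2 * n - 1
        ticks = np.linspace(0.0, 1.0, m)
        uu, vv = np.meshgrid(ticks, ticks)
        pts = np.column_stack([uu.ravel(), vv.ravel()])
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return SensorLayout(level=level, points=pts[order])


def sensor_reduction(level: int, geometry_a: MatGeometry, geometry_b: MatGeometry) -> float:
    """Fraction of sensing elements removed when both mats use this layout."""
    full = geometry_a.n_rows * geometry_a.n_cols + geometry_b.n_rows * geometry_b.n_cols
    reduced = 2 * layout_size(level)
    return (full - reduced) / full


def _axis_snap(fractional: np.ndarray, n: int) -> np.ndarray:
    """Nearest index on one axis; exact midpoints snap to the lower index."""
    lo = np.clip(np.floor(fractional).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    d_lo = fractional - lo
    d_hi = hi - fractional
    take_lo = d_lo <= d_hi + 1e-12  # ties -> lower index
    return np.where(take_lo, lo, hi)


def snap_to_cells(layout: SensorLayout, geometry: MatGeometry) -> np.ndarray:
    """Snap each key point to the cell whose center is nearest (ties break to
    the lexicographically smaller (row, col)).  Returns (m, 2) indices."""
    rows = _axis_snap(layout.points[:, 1] * (geometry.n_rows - 1), geometry.n_rows)
    cols = _axis_snap(layout.points[:, 0] * (geometry.n_cols - 1), geometry.n_cols)
    return np.column_stack([rows, cols])


def sample_frame(frame: PressureFrame, layout: SensorLayout) -> SparseSample:
    """Read the frame's pressure at each key point via the nearest-cell rule."""
    idx = snap_to_cells(layout, frame.geometry)
    values = frame.values[idx[:, 0], idx[:, 1]]
    return SparseSample(layout=layout, cell_indices=idx, values=values)


def _sample_coordinates(layout: SensorLayout, geometry: MatGeometry) -> np.ndarray:
    cs = geometry.cell_size
    x = layout.points[:, 0] * (geometry.n_cols - 1) * cs
    y = layout.points[:, 1] * (geometry.n_rows - 1) * cs
    return np.column_stack([x, y])


def idw_weight_matrix(
    layout: SensorLayout,
    geometry: MatGeometry,
    power: float = 2.0,
    n_neighbors: int = 4,
    exact_eps: float = 1e-12,
) -> np.ndarray:
    """Dense (n_cells, n_points) matrix W with each row the normalized IDW
    weights of a cell, so reconstruction of many frames is ``values @ W.T``.

    A cell within ``exact_eps`` of a sample point copies that sample exactly.
    """
    if power <= 0:
        raise ValueError("IDW power must be positive")
    if layout.n_sensors == 0:
        raise ValueError("empty sample: nothing to interpolate from")
    pts = _sample_coordinates(layout, geometry)
    cs = geometry.cell_size
    gx, gy = np.meshgrid(np.arange(geometry.n_cols) * cs, np.arange(geometry.n_rows) * cs)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    k = min(n_neighbors, len(pts))
    tree = cKDTree(pts)
    dist, nbr = tree.query(cells, k=k)
    dist = np.atleast_2d(dist.reshape(len(cells), k))
    nbr = np.atleast_2d(nbr.reshape(len(cells), k))
    W = np.zeros((len(cells), len(pts)))
    exact = dist[:, 0] <= exact_eps
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    rows = np.arange(len(cells))
    for j in range(k):
        W[rows, nbr[:, j]] += np.where(exact, 0.0, w[:, j])
    norm = W.sum(axis=1, keepdims=True)
    np.divide(W, norm, out=W, where=norm > 0)
    W[exact] = 0.0
    W[rows[exact], nbr[exact, 0]] = 1.0
    return W


def idw_reconstruct(
    sample: SparseSample,
    geometry: MatGeometry,
    power: float = 2.0,
    n_neighbors: int = 4,
    exact_eps: float = 1e-12,
) -> PressureFrame:
    """Reconstruct a full-resolution frame from a sparse sample by IDW."""
    W = idw_weight_matrix(sample.layout, geometry, power, n_neighbors, exact_eps)
    values = (W @ sample.values).reshape(geometry.shape)
    return PressureFrame(geometry, values)


def reconstruction_error(
    original: PressureFrame, reconstructed: PressureFrame
) -> tuple[float, float]:
    """Elementwise (RMSE, max absolute deviation) between two frames."""
    if original.geometry.shape != reconstructed.geometry.shape:
        raise GeometryError("frames have different geometries")
    diff = original.values - reconstructed.values
    return float(np.sqrt(np.mean(diff**2))), float(np.abs(diff).max())


def reconstruct_stack(
    stack: np.ndarray,
    layout: SensorLayout,
    geometry: MatGeometry,
    power: float = 2.0,
    n_neighbors: int = 4,
) -> np.ndarray:
    """Sample-and-reconstruct an entire (n, rows, cols) frame stack at once."""
    idx = snap_to_cells(layout, geometry)
    sampled = stack[:, idx[:, 0], idx[:, 1]]  # (n, m)
    W = idw_weight_matrix(layout, geometry, power, n_neighbors)
    return (sampled @ W.T).reshape(len(stack), *geometry.shape)
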