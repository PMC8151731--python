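"""Mat geometry, pressure frames and the subarea segmentation of both mats.

A driver seat is instrumented with two pressure mats — one on the backrest,
one on the seat pan — each an array of square sensing cells.  The default
geometry is the 42-row x 44-column mat with 1.27 cm cells used throughout the
package.  Cell indices are 0-based ``(row, col)``; row 0 is the top of the
backrest and the front of the seat pan; the x-axis runs across columns
(sitter's left to right) and the y-axis down rows.  Physical coordinates are
in cm with the origin at the top-left cell *center*.

The sensing area of each mat is partitioned into named rectangular subareas
(B1..B12 on the backrest, S1..S8 on the seat pan), and "regions" — unions of
two or more adjacent subareas — provide coarser sensing areas for feature
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKREST = "backrest"
SEATPAN = "seatpan"
_SIDES = (BACKREST, SEATPAN)


class GeometryError(ValueError):
    """Frame shape or side does not match the expected mat geometry."""


@dataclass(frozen=True)
class MatGeometry:
    """Rectangular mat of square sensing cells.

    Parameters
    ----------
    side : {'backrest', 'seatpan'}
    n_rows, n_cols : int
        Cell counts; at least 2 each.
    cell_size : float
        Cell edge length in cm.
    """

    side: str
    n_rows: int = 42
    n_cols: int = 44
    cell_size: float = 1.27

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise GeometryError(f"unknown mat side {self.side!r}; expected one of {_SIDES}")
        if self.n_rows < 2 or self.n_cols < 2:
            raise GeometryError("mat needs at least 2 rows and 2 columns")
        if self.cell_size <= 0:
            raise GeometryError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers_x(self) -> np.ndarray:
        """x coordinate (cm) of each column's cell centers, origin at column 0."""
        return np.arange(self.n_cols) * self.cell_size

    def cell_centers_y(self) -> np.ndarray:
        """y coordinate (cm) of each row's cell centers, origin at row 0."""
        return np.arange(self.n_rows) * self.cell_size

    @classmethod
    def backrest(cls) -> "MatGeometry":
        return cls(BACKREST)

    @classmethod
    def seatpan(cls) -> "MatGeometry":
        return cls(SEATPAN)


@dataclass
class PressureFrame:
    """One mat's pressure grid at one time instant."""

    geometry: MatGeometry
    values: np.ndarray
    frame_index: int = 0
    subject_id: str = ""
    task_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"frame shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(f"negative pressure at cell ({r}, {c})")


def normalize_by_peak(frame: PressureFrame) -> PressureFrame:
    """Divide a frame by its peak pressure (visualization aid only).

    Feature computation never uses peak-normalized frames; features are
    unit-covariant by design.
    """
    peak = float(frame.values.max(initial=0.0))
    if peak <= 0:
        raise ValueError("cannot peak-normalize a frame with no contact (all zeros)")
    return PressureFrame(
        frame.geometry,
        frame.values / peak,
        frame_index=frame.frame_index,
        subject_id=frame.subject_id,
        task_id=frame.task_id,
    )


@dataclass
class SegmentationScheme:
    """Named partition of a mat into subareas plus regional unions.

    ``subareas`` maps name -> boolean mask over the cell grid; the masks are
    pairwise disjoint and together cover the whole sensing area.  ``regions``
    maps a region name to the tuple of subarea names it unites (always >= 2
    adjacent subareas).  ``global_name`` names the whole mat.
    """

    side: str
    subareas: dict[str, np.ndarray]
    regions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    global_name: str = ""

    def __post_init__(self) -> None:
        if not self.global_name:
            self.global_name = "B" if self.side == BACKREST else "S"
        self.validate()

    def validate(self) -> None:
        masks = list(self.subareas.values())
        if not masks:
            raise ValueError("segmentation scheme has no subareas")
        shape = masks[0].shape
        total = np.zeros(shape, dtype=int)
        for m in masks:
            if m.shape != shape:
                raise ValueError("subarea masks have inconsistent shapes")
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("subarea masks overlap")
        if total.min() < 1:
            raise ValueError("subarea masks do not cover the sensing area")
        for name, members in self.regions.items():
            if len(members) < 2:
                raise ValueError(f"region {name!r} unites fewer than 2 subareas")
            for s in members:
                if s not in self.subareas:
                    raise ValueError(f"region {name!r} references unknown subarea {s!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.subareas.values())).shape

    def global_mask(self) -> np.ndarray:
        return np.ones(self.shape, dtype=bool)

    def region_mask(self, name: str) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for s in self.regions[name]:
            mask |= self.subareas[s]
        return mask

    def area_mask(self, name: str) -> np.ndarray:
        """Mask for any named area: global, subarea or region."""
        if name == self.global_name:
            return self.global_mask()
        if name in self.subareas:
            return self.subareas[name]
        if name in self.regions:
            return self.region_mask(name)
        raise KeyError(f"unknown area {name!r} on side {self.side!r}")

    def area_names(self) -> list[str]:
        return [self.global_name, *self.subareas, *self.regions]


def _symmetric_split(n: int, k: int) -> list[int]:
    """Split n cells into k contiguous bands, as equal as possible and
    palindromic so the band widths are mirror symmetric (e.g. 44 into 3
    gives [15, 14, 15])."""
    base = [n // k] * k
    rem = n - sum(base)
    i, j = 0, k - 1
    while rem > 0:  # hand out the remainder to outermost band pairs
        if rem >= 2 and i < j:
            base[i] += 1
            base[j] += 1
            rem -= 2
            i, j = i + 1, j - 1
        else:
            base[k // 2] += rem
            rem = 0
    return base


def _band_edges(sizes: list[int]) -> list[tuple[int, int]]:
    edges = []
    start = 0
    for s in sizes:
        edges.append((start, start + s))
        start += s
    return edges


def _grid_subareas(
    geometry: MatGeometry, n_band_rows: int, n_band_cols: int, prefix: str
) -> dict[str, np.ndarray]:
    # rows: plain equal-as-possible (top-heavy); columns: mirror-symmetric split
    row_sizes = [len(a) for a in np.array_split(np.arange(geometry.n_rows), n_band_rows)]
    col_sizes = _symmetric_split(geometry.n_cols, n_band_cols)
    subareas: dict[str, np.ndarray] = {}
    idx = 1
    for r0, r1 in _band_edges(row_sizes):
        for c0, c1 in _band_edges(col_sizes):
            m = np.zeros(geometry.shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            subareas[f"{prefix}{idx}"] = m
            idx += 1
    return subareas


def _grid_regions(prefix: str, n_band_rows: int, n_band_cols: int) -> dict[str, tuple[str, ...]]:
    def name(r: int, c: int) -> str:
        return f"{prefix}{r * n_band_cols + c + 1}"

    regions: dict[str, tuple[str, ...]] = {}
    # horizontally adjacent pairs (skip when a pair would equal a full row band)
    if n_band_cols > 2:
        for r in range(n_band_rows):
            for c in range(n_band_cols - 1):
                regions[f"{name(r, c)}-{name(r, c + 1)}"] = (name(r, c), name(r, c + 1))
    # full row bands
    for r in range(n_band_rows):
        regions[f"{prefix}row{r + 1}"] = tuple(name(r, c) for c in range(n_band_cols))
    # full column bands
    for c in range(n_band_cols):
        regions[f"{prefix}col{c + 1}"] = tuple(name(r, c) for r in range(n_band_rows))
    # upper / lower halves (first vs last half of the row bands)
    half = n_band_rows // 2
    regions[f"{prefix}upper"] = tuple(
        name(r, c) for r in range(half) for c in range(n_band_cols)
    )
    regions[f"{prefix}lower"] = tuple(
        name(r, c) for r in range(half, n_band_rows) for c in range(n_band_cols)
    )
    return regions


def default_segmentation(geometry: MatGeometry) -> SegmentationScheme:
    """Default subarea partition: backrest 4x3 blocks (B1..B12, row-major from
    top-left), seat pan 4x2 blocks (S1..S8, row-major from front-left), with
    the standard regional unions (adjacent pairs, row/column bands, halves).
    """
    if geometry.side == BACKREST:
        rows, cols, prefix = 4, 3, "B"
    elif geometry.side == SEATPAN:
        rows, cols, prefix = 4, 2, "S"
    else:  # pragma: no cover - MatGeometry already rejects unknown sides
        raise GeometryError(f"unknown mat side {geometry.side!r}")
    subareas = _grid_subareas(geometry, rows, cols, prefix)
    regions = _grid_regions(prefix, rows, cols)
    return SegmentationScheme(side=geometry.side, subareas=subareas, regions=regions,
                              global_name=prefix)
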