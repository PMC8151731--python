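"""Pressure feature extraction from segmented body-pressure distributions.

The feature collection covers, per mat, the global sensing area, every
subarea and every regional union with combinations of:

* ``cop_x`` / ``cop_y`` — pressure-weighted centroid (center of pressure) of
  the area, in cm;
* ``contact_area_proportion`` — fraction of the area's cells whose pressure
  exceeds the contact threshold;
* ``mean_pressure`` / ``peak_pressure`` / ``total_force`` — area statistics
  (mean includes zero cells; total force is pressure sum times cell area);
* ``pressure_ratio`` — load in one area divided by the combined load of two
  disjoint areas, for adjacent subarea pairs and the half/band splits.

The default enumeration over the default segmentation schemes yields exactly
200 candidate descriptors; this count is asserted, never truncated.

Classification uses *relative* features — the value minus its value in the
subject's task-initial standard posture — which removes most of the
between-subject anthropometric variation from the feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pressuremap import (
    BACKREST,
    SEATPAN,
    GeometryError,
    MatGeometry,
    PressureFrame,
    SegmentationScheme,
    default_segmentation,
)

COP_X = "cop_x"
COP_Y = "cop_y"
CONTACT = "contact_area_proportion"
RATIO = "pressure_ratio"
MEAN = "mean_pressure"
PEAK = "peak_pressure"
TOTAL = "total_force"

KINDS = (COP_X, COP_Y, CONTACT, RATIO, MEAN, PEAK, TOTAL)

EXPECTED_N_FEATURES = 200


class UndefinedFeatureError(ValueError):
    """A feature has no defined value on this frame (zero load in its area)."""


class FeatureEnumerationError(ValueError):
    """Scheme pair cannot produce the documented candidate collection."""


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    kind: str
    side: str
    area: str
    area2: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == RATIO:
            if self.area2 is None or self.area2 == self.area:
                raise ValueError("pressure_ratio needs two distinct areas")
        elif self.area2 is not None:
            raise ValueError(f"{self.kind} takes a single area")


@dataclass
class FeatureVector:
    """Values of an ordered descriptor collection for one frame pair."""

    descriptors: list[FeatureDescriptor]
    values: np.ndarray
    reference_values: np.ndarray | None = None
    relative_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.descriptors):
            raise ValueError("values misaligned with descriptors")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]


# ---------------------------------------------------------------------------
# elementary per-area operations


def center_of_pressure(frame: PressureFrame, mask: np.ndarray) -> tuple[float, float]:
    """Load-weighted centroid of the masked cells, cell-center coordinates (cm)."""
    mask = np.asarray(mask, dtype=bool)
    p = frame.values[mask]
    total = p.sum()
    if total <= 0:
        raise UndefinedFeatureError("zero total pressure in mask: CoP undefined")
    rows, cols = np.nonzero(mask)
    cs = frame.geometry.cell_size
    x = float((p * cols * cs).sum() / total)
    y = float((p * rows * cs).sum() / total)
    return x, y


def contact_area_proportion(
    frame: PressureFrame, mask: np.ndarray, threshold: float = 0.0
) -> float:
    """Fraction of masked cells with pressure strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("contact threshold must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return float((frame.values[mask] > threshold).sum() / n)


def pressure_ratio(frame: PressureFrame, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Load share of area A among areas A and B: sum(A) / (sum(A) + sum(B))."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if np.any(mask_a & mask_b):
        raise ValueError("pressure_ratio areas must be disjoint")
    a = float(frame.values[mask_a].sum())
    b = float(frame.values[mask_b].sum())
    if a + b <= 0:
        raise UndefinedFeatureError("zero load in both areas: ratio undefined")
    return a / (a + b)


def area_statistics(frame: PressureFrame, mask: np.ndarray) -> tuple[float, float, float]:
    """(mean pressure incl. zero cells, peak pressure, total force = sum * cell area)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    p = frame.values[mask]
    return float(p.mean()), float(p.max()), float(p.sum() * frame.geometry.cell_area)


# ---------------------------------------------------------------------------
# candidate enumeration


def _adjacent_pairs(scheme: SegmentationScheme) -> tuple[list, list]:
    """(horizontal, vertical) ordered adjacent subarea pairs, from the masks."""
    names = list(scheme.subareas)
    horizontal, vertical = [], []
    for i, a in enumerate(names):
        ma = scheme.subareas[a]
        for b in names[i + 1 :]:
            mb = scheme.subareas[b]
            left_right = np.any(ma[:, :-1] & mb[:, 1:]) or np.any(mb[:, :-1] & ma[:, 1:])
            above_below = np.any(ma[:-1, :] & mb[1:, :]) or np.any(mb[:-1, :] & ma[1:, :])
            if left_right and not above_below:
                # order left area first
                first = a if np.any(ma[:, :-1] & mb[:, 1:]) else b
                second = b if first == a else a
                horizontal.append((first, second))
            elif above_below and not left_right:
                first = a if np.any(ma[:-1, :] & mb[1:, :]) else b
                second = b if first == a else a
                vertical.append((first, second))
    return horizontal, vertical


def _ratio_pairs(scheme: SegmentationScheme) -> list[tuple[str, str]]:
    horizontal, vertical = _adjacent_pairs(scheme)
    pairs = list(horizontal) + list(vertical)
    p = scheme.global_name
    if f"{p}upper" in scheme.regions and f"{p}lower" in scheme.regions:
        pairs.append((f"{p}upper", f"{p}lower"))
    col_bands = sorted(n for n in scheme.regions if n.startswith(f"{p}col"))
    for i, a in enumerate(col_bands):
        for b in col_bands[i + 1 :]:
            pairs.append((a, b))
    return pairs


def enumerate_feature_set(
    backrest_scheme: SegmentationScheme,
    seatpan_scheme: SegmentationScheme,
    expected: int | None = EXPECTED_N_FEATURES,
) -> list[FeatureDescriptor]:
    """Build the ordered candidate collection from two segmentation schemes.

    Composition: per side, the global area gets all six single-area kinds;
    each subarea gets CoP (x, y), contact proportion and total force; each
    region gets CoP (x, y) and contact proportion; pressure ratios cover all
    adjacent subarea pairs, the upper/lower halves and the column-band pairs.
    On the default schemes this yields exactly 200 descriptors.
    """
    descriptors: list[FeatureDescriptor] = []
    pair = ((BACKREST, backrest_scheme), (SEATPAN, seatpan_scheme))

    for side, scheme in pair:
        g = scheme.global_name
        for kind, suffix in (
            (COP_X, "cop_x"),
            (COP_Y, "cop_y"),
            (CONTACT, "contact"),
            (MEAN, "mean"),
            (PEAK, "peak"),
            (TOTAL, "total"),
        ):
            descriptors.append(FeatureDescriptor(f"{g}_{suffix}", kind, side, g))
    for side, scheme in pair:
        for name in scheme.subareas:
            descriptors.append(FeatureDescriptor(f"{name}_cop_x", COP_X, side, name))
            descriptors.append(FeatureDescriptor(f"{name}_cop_y", COP_Y, side, name))
            descriptors.append(FeatureDescriptor(f"{name}_contact", CONTACT, side, name))
            descriptors.append(FeatureDescriptor(f"{name}_total", TOTAL, side, name))
    for side, scheme in pair:
        for name in scheme.regions:
            descriptors.append(FeatureDescriptor(f"{name}_cop_x", COP_X, side, name))
            descriptors.append(FeatureDescriptor(f"{name}_cop_y", COP_Y, side, name))
            descriptors.append(FeatureDescriptor(f"{name}_contact", CONTACT, side, name))
    for side, scheme in pair:
        for a, b in _ratio_pairs(scheme):
            descriptors.append(
                FeatureDescriptor(f"{a}_vs_{b}_ratio", RATIO, side, a, b)
            )

    names = [d.name for d in descriptors]
    if len(set(names)) != len(names):
        raise FeatureEnumerationError("duplicate descriptor names in enumeration")
    if expected is not None and len(descriptors) != expected:
        raise FeatureEnumerationError(
            f"enumeration produced {len(descriptors)} descriptors, expected {expected}"
        )
    return descriptors


def write_manifest(descriptors: list[FeatureDescriptor], path: str | Path) -> None:
    rows = [
        {"name": d.name, "kind": d.kind, "side": d.side, "area": d.area,
         "area2": d.area2 or ""}
        for d in descriptors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[FeatureDescriptor]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        FeatureDescriptor(r["name"], r["kind"], r["side"], r["area"], r["area2"] or None)
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# vectorized extraction

_KIND_CODE = {k: i for i, k in enumerate(KINDS)}


class FeatureExtractor:
    """Computes the candidate collection for frame pairs (optionally in batch).

    Undefined entries are made dense before classification: a CoP over a
    zero-load area is replaced by the area's geometric center, an undefined
    ratio by 0.5.
    """

    def __init__(
        self,
        backrest_geometry: MatGeometry | None = None,
        seatpan_geometry: MatGeometry | None = None,
        backrest_scheme: SegmentationScheme | None = None,
        seatpan_scheme: SegmentationScheme | None = None,
        descriptors: list[FeatureDescriptor] | None = None,
        contact_threshold: float = 0.0,
    ) -> None:
        if contact_threshold < 0:
            raise ValueError("contact threshold must be non-negative")
        self.geometry = {
            BACKREST: backrest_geometry or MatGeometry.backrest(),
            SEATPAN: seatpan_geometry or MatGeometry.seatpan(),
        }
        self.scheme = {
            BACKREST: backrest_scheme or default_segmentation(self.geometry[BACKREST]),
            SEATPAN: seatpan_scheme or default_segmentation(self.geometry[SEATPAN]),
        }
        self.descriptors = descriptors or enumerate_feature_set(
            self.scheme[BACKREST], self.scheme[SEATPAN]
        )
        self.contact_threshold = float(contact_threshold)
        self._precompute()

    def _precompute(self) -> None:
        self._side: dict[str, dict] = {}
        for side in (BACKREST, SEATPAN):
            geo, scheme = self.geometry[side], self.scheme[side]
            names = scheme.area_names()
            masks = np.stack([scheme.area_mask(n).ravel() for n in names])
            cs = geo.cell_size
            xs = np.tile(np.arange(geo.n_cols) * cs, geo.n_rows)
            ys = np.repeat(np.arange(geo.n_rows) * cs, geo.n_cols)
            counts = masks.sum(axis=1).astype(float)
            centers_x = (masks * xs).sum(axis=1) / counts
            centers_y = (masks * ys).sum(axis=1) / counts
            self._side[side] = {
                "index": {n: i for i, n in enumerate(names)},
                "masks": masks.astype(float),
                "counts": counts,
                "xs": xs,
                "ys": ys,
                "centers_x": centers_x,
                "centers_y": centers_y,
            }
        # compile descriptor dispatch table
        self._plan = []
        for d in self.descriptors:
            s = self._side[d.side]
            self._plan.append(
                (_KIND_CODE[d.kind], d.side, s["index"][d.area],
                 s["index"][d.area2] if d.area2 else -1)
            )

    def _side_accumulators(self, stack: np.ndarray, side: str) -> dict[str, np.ndarray]:
        geo = self.geometry[side]
        if stack.shape[1:] != geo.shape:
            raise GeometryError(
                f"{side} stack shape {stack.shape[1:]} != geometry {geo.shape}"
            )
        s = self._side[side]
        flat = stack.reshape(len(stack), -1)
        m = s["masks"].T  # (RC, n_areas)
        sums = flat @ m
        wx = (flat * s["xs"]) @ m
        wy = (flat * s["ys"]) @ m
        cnt = (flat > self.contact_threshold).astype(float) @ m
        return {"sums": sums, "wx": wx, "wy": wy, "cnt": cnt, "flat": flat,
                "peak": flat.max(axis=1)}

    def compute_matrix(self, backrest_stack: np.ndarray, seatpan_stack: np.ndarray) -> np.ndarray:
        """Feature matrix (n_frames, n_descriptors) for aligned frame stacks."""
        backrest_stack = np.asarray(backrest_stack, dtype=float)
        seatpan_stack = np.asarray(seatpan_stack, dtype=float)
        if len(backrest_stack) != len(seatpan_stack):
            raise ValueError("frame stacks differ in length")
        acc = {
            BACKREST: self._side_accumulators(backrest_stack, BACKREST),
            SEATPAN: self._side_accumulators(seatpan_stack, SEATPAN),
        }
        n = len(backrest_stack)
        out = np.empty((n, len(self.descriptors)))
        for j, (code, side, ai, bi) in enumerate(self._plan):
            a = acc[side]
            meta = self._side[side]
            sums = a["sums"][:, ai]
            if code == _KIND_CODE[COP_X]:
                with np.errstate(invalid="ignore", divide="ignore"):
                    col = np.where(sums > 0, a["wx"][:, ai] / sums, meta["centers_x"][ai])
            elif code == _KIND_CODE[COP_Y]:
                with np.errstate(invalid="ignore", divide="ignore"):
                    col = np.where(sums > 0, a["wy"][:, ai] / sums, meta["centers_y"][ai])
            elif code == _KIND_CODE[CONTACT]:
                col = a["cnt"][:, ai] / meta["counts"][ai]
            elif code == _KIND_CODE[RATIO]:
                denom = sums + a["sums"][:, bi]
                with np.errstate(invalid="ignore", divide="ignore"):
                    col = np.where(denom > 0, sums / denom, 0.5)
            elif code == _KIND_CODE[MEAN]:
                col = sums / meta["counts"][ai]
            elif code == _KIND_CODE[PEAK]:
                mask = meta["masks"][ai] > 0
                col = a["peak"] if mask.all() else a["flat"][:, mask].max(axis=1)
            else:  # TOTAL
                col = sums * self.geometry[side].cell_area
            out[:, j] = col
        return out

    def compute(self, backrest_frame: PressureFrame, seatpan_frame: PressureFrame) -> FeatureVector:
        """Feature vector for one frame pair."""
        values = self.compute_matrix(
            backrest_frame.values[None], seatpan_frame.values[None]
        )[0]
        return FeatureVector(self.descriptors, values)


def compute_features(
    backrest_frame: PressureFrame,
    seatpan_frame: PressureFrame,
    descriptors: list[FeatureDescriptor],
    backrest_scheme: SegmentationScheme | None = None,
    seatpan_scheme: SegmentationScheme | None = None,
    contact_threshold: float = 0.0,
) -> FeatureVector:
    """Functional wrapper around :class:`FeatureExtractor` for one frame pair."""
    extractor = FeatureExtractor(
        backrest_frame.geometry,
        seatpan_frame.geometry,
        backrest_scheme,
        seatpan_scheme,
        descriptors,
        contact_threshold,
    )
    return extractor.compute(backrest_frame, seatpan_frame)


def relative_features(current: FeatureVector, reference: FeatureVector) -> FeatureVector:
    """Relative feature vector: current minus reference, elementwise."""
    if current.descriptors != reference.descriptors:
        raise ValueError("descriptor lists differ between current and reference")
    return FeatureVector(
        current.descriptors,
        current.values,
        reference_values=reference.values.copy(),
        relative_values=current.values - reference.values,
    )


def feature_frame(matrix: np.ndarray, descriptors: list[FeatureDescriptor]) -> pd.DataFrame:
    """Feature matrix as a DataFrame with descriptor names as columns."""
    return pd.DataFrame(matrix, columns=[d.name for d in descriptors])
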