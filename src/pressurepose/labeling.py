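"""Posture class assignment and the intra-/inter-motion redundancy filter.

Posture classes are assigned per body part from ground-truth kinematics:

* **Trunk** — five classes from the three trunk angles (rotation,
  inclination, lateral tilt, in degrees, relative to the task-initial
  standard trunk position TP0): TP0 standard; TP2 pronounced forward /
  backward inclination; TP3 pronounced rotation; TP1 moderate lateral tilt;
  TP4 large lateral tilt (same direction of deviation as TP1, larger band).
* **Right foot** — RFP0 on the accelerator pedal, RFP1 on the brake pedal,
  RFP2 on the floor; assigned by nearest foot-zone reference point.
* **Left foot** — LFP0 on the floor, LFP1 on the clutch; likewise.

The redundancy filter removes near-duplicate postures of the same subject:
a sample is kept only if it differs from *every* previously kept sample of
that subject — by more than 3 degrees in at least one trunk angle (trunk),
or by more than 2 cm of foot-center distance (each foot).  Each body part is
filtered independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRUNK_CLASSES = ("TP0", "TP1", "TP2", "TP3", "TP4")
LEFT_FOOT_CLASSES = ("LFP0", "LFP1")
RIGHT_FOOT_CLASSES = ("RFP0", "RFP1", "RFP2")
ALL_CLASSES = TRUNK_CLASSES + LEFT_FOOT_CLASSES + RIGHT_FOOT_CLASSES

TRUNK = "trunk"
LEFT_FOOT = "left_foot"
RIGHT_FOOT = "right_foot"
BODY_PARTS = (TRUNK, LEFT_FOOT, RIGHT_FOOT)

TRUNK_ANGLE_COLUMNS = [
    "trunk_rotation_deg",
    "trunk_inclination_deg",
    "trunk_lateral_tilt_deg",
]
FOOT_COLUMNS = {
    LEFT_FOOT: ["left_foot_x_cm", "left_foot_y_cm"],
    RIGHT_FOOT: ["right_foot_x_cm", "right_foot_y_cm"],
}

#: redundancy-filter similarity bounds: postures are *different* only above these
TRUNK_ANGLE_TOLERANCE_DEG = 3.0
FOOT_DISTANCE_TOLERANCE_CM = 2.0


@dataclass(frozen=True)
class TrunkAngles:
    """Trunk orientation relative to the task-initial standard position (deg)."""

    rotation: float
    inclination: float
    lateral_tilt: float


@dataclass(frozen=True)
class FootPosition:
    """Foot-center coordinates in the vehicle floor plane (cm)."""

    x: float
    y: float


@dataclass(frozen=True)
class PostureLabel:
    trunk: str
    left_foot: str
    right_foot: str

    def __post_init__(self) -> None:
        if self.trunk not in TRUNK_CLASSES:
            raise ValueError(f"unknown trunk class {self.trunk!r}")
        if self.left_foot not in LEFT_FOOT_CLASSES:
            raise ValueError(f"unknown left-foot class {self.left_foot!r}")
        if self.right_foot not in RIGHT_FOOT_CLASSES:
            raise ValueError(f"unknown right-foot class {self.right_foot!r}")


def _default_right_zones() -> dict[str, tuple[float, float]]:
    # accelerator / brake / floor reference points, vehicle floor plane (cm);
    # x lateral (driver's left negative), y longitudinal (forward positive)
    return {"RFP0": (15.0, 40.0), "RFP1": (0.0, 40.0), "RFP2": (8.0, 15.0)}


def _default_left_zones() -> dict[str, tuple[float, float]]:
    return {"LFP0": (-8.0, 15.0), "LFP1": (-15.0, 40.0)}


@dataclass
class ClassThresholds:
    """Angle bands and foot-zone reference points defining the classes.

    ``dead_band_deg`` is the TP0 half-width on every trunk angle;
    lateral tilt inside ``(dead_band_deg, tp4_lateral_min_deg]`` is TP1 and
    beyond ``tp4_lateral_min_deg`` is TP4.  When several angles leave the
    dead band, the largest dead-band-normalized deviation decides, with ties
    broken in the fixed order inclination (TP2) > rotation (TP3) > lateral.
    """

    dead_band_deg: float = 10.0
    tp4_lateral_min_deg: float = 25.0
    angle_band_max_deg: float = 35.0  # outer edge used by the synthetic generator
    right_zones: dict[str, tuple[float, float]] = field(default_factory=_default_right_zones)
    left_zones: dict[str, tuple[float, float]] = field(default_factory=_default_left_zones)

    def __post_init__(self) -> None:
        if not 0 < self.dead_band_deg < self.tp4_lateral_min_deg:
            raise ValueError("need 0 < dead_band < TP4 lateral threshold")
        if set(self.right_zones) != set(RIGHT_FOOT_CLASSES):
            raise ValueError("right_zones must define RFP0, RFP1, RFP2")
        if set(self.left_zones) != set(LEFT_FOOT_CLASSES):
            raise ValueError("left_zones must define LFP0, LFP1")


def label_trunk(angles: TrunkAngles, thresholds: ClassThresholds | None = None) -> str:
    thresholds = thresholds or ClassThresholds()
    db = thresholds.dead_band_deg
    dev = {
        "inclination": abs(angles.inclination) / db,
        "rotation": abs(angles.rotation) / db,
        "lateral": abs(angles.lateral_tilt) / db,
    }
    if max(dev.values()) <= 1.0:
        return "TP0"
    # largest normalized deviation wins; tie order inclination > rotation > lateral
    winner = max(("inclination", "rotation", "lateral"), key=lambda k: dev[k])
    if winner == "inclination":
        return "TP2"
    if winner == "rotation":
        return "TP3"
    return "TP1" if abs(angles.lateral_tilt) <= thresholds.tp4_lateral_min_deg else "TP4"


def _nearest_zone(pos: FootPosition, zones: dict[str, tuple[float, float]]) -> str:
    names = sorted(zones)  # deterministic tie-breaking by class name
    d2 = [
        (pos.x - zones[n][0]) ** 2 + (pos.y - zones[n][1]) ** 2 for n in names
    ]
    return names[int(np.argmin(d2))]


def label_feet(
    left: FootPosition,
    right: FootPosition,
    thresholds: ClassThresholds | None = None,
) -> tuple[str, str]:
    thresholds = thresholds or ClassThresholds()
    return (
        _nearest_zone(left, thresholds.left_zones),
        _nearest_zone(right, thresholds.right_zones),
    )


def label_table(labels: pd.DataFrame, thresholds: ClassThresholds | None = None) -> pd.DataFrame:
    """Assign the three class columns for every row of a kinematics table."""
    thresholds = thresholds or ClassThresholds()
    out = labels.copy()
    out[TRUNK] = [
        label_trunk(TrunkAngles(r, i, t), thresholds)
        for r, i, t in labels[TRUNK_ANGLE_COLUMNS].to_numpy()
    ]
    feet = [
        label_feet(FootPosition(lx, ly), FootPosition(rx, ry), thresholds)
        for lx, ly, rx, ry in labels[
            FOOT_COLUMNS[LEFT_FOOT] + FOOT_COLUMNS[RIGHT_FOOT]
        ].to_numpy()
    ]
    out[LEFT_FOOT] = [f[0] for f in feet]
    out[RIGHT_FOOT] = [f[1] for f in feet]
    return out


def _greedy_keep(coords: np.ndarray, any_similar, compare_all: bool = True) -> np.ndarray:
    """Greedy temporal pass: keep a sample iff it differs from every kept one
    (or, with ``compare_all=False``, only from the most recently kept).

    ``any_similar(kept_matrix, candidate)`` reports whether any kept sample
    is within the similarity tolerance of the candidate.
    """
    keep: list[int] = []
    kept = np.empty((0, coords.shape[1]))
    for i, c in enumerate(coords):
        ref = kept if compare_all else kept[-1:]
        if len(ref) == 0 or not any_similar(ref, c):
            keep.append(i)
            kept = np.vstack([kept, c[None]])
    mask = np.zeros(len(coords), dtype=bool)
    mask[keep] = True
    return mask


def redundancy_filter(
    samples: pd.DataFrame,
    body_part: str,
    angle_tolerance_deg: float = TRUNK_ANGLE_TOLERANCE_DEG,
    distance_tolerance_cm: float = FOOT_DISTANCE_TOLERANCE_CM,
    compare_all: bool = True,
) -> np.ndarray:
    """Boolean keep-mask implementing the intra-/inter-motion filter.

    ``samples`` must carry ``subject_id`` and ``frame_index`` (time-ordered
    within each subject; unordered input raises) plus the kinematic columns
    of the requested body part.  The filter never consults the other body
    parts' kinematics.
    """
    if body_part not in BODY_PARTS:
        raise ValueError(f"unknown body part {body_part!r}")
    order_cols = ["subject_id", "task_id"] if "task_id" in samples.columns else ["subject_id"]
    order_ok = (
        samples.groupby(order_cols, sort=False)["frame_index"]
        .apply(lambda s: bool(s.is_monotonic_increasing))
        .all()
        if len(samples)
        else True
    )
    if not order_ok:
        raise ValueError("samples must be time-ordered within each subject")

    if body_part == TRUNK:
        cols = TRUNK_ANGLE_COLUMNS
        tol = angle_tolerance_deg

        def any_similar(kept: np.ndarray, c: np.ndarray) -> bool:
            # similar = no angle differs by more than the tolerance
            return bool(np.any(np.max(np.abs(kept - c), axis=1) <= tol))

    else:
        cols = FOOT_COLUMNS[body_part]
        tol = distance_tolerance_cm

        def any_similar(kept: np.ndarray, c: np.ndarray) -> bool:
            d = kept - c
            return bool(np.any(np.hypot(d[:, 0], d[:, 1]) <= tol))

    mask = np.zeros(len(samples), dtype=bool)
    subjects = samples["subject_id"].to_numpy()
    all_coords = samples[cols].to_numpy(dtype=float)
    for subj in pd.unique(subjects):
        sel = subjects == subj
        mask[sel] = _greedy_keep(all_coords[sel], any_similar, compare_all)
    return mask
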