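"""Synthetic driver body-pressure-distribution generator.

Emulates the statistical structure the analysis pipeline assumes, without
any real recordings: each mat's pressure field is a sum of anisotropic
Gaussian contact lobes (two scapular + one lumbar lobe on the backrest; two
ischial + two thigh lobes on the seat pan) whose amplitudes and centers
respond to the ground-truth kinematics:

* forward inclination unloads the backrest and shifts the seat-pan load
  forward; backward inclination loads the backrest;
* lateral tilt shifts both mats' load laterally and loads the tilted side;
* trunk rotation loads one scapular lobe and unloads the other;
* each foot's position (pedal / floor / clutch) moves the same-side thigh
  lobe and modulates its amplitude.

Per-subject anthropometric variation enters as a global pressure multiplier
(mass), a lobe-spread multiplier (width) and a small seating-position
offset.  Measurement noise is multiplicative (a fraction of the local
signal) plus an optional additive noise floor on every cell, and every task
opens and closes with the standard posture (TP0 / LFP0 / RFP0), supplying
the reference frames for relative features.

Pressure values are in arbitrary consistent units; every downstream feature
is unit-covariant, so no calibration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Dataset, Recording
from .labeling import (
    ClassThresholds,
    FootPosition,
    PostureLabel,
    TrunkAngles,
    label_feet,
    label_trunk,
)
from .pressuremap import MatGeometry

BASE_AMPLITUDE = 100.0  # arbitrary pressure units
PRESSURE_CUTOFF = 1.0  # sensor detection limit: smaller values read as zero


@dataclass(frozen=True)
class Lobe:
    """One anisotropic Gaussian contact lobe in normalized mat coordinates."""

    center_u: float
    center_v: float
    amplitude: float
    spread_u: float
    spread_v: float


@dataclass
class BodyContactModel:
    """Named contact lobes for both mats (the TP0 standard-posture pattern)."""

    backrest: dict[str, Lobe]
    seatpan: dict[str, Lobe]

    @classmethod
    def default(cls) -> "BodyContactModel":
        a = BASE_AMPLITUDE
        return cls(
            backrest={
                "scapular_left": Lobe(0.35, 0.25, 1.0 * a, 0.12, 0.12),
                "scapular_right": Lobe(0.65, 0.25, 1.0 * a, 0.12, 0.12),
                "lumbar": Lobe(0.50, 0.75, 0.8 * a, 0.18, 0.12),
            },
            seatpan={
                "ischial_left": Lobe(0.38, 0.70, 1.2 * a, 0.10, 0.10),
                "ischial_right": Lobe(0.62, 0.70, 1.2 * a, 0.10, 0.10),
                "thigh_left": Lobe(0.36, 0.30, 0.6 * a, 0.09, 0.18),
                "thigh_right": Lobe(0.64, 0.30, 0.6 * a, 0.09, 0.18),
            },
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometric scaling of one synthetic subject."""

    subject_id: str
    mass_scale: float = 1.0  # global pressure multiplier
    width_scale: float = 1.0  # lobe spread multiplier
    seat_shift: tuple[float, float] = (0.0, 0.0)  # (du, dv), normalized
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.6 <= self.mass_scale <= 1.6 and 0.6 <= self.width_scale <= 1.6):
            raise ValueError("subject scales must lie in [0.6, 1.6]")
        if max(abs(self.seat_shift[0]), abs(self.seat_shift[1])) > 0.08:
            raise ValueError("|seat shift| must be <= 0.08")

    @classmethod
    def sample(cls, subject_id: str, rng: np.random.Generator) -> "SubjectProfile":
        return cls(
            subject_id=subject_id,
            mass_scale=float(rng.uniform(0.7, 1.4)),
            width_scale=float(rng.uniform(0.85, 1.25)),
            seat_shift=(float(rng.uniform(-0.05, 0.05)), float(rng.uniform(-0.05, 0.05))),
            seed=int(rng.integers(2**31 - 1)),
        )


@dataclass(frozen=True)
class FrameKinematics:
    trunk: TrunkAngles
    left_foot: FootPosition
    right_foot: FootPosition


@dataclass
class ScenarioSpec:
    """Study-scale scenario: who sits, what they do, how noisy the mats are."""

    n_subjects: int = 10
    n_tasks: int = 10
    n_frames: int = 60  # frames per task
    fps: float = 25.0
    noise_sd: float = 0.15  # multiplicative, fraction of local signal
    noise_floor: float = 0.0  # additive pressure on every cell
    pressure_cutoff: float = PRESSURE_CUTOFF
    seed: int = 0
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)

    def __post_init__(self) -> None:
        n_open = standard_segment_length(self.fps)
        if self.n_frames < 2 * n_open + 1:
            raise ValueError("n_frames too small to fit opening/closing standard segments")


def standard_segment_length(fps: float) -> int:
    """Frames in the opening (and closing) standard-posture segment (0.5 s)."""
    return max(1, int(round(0.5 * fps)))


# ---------------------------------------------------------------------------
# rendering

# kinematics -> lobe response gains (per degree / per cm, normalized units)
_INCL_UNLOAD_PER_DEG = 1.0 / 40.0  # backrest amplitude loss per forward degree
_SEAT_FWD_PER_DEG = 0.004  # seat lobe v shift per forward degree
_LAT_SHIFT_PER_DEG = 0.004  # lobe u shift per lateral-tilt degree
_LAT_LOAD_PER_DEG = 0.008  # ischial load asymmetry per lateral-tilt degree
_ROT_ASYM_PER_DEG = 0.012  # scapular load asymmetry per rotation degree
_FOOT_U_PER_CM = 0.006  # thigh lobe u shift per lateral foot cm
_FOOT_V_PER_CM = 0.003  # thigh lobe v shift per longitudinal foot cm
_FOOT_LOAD_PER_CM = 0.008  # thigh amplitude change per longitudinal foot cm


def _posed_lobes(
    kin: FrameKinematics,
    subject: SubjectProfile,
    model: BodyContactModel,
    thresholds: ClassThresholds,
) -> tuple[list[Lobe], list[Lobe]]:
    rot, incl, lat = kin.trunk.rotation, kin.trunk.inclination, kin.trunk.lateral_tilt
    du_lat = lat * _LAT_SHIFT_PER_DEG
    f_incl = float(np.clip(1.0 - incl * _INCL_UNLOAD_PER_DEG, 0.05, 2.0))

    back: list[Lobe] = []
    for name, lobe in model.backrest.items():
        amp = lobe.amplitude * f_incl
        if name == "scapular_left":
            amp *= float(np.clip(1.0 - rot * _ROT_ASYM_PER_DEG, 0.05, 2.0))
        elif name == "scapular_right":
            amp *= float(np.clip(1.0 + rot * _ROT_ASYM_PER_DEG, 0.05, 2.0))
        back.append(replace(lobe, center_u=lobe.center_u + du_lat, amplitude=amp))

    seat: list[Lobe] = []
    dv_incl = -incl * _SEAT_FWD_PER_DEG
    foot_anchor = {
        "thigh_left": (thresholds.left_zones["LFP0"], kin.left_foot),
        "thigh_right": (thresholds.right_zones["RFP0"], kin.right_foot),
    }
    for name, lobe in model.seatpan.items():
        du, dv, amp = du_lat, dv_incl, lobe.amplitude
        if name.startswith("ischial"):
            side_sign = -1.0 if name.endswith("left") else 1.0
            amp *= float(np.clip(1.0 + side_sign * lat * _LAT_LOAD_PER_DEG, 0.05, 2.0))
        else:
            (cx, cy), foot = foot_anchor[name]
            du += (foot.x - cx) * _FOOT_U_PER_CM
            dv += -(foot.y - cy) * _FOOT_V_PER_CM
            amp *= float(np.clip(1.0 - (foot.y - cy) * _FOOT_LOAD_PER_CM, 0.2, 2.5))
        seat.append(
            replace(lobe, center_u=lobe.center_u + du, center_v=lobe.center_v + dv,
                    amplitude=amp)
        )

    def personalize(lobes: list[Lobe]) -> list[Lobe]:
        du, dv = subject.seat_shift
        return [
            replace(
                lo,
                center_u=lo.center_u + du,
                center_v=lo.center_v + dv,
                amplitude=lo.amplitude * subject.mass_scale,
                spread_u=lo.spread_u * subject.width_scale,
                spread_v=lo.spread_v * subject.width_scale,
            )
            for lo in lobes
        ]

    return personalize(back), personalize(seat)


def _render_side(lobes: list[Lobe], geometry: MatGeometry) -> np.ndarray:
    u = np.linspace(0.0, 1.0, geometry.n_cols)
    v = np.linspace(0.0, 1.0, geometry.n_rows)
    uu, vv = np.meshgrid(u, v)
    out = np.zeros(geometry.shape)
    for lo in lobes:
        out += lo.amplitude * np.exp(
            -((uu - lo.center_u) ** 2 / (2 * lo.spread_u**2)
              + (vv - lo.center_v) ** 2 / (2 * lo.spread_v**2))
        )
    return out


def render_frames(
    label: PostureLabel,
    kinematics: FrameKinematics,
    subject: SubjectProfile | None = None,
    model: BodyContactModel | None = None,
    noise_sd: float = 0.0,
    noise_floor: float = 0.0,
    rng: np.random.Generator | int | None = None,
    thresholds: ClassThresholds | None = None,
    backrest_geometry: MatGeometry | None = None,
    seatpan_geometry: MatGeometry | None = None,
    pressure_cutoff: float = PRESSURE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one (backrest, seat pan) pressure-grid pair for a posture.

    Values below ``pressure_cutoff`` read as zero (the mat's detection
    limit), so frames have a genuine non-contact background.  Raises if
    ``label`` disagrees with what the labeling rules assign to
    ``kinematics`` under the active thresholds, so synthetic data and labels
    can never drift apart.
    """
    thresholds = thresholds or ClassThresholds()
    subject = subject or SubjectProfile("s00")
    model = model or BodyContactModel.default()
    bgeo = backrest_geometry or MatGeometry.backrest()
    sgeo = seatpan_geometry or MatGeometry.seatpan()
    implied_trunk = label_trunk(kinematics.trunk, thresholds)
    implied_left, implied_right = label_feet(
        kinematics.left_foot, kinematics.right_foot, thresholds
    )
    implied = PostureLabel(implied_trunk, implied_left, implied_right)
    if implied != label:
        raise ValueError(f"kinematics imply {implied}, but label is {label}")

    back_lobes, seat_lobes = _posed_lobes(kinematics, subject, model, thresholds)
    back = _render_side(back_lobes, bgeo)
    seat = _render_side(seat_lobes, sgeo)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        back = back * (1.0 + noise_sd * gen.standard_normal(back.shape))
        seat = seat * (1.0 + noise_sd * gen.standard_normal(seat.shape))
    back = np.clip(back, 0.0, None)
    seat = np.clip(seat, 0.0, None)
    back[back < pressure_cutoff] = 0.0
    seat[seat < pressure_cutoff] = 0.0
    return back + noise_floor, seat + noise_floor


# ---------------------------------------------------------------------------
# scenario generation

_BAND_MARGIN = 0.10  # fraction of band width kept clear of class boundaries


def _draw_in_band(rng: np.random.Generator, lo: float, hi: float, sign: float) -> float:
    width = hi - lo
    return sign * rng.uniform(lo + _BAND_MARGIN * width, hi - _BAND_MARGIN * width)


def _draw_trunk(rng: np.random.Generator, tp: str, sign: float, thr: ClassThresholds) -> TrunkAngles:
    db, tp4, outer = thr.dead_band_deg, thr.tp4_lateral_min_deg, thr.angle_band_max_deg
    small = lambda: _draw_in_band(rng, -db, db, 1.0)  # inside the dead band
    if tp == "TP0":
        return TrunkAngles(small(), small(), small())
    if tp == "TP2":
        return TrunkAngles(small(), _draw_in_band(rng, db, outer, sign), small())
    if tp == "TP3":
        return TrunkAngles(_draw_in_band(rng, db, outer, sign), small(), small())
    if tp == "TP1":
        return TrunkAngles(small(), small(), _draw_in_band(rng, db, tp4, sign))
    if tp == "TP4":
        return TrunkAngles(small(), small(), _draw_in_band(rng, tp4, outer, sign))
    raise ValueError(f"unknown trunk class {tp!r}")


def _draw_foot(
    rng: np.random.Generator, zones: dict[str, tuple[float, float]], cls: str,
    jitter_cm: float,
) -> FootPosition:
    cx, cy = zones[cls]
    r = jitter_cm * np.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * np.pi)
    return FootPosition(cx + r * np.cos(theta), cy + r * np.sin(theta))


def _task_schedule(n_tasks: int) -> list[PostureLabel]:
    """Deterministic class combinations visiting all 10 classes."""
    return [
        PostureLabel(f"TP{t % 5}", f"LFP{t % 2}", f"RFP{t % 3}")
        for t in range(n_tasks)
    ]


def generate_dataset(spec: ScenarioSpec, model: BodyContactModel | None = None) -> Dataset:
    """Generate the full synthetic recording bundle plus its label table.

    Every task opens and closes with a 0.5 s standard-posture segment
    (TP0 / LFP0 / RFP0 with tight jitter) and holds one scheduled posture
    combination in between, with per-frame kinematic variation drawn inside
    the class bands (10% margin from the boundaries).
    """
    model = model or BodyContactModel.default()
    thr = spec.thresholds
    rng = np.random.default_rng(spec.seed)
    n_open = standard_segment_length(spec.fps)
    schedule = _task_schedule(spec.n_tasks)
    standard = PostureLabel("TP0", "LFP0", "RFP0")

    recordings: list[Recording] = []
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject = SubjectProfile.sample(f"s{s + 1:02d}", rng)
        for t, task_label in enumerate(schedule):
            task_id = f"t{t + 1:02d}"
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            backs, seats = [], []
            for f in range(spec.n_frames):
                in_standard = f < n_open or f >= spec.n_frames - n_open
                if in_standard:
                    label = standard
                    kin = FrameKinematics(
                        TrunkAngles(*rng.uniform(-2, 2, size=3)),
                        _draw_foot(rng, thr.left_zones, "LFP0", 1.0),
                        _draw_foot(rng, thr.right_zones, "RFP0", 1.0),
                    )
                else:
                    label = task_label
                    kin = FrameKinematics(
                        _draw_trunk(rng, task_label.trunk, sign, thr),
                        _draw_foot(rng, thr.left_zones, task_label.left_foot, 3.0),
                        _draw_foot(rng, thr.right_zones, task_label.right_foot, 3.0),
                    )
                back, seat = render_frames(
                    label, kin, subject, model,
                    noise_sd=spec.noise_sd, noise_floor=spec.noise_floor,
                    rng=rng, thresholds=thr,
                    pressure_cutoff=spec.pressure_cutoff,
                )
                backs.append(back)
                seats.append(seat)
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "task_id": task_id,
                        "frame_index": f,
                        "trunk_rotation_deg": kin.trunk.rotation,
                        "trunk_inclination_deg": kin.trunk.inclination,
                        "trunk_lateral_tilt_deg": kin.trunk.lateral_tilt,
                        "left_foot_x_cm": kin.left_foot.x,
                        "left_foot_y_cm": kin.left_foot.y,
                        "right_foot_x_cm": kin.right_foot.x,
                        "right_foot_y_cm": kin.right_foot.y,
                        "trunk": label.trunk,
                        "left_foot": label.left_foot,
                        "right_foot": label.right_foot,
                    }
                )
            recordings.append(
                Recording(
                    subject_id=subject.subject_id,
                    task_id=task_id,
                    backrest=np.stack(backs),
                    seatpan=np.stack(seats),
                    fps=spec.fps,
                )
            )
    return Dataset(recordings=recordings, labels=pd.DataFrame(rows))
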