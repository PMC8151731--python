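"""Plain-text I/O for pressure frames, recordings and label tables.

Formats
-------
Single frame: one line per mat row, whitespace-separated decimal values,
preceded by optional ``#``-prefixed header lines (``# key: value``) carrying
side / subject / task / frame metadata.

Recording container: one text file per recording holding the ordered frames
of both mats.  Header lines declare the geometry, then blocks of the form
``FRAME <index> <side>`` each followed by the grid lines for that mat.

Label table: delimited text (TSV) with one row per frame carrying the
ground-truth kinematics: subject_id, task_id, frame_index,
trunk_rotation_deg, trunk_inclination_deg, trunk_lateral_tilt_deg,
left_foot_x_cm, left_foot_y_cm, right_foot_x_cm, right_foot_y_cm (plus,
optionally, the assigned posture classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pressuremap import BACKREST, SEATPAN, GeometryError, MatGeometry, PressureFrame

LABEL_COLUMNS = [
    "subject_id",
    "task_id",
    "frame_index",
    "trunk_rotation_deg",
    "trunk_inclination_deg",
    "trunk_lateral_tilt_deg",
    "left_foot_x_cm",
    "left_foot_y_cm",
    "right_foot_x_cm",
    "right_foot_y_cm",
]


def _parse_grid(lines: list[str], geometry: MatGeometry, origin: str) -> np.ndarray:
    try:
        rows = [np.array(ln.split(), dtype=float) for ln in lines]
        values = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    except ValueError as exc:  # ragged rows
        raise GeometryError(f"{origin}: inconsistent row lengths ({exc})") from exc
    if values.ndim != 2 or values.shape != geometry.shape:
        raise GeometryError(
            f"{origin}: expected grid of shape {geometry.shape}, found {values.shape}"
        )
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(f"{origin}: negative pressure value at cell ({r}, {c})")
    return values


def read_frame(path: str | Path, geometry: MatGeometry) -> PressureFrame:
    """Read a single-frame grid file; header metadata populates the frame."""
    path = Path(path)
    meta: dict[str, str] = {}
    grid_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        grid_lines.append(line)
    values = _parse_grid(grid_lines, geometry, str(path))
    return PressureFrame(
        geometry,
        values,
        frame_index=int(meta.get("frame", 0)),
        subject_id=meta.get("subject", ""),
        task_id=meta.get("task", ""),
    )


def write_frame(frame: PressureFrame, path: str | Path, precision: int = 6) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# side: {frame.geometry.side}\n")
        if frame.subject_id:
            fh.write(f"# subject: {frame.subject_id}\n")
        if frame.task_id:
            fh.write(f"# task: {frame.task_id}\n")
        fh.write(f"# frame: {frame.frame_index}\n")
        np.savetxt(fh, frame.values, fmt=f"%.{precision}g")


@dataclass
class Recording:
    """Ordered frame pairs for one (subject, task): both mats, all instants."""

    subject_id: str
    task_id: str
    backrest: np.ndarray  # (n_frames, n_rows, n_cols)
    seatpan: np.ndarray
    fps: float = 25.0
    backrest_geometry: MatGeometry = field(default_factory=MatGeometry.backrest)
    seatpan_geometry: MatGeometry = field(default_factory=MatGeometry.seatpan)

    def __post_init__(self) -> None:
        self.backrest = np.asarray(self.backrest, dtype=float)
        self.seatpan = np.asarray(self.seatpan, dtype=float)
        if len(self.backrest) != len(self.seatpan):
            raise ValueError("backrest and seat pan frame counts differ")

    @property
    def n_frames(self) -> int:
        return len(self.backrest)

    def frame_pair(self, i: int) -> tuple[PressureFrame, PressureFrame]:
        kw = dict(frame_index=i, subject_id=self.subject_id, task_id=self.task_id)
        return (
            PressureFrame(self.backrest_geometry, self.backrest[i], **kw),
            PressureFrame(self.seatpan_geometry, self.seatpan[i], **kw),
        )


def write_recording(rec: Recording, path: str | Path, precision: int = 6) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# pressurepose-recording: 1\n")
        fh.write(f"# subject: {rec.subject_id}\n")
        fh.write(f"# task: {rec.task_id}\n")
        fh.write(f"# fps: {rec.fps}\n")
        for side, geo in ((BACKREST, rec.backrest_geometry), (SEATPAN, rec.seatpan_geometry)):
            fh.write(f"# geometry {side}: {geo.n_rows} {geo.n_cols} {geo.cell_size}\n")
        for i in range(rec.n_frames):
            for side, stack in ((BACKREST, rec.backrest), (SEATPAN, rec.seatpan)):
                fh.write(f"FRAME {i} {side}\n")
                np.savetxt(fh, stack[i], fmt=f"%.{precision}g")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta: dict[str, str] = {}
    geometries: dict[str, MatGeometry] = {}
    blocks: dict[str, list[np.ndarray]] = {BACKREST: [], SEATPAN: []}
    current: list[str] | None = None
    current_side = ""

    def flush() -> None:
        if current is not None:
            geo = geometries[current_side]
            blocks[current_side].append(_parse_grid(current, geo, str(path)))

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            if key.startswith("geometry"):
                side = key.split()[1]
                nr, nc, cs = val.split()
                geometries[side] = MatGeometry(side, int(nr), int(nc), float(cs))
            else:
                meta[key] = val
            continue
        if line.startswith("FRAME"):
            flush()
            _, _, current_side = line.split()
            current = []
            continue
        if current is None:
            raise ValueError(f"{path}: grid data before any FRAME header")
        current.append(line)
    flush()
    if len(blocks[BACKREST]) != len(blocks[SEATPAN]):
        raise ValueError(f"{path}: unequal backrest/seatpan frame counts")
    return Recording(
        subject_id=meta.get("subject", ""),
        task_id=meta.get("task", ""),
        backrest=np.stack(blocks[BACKREST]),
        seatpan=np.stack(blocks[SEATPAN]),
        fps=float(meta.get("fps", 25.0)),
        backrest_geometry=geometries.get(BACKREST, MatGeometry.backrest()),
        seatpan_geometry=geometries.get(SEATPAN, MatGeometry.seatpan()),
    )


@dataclass
class Dataset:
    """A set of recordings plus the aligned ground-truth label table."""

    recordings: list[Recording]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"label table is missing columns: {missing}")

    def recording(self, subject_id: str, task_id: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.task_id == task_id:
                return rec
        raise KeyError((subject_id, task_id))


def save_dataset(dataset: Dataset, out_dir: str | Path, precision: int = 6) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        write_recording(rec, out_dir / f"{rec.subject_id}_{rec.task_id}.rec", precision)
    dataset.labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)


def load_dataset(in_dir: str | Path) -> Dataset:
    in_dir = Path(in_dir)
    recordings = [read_recording(p) for p in sorted(in_dir.glob("*.rec"))]
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t")
    return Dataset(recordings=recordings, labels=labels)
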