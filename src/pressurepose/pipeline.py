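"""End-to-end plumbing: recordings -> relative features -> per-body-part
classification -> reduced-layout benchmark.

The unit of analysis is the *relative* feature vector of a frame pair: the
200 candidate features minus their reference values, where the reference is
the mean feature vector over the first 0.5 s of the task (the standard
posture that opens every task).  Each body part (trunk, left foot, right
foot) gets its own sample set — redundancy-filtered independently — and its
own classifier; the study-level summary averages the per-class F1 scores of
all ten classes without support weighting.

A reduced sensor layout is evaluated by sampling every full-resolution frame
at the layout's key points, reconstructing the full grid by IDW, recomputing
the *same* features from the reconstruction, and repeating the LOSO
evaluation; per-class paired t-tests (paired by held-out subject) compare
each layout against the full-resolution benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureDescriptor, FeatureExtractor
from .io import Dataset
from .labeling import BODY_PARTS, ALL_CLASSES, label_table, redundancy_filter
from .layouts import generate_layout, reconstruct_stack
from .mleval import ClassifierConfig, LosoResult, loso_cv, paired_fold_ttest
from .synth import standard_segment_length


@dataclass
class FeatureTable:
    """Relative feature matrix aligned row-for-row with the label table."""

    X: np.ndarray  # (n_frames, n_features) relative features
    descriptors: list[FeatureDescriptor]
    labels: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def columns_for(self, names: list[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.feature_names)}
        return np.array([index[n] for n in names])


def extract_feature_table(
    dataset: Dataset,
    extractor: FeatureExtractor | None = None,
    layout_level: int | None = None,
    idw_power: float = 2.0,
    idw_neighbors: int = 4,
) -> FeatureTable:
    """Compute relative features for every frame of every recording.

    With ``layout_level`` set, each frame is first downsampled to that
    layout and IDW-reconstructed, emulating a reduced-resolution mat.
    """
    extractor = extractor or FeatureExtractor()
    layout = generate_layout(layout_level) if layout_level is not None else None
    labels = dataset.labels
    if not all(c in labels.columns for c in BODY_PARTS):
        labels = label_table(labels)

    blocks: list[np.ndarray] = []
    ordered_rows: list[pd.DataFrame] = []
    for (subject_id, task_id), grp in labels.groupby(
        ["subject_id", "task_id"], sort=False
    ):
        rec = dataset.recording(str(subject_id), str(task_id))
        grp = grp.sort_values("frame_index")
        if len(grp) != rec.n_frames:
            raise ValueError(
                f"label rows ({len(grp)}) != frames ({rec.n_frames}) "
                f"for {subject_id}/{task_id}"
            )
        back, seat = rec.backrest, rec.seatpan
        if layout is not None:
            back = reconstruct_stack(back, layout, rec.backrest_geometry,
                                     idw_power, idw_neighbors)
            seat = reconstruct_stack(seat, layout, rec.seatpan_geometry,
                                     idw_power, idw_neighbors)
        M = extractor.compute_matrix(back, seat)
        n_ref = min(standard_segment_length(rec.fps), len(M))
        reference = M[:n_ref].mean(axis=0)
        blocks.append(M - reference)
        ordered_rows.append(grp)
    X = np.vstack(blocks)
    out_labels = pd.concat(ordered_rows, ignore_index=True)
    return FeatureTable(X=X, descriptors=extractor.descriptors, labels=out_labels)


def body_part_samples(
    table: FeatureTable,
    body_part: str,
    apply_filter: bool = True,
    keep_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, groups, keep_mask) for one body part's classification problem.

    ``keep_mask`` can be supplied to reuse a filter decision (e.g. so a
    layout condition classifies exactly the frames the benchmark kept).
    """
    if keep_mask is None:
        keep_mask = (
            redundancy_filter(table.labels, body_part)
            if apply_filter
            else np.ones(len(table.labels), dtype=bool)
        )
    y = table.labels[body_part].to_numpy()[keep_mask]
    groups = table.labels["subject_id"].to_numpy()[keep_mask]
    return table.X[keep_mask], y, groups, keep_mask


@dataclass
class EvaluationResult:
    """Per-body-part LOSO results plus the ten-class summary row."""

    per_part: dict[str, LosoResult]

    def class_f1(self) -> pd.Series:
        values = {}
        for part, res in self.per_part.items():
            for cls, f1 in zip(res.report.classes, res.report.f1):
                values[cls] = float(f1)
        ordered = {c: values[c] for c in ALL_CLASSES if c in values}
        return pd.Series(ordered, name="f1")

    @property
    def average_f1(self) -> float:
        """Unweighted mean F1 across all posture classes of all body parts."""
        return float(self.class_f1().mean())


def evaluate_dataset(
    table: FeatureTable,
    config: ClassifierConfig | None = None,
    feature_subset: dict[str, list[str]] | None = None,
    seed: int = 0,
    apply_filter: bool = True,
    keep_masks: dict[str, np.ndarray] | None = None,
) -> tuple[EvaluationResult, dict[str, np.ndarray]]:
    """Run the per-body-part LOSO evaluation on a feature table.

    ``feature_subset`` optionally maps body part -> list of feature names
    (the selected important features); by default all candidates are used.
    Returns the result and the per-part keep-masks actually used.
    """
    config = config or ClassifierConfig.default("RF")
    results: dict[str, LosoResult] = {}
    masks: dict[str, np.ndarray] = {}
    for part in BODY_PARTS:
        X, y, groups, mask = body_part_samples(
            table,
            part,
            apply_filter=apply_filter,
            keep_mask=None if keep_masks is None else keep_masks[part],
        )
        idx = (
            table.columns_for(feature_subset[part])
            if feature_subset and part in feature_subset
            else None
        )
        results[part] = loso_cv(X, y, groups, config, seed=seed, feature_idx=idx)
        masks[part] = mask
    return EvaluationResult(per_part=results), masks


@dataclass
class LayoutBenchmark:
    """Per-class F1 by layout with significance against the benchmark."""

    benchmark: EvaluationResult
    by_level: dict[int, EvaluationResult]
    significance: dict[int, pd.DataFrame] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = {"full": self.benchmark.class_f1()}
        for level in sorted(self.by_level):
            rows[f"D{level}"] = self.by_level[level].class_f1()
        df = pd.DataFrame(rows).T
        df["average"] = df.mean(axis=1)
        return df

    def flags(self) -> pd.DataFrame:
        """'**' for p<0.01, '*' for 0.01<=p<0.05, '' otherwise."""
        out = {}
        for level, sig in sorted(self.significance.items()):
            out[f"D{level}"] = sig.apply(
                lambda r: "**" if r.sig_01 else ("*" if r.sig_05 else ""), axis=1
            )
        return pd.DataFrame(out).T


def benchmark_layouts(
    dataset: Dataset,
    levels: list[int],
    config: ClassifierConfig | None = None,
    feature_subset: dict[str, list[str]] | None = None,
    extractor: FeatureExtractor | None = None,
    idw_power: float = 2.0,
    idw_neighbors: int = 4,
    seed: int = 0,
    apply_filter: bool = True,
) -> LayoutBenchmark:
    """Evaluate reduced layouts against the full-resolution benchmark.

    Every layout condition reuses the benchmark's redundancy-filter
    decisions and feature subset, so only the sensing resolution differs.
    """
    config = config or ClassifierConfig.default("RF")
    extractor = extractor or FeatureExtractor()
    full = extract_feature_table(dataset, extractor)
    bench, masks = evaluate_dataset(
        full, config, feature_subset, seed=seed, apply_filter=apply_filter
    )
    by_level: dict[int, EvaluationResult] = {}
    significance: dict[int, pd.DataFrame] = {}
    for level in levels:
        table = extract_feature_table(
            dataset, extractor, layout_level=level,
            idw_power=idw_power, idw_neighbors=idw_neighbors,
        )
        res, _ = evaluate_dataset(
            table, config, feature_subset, seed=seed, keep_masks=masks
        )
        by_level[level] = res
        sig_parts = []
        for part in BODY_PARTS:
            sig_parts.append(
                paired_fold_ttest(bench.per_part[part], res.per_part[part])
            )
        significance[level] = pd.concat(sig_parts)
    return LayoutBenchmark(benchmark=bench, by_level=by_level, significance=significance)
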