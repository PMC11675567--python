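"""Per-recording feature vectors and the subject-by-indicator table.

Each task recording yields the 23-feature vector of the catalog; a
subject's eight recordings concatenate to one 184-column row named
``<task>__<feature>``. Perturbation measures on syllable-train (DDK)
recordings are computed within each voiced burst of at least
``min_segment_cycles`` cycles and averaged weighted by cycle count, so
inter-syllable gaps are never read as glottal periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .._missing import MissingValue, as_float, is_missing
from ..waveform import Waveform
from . import catalog
from .perturbation import compute_jitter, compute_shimmer
from .periods import PeriodSequence, detect_periods
from .spectral import (
    compute_hnr,
    f0_statistics,
    formant_statistics,
    measure_duration,
    track_formants,
    track_pitch,
)

__all__ = [
    "FeatureConfig",
    "TaskRecording",
    "FeatureVector",
    "extract_features",
    "build_feature_table",
    "write_feature_table_csv",
    "read_feature_table_csv",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable analysis settings shared by all feature extractors."""

    f0_min: float = 60.0
    f0_max: float = 400.0
    frame_s: float = 0.040
    hop_s: float = 0.010
    voicing_threshold: float = 0.45
    #: minimum cycles for a DDK voiced segment to enter perturbation stats
    min_segment_cycles: int = 5
    endpoint_threshold_db: float = 25.0


@dataclass(frozen=True)
class TaskRecording:
    """One subject's recording of one of the eight speech tasks."""

    task_id: str
    waveform: Waveform
    subject_id: str

    def __post_init__(self) -> None:
        if self.task_id not in catalog.TASK_IDS:
            raise ValueError(
                f"task_id must be one of {catalog.TASK_IDS}, got {self.task_id!r}"
            )

    @property
    def is_ddk(self) -> bool:
        return self.task_id in catalog.DDK_TASKS


@dataclass(frozen=True)
class FeatureVector:
    """The 23 named features of one task recording."""

    values: Mapping[str, float | MissingValue]

    def __post_init__(self) -> None:
        if tuple(self.values) != catalog.FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 23 catalog features")
        for name, v in self.values.items():
            if not is_missing(v) and _is_relative(name) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def __getitem__(self, name: str) -> float | MissingValue:
        return self.values[name]

    def as_floats(self) -> dict[str, float]:
        return {k: as_float(v) for k, v in self.values.items()}

    def missing_reasons(self) -> dict[str, str]:
        return {k: v.reason for k, v in self.values.items() if is_missing(v)}


def _is_relative(name: str) -> bool:
    return name.endswith("Jitter") or name.endswith("Shimmer")


def _segmentwise(
    seq: PeriodSequence, min_cycles: int, func, variant: str
) -> float | MissingValue:
    """Cycle-count-weighted average of a perturbation measure over segments."""
    values, weights = [], []
    for segment in seq.segments():
        if segment.n < min_cycles:
            continue
        v = func(segment, variant)
        if not is_missing(v):
            values.append(v)
            weights.append(segment.n)
    if not values:
        return MissingValue("no_segment_with_enough_cycles")
    return float(np.average(values, weights=weights))


def extract_features(
    rec: TaskRecording, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Compute all 23 catalog features for one task recording."""
    wave = rec.waveform
    kwargs = dict(
        f0_min=config.f0_min,
        f0_max=config.f0_max,
        frame_s=config.frame_s,
        hop_s=config.hop_s,
        voicing_threshold=config.voicing_threshold,
    )
    seq = detect_periods(wave, **kwargs)
    values: dict[str, float | MissingValue] = {}

    jitter_variant = {
        "localJitter": "local",
        "localabsoluteJitter": "absolute",
        "rapJitter": "rap",
        "ppq5Jitter": "ppq5",
        "ddpJitter": "ddp",
    }
    shimmer_variant = {
        "localShimmer": "local",
        "localdbShimmer": "local_db",
        "apq3Shimmer": "apq3",
        "apq5Shimmer": "apq5",
        "apq11Shimmer": "apq11",
        "ddaShimmer": "dda",
    }
    if rec.is_ddk:
        for name, variant in jitter_variant.items():
            values[name] = _segmentwise(
                seq, config.min_segment_cycles, compute_jitter, variant
            )
        for name, variant in shimmer_variant.items():
            values[name] = _segmentwise(
                seq, config.min_segment_cycles, compute_shimmer, variant
            )
    else:
        for name, variant in jitter_variant.items():
            values[name] = compute_jitter(seq, variant)
        for name, variant in shimmer_variant.items():
            values[name] = compute_shimmer(seq, variant)

    values["hnr"] = compute_hnr(wave, **kwargs)
    values["duration"] = measure_duration(
        wave, threshold_db=config.endpoint_threshold_db
    )
    mean_f0, stdev_f0 = f0_statistics(track_pitch(wave, **kwargs))
    values["meanF0"] = mean_f0
    values["stdevF0"] = stdev_f0

    stats = formant_statistics(
        track_formants(
            wave,
            f0_min=config.f0_min,
            f0_max=config.f0_max,
            voicing_threshold=config.voicing_threshold,
        )
    )
    if is_missing(stats):
        for i in range(4):
            values[f"meanF{i + 1}"] = stats
            values[f"medianF{i + 1}"] = stats
    else:
        for i in range(4):
            values[f"meanF{i + 1}"] = stats.means[i]
            values[f"medianF{i + 1}"] = stats.medians[i]

    ordered = {name: values[name] for name in catalog.FEATURE_NAMES}
    return FeatureVector(values=ordered)


def build_feature_table(
    recordings: Iterable[TaskRecording], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Subjects x 184 indicator table from per-task recordings.

    One row per subject (order of first appearance); a subject's missing
    tasks leave their 23 columns as NaN. Duplicate (subject, task) pairs
    are an input error.
    """
    seen: set[tuple[str, str]] = set()
    by_subject: dict[str, dict[str, FeatureVector]] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.task_id)
        if key in seen:
            raise ValueError(f"duplicate recording for subject/task pair {key}")
        seen.add(key)
        by_subject.setdefault(rec.subject_id, {})[rec.task_id] = extract_features(
            rec, config
        )
    columns = catalog.indicator_names()
    rows = []
    for subject_id, tasks in by_subject.items():
        row: dict[str, float] = {}
        for task in catalog.TASK_IDS:
            if task in tasks:
                for feat, value in tasks[task].as_floats().items():
                    row[f"{task}__{feat}"] = value
            else:
                for feat in catalog.FEATURE_NAMES:
                    row[f"{task}__{feat}"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(list(by_subject), name="subject_id"))
    return table[columns]


def write_feature_table_csv(path, table: pd.DataFrame) -> None:
    """Write a feature table CSV (missing values as empty cells)."""
    table.to_csv(path, index=True)


def read_feature_table_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="subject_id")
    unknown = [c for c in table.columns if c not in catalog.indicator_names()]
    if unknown:
        raise ValueError(f"unexpected feature columns: {unknown[:5]}")
    return table
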