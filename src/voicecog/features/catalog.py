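"""Names of the speech tasks and the per-task acoustic feature set.

Eight tasks (three sustained vowels, one vowel prolongation, three
alternating-motion-rate syllable repetitions and one sequential-motion-rate
task) times 23 features per task gives the 184 indicator columns, named
``<task>__<feature>``.
"""

from __future__ import annotations

__all__ = [
    "TASK_IDS",
    "VOWEL_TASKS",
    "DDK_TASKS",
    "JITTER_FEATURES",
    "SHIMMER_FEATURES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "N_INDICATORS",
    "indicator_names",
    "split_indicator",
]

VOWEL_TASKS = ("a", "i", "u", "a_prolonged")
DDK_TASKS = ("puh", "tuh", "kuh", "puhtuhkuh")
TASK_IDS = VOWEL_TASKS + DDK_TASKS

JITTER_FEATURES = (
    "localJitter",
    "localabsoluteJitter",
    "rapJitter",
    "ppq5Jitter",
    "ddpJitter",
)
SHIMMER_FEATURES = (
    "localShimmer",
    "localdbShimmer",
    "apq3Shimmer",
    "apq5Shimmer",
    "apq11Shimmer",
    "ddaShimmer",
)
PITCH_FEATURES = ("meanF0", "stdevF0")
FORMANT_FEATURES = (
    "meanF1",
    "meanF2",
    "meanF3",
    "meanF4",
    "medianF1",
    "medianF2",
    "medianF3",
    "medianF4",
)

#: The 23 features extracted from every task recording.
FEATURE_NAMES = (
    JITTER_FEATURES
    + SHIMMER_FEATURES
    + ("hnr", "duration")
    + PITCH_FEATURES
    + FORMANT_FEATURES
)

N_FEATURES = len(FEATURE_NAMES)
N_INDICATORS = len(TASK_IDS) * N_FEATURES

assert N_FEATURES == 23 and N_INDICATORS == 184


def indicator_names() -> list[str]:
    """The 184 ``<task>__<feature>`` column names in canonical order."""
    return [f"{task}__{feat}" for task in TASK_IDS for feat in FEATURE_NAMES]


def split_indicator(name: str) -> tuple[str, str]:
    """Split an indicator column name into (task_id, feature_name)."""
    task, sep, feat = name.partition("__")
    if not sep or task not in TASK_IDS or feat not in FEATURE_NAMES:
        raise ValueError(f"not a valid indicator name: {name!r}")
    return task, feat
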