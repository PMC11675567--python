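"""Study configuration: a TOML file with one block per pipeline stage.

Example::

    seed = 7
    output_dir = "out"

    [synthesis]
    n_severe = 10
    n_mild = 8
    n_normal = 12
    sample_rate_hz = 16000

    [features]
    f0_min = 60.0
    f0_max = 400.0

    [classification]
    families = ["linear_logistic", "random_forest"]
    search_budget = 8

    [explain]
    background_size = 50
    n_permutations = 100
"""

from __future__ import annotations

import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .classify import MODEL_FAMILIES
from .features import FeatureConfig

__all__ = ["ConfigError", "StudyConfig", "stage_seed", "load_config"]

REQUIRED_BLOCKS = ("synthesis", "features", "classification", "explain")


class ConfigError(ValueError):
    """Invalid or incomplete study configuration."""


@dataclass(frozen=True)
class SynthesisConfig:
    n_severe: int = 10
    n_mild: int = 8
    n_normal: int = 12
    sample_rate_hz: int = 16000
    vowel_duration_s: float = 2.0
    prolonged_duration_s: float = 4.0
    ddk_syllable_rate_hz: float = 4.5
    ddk_n_syllables: int = 8
    ddk_gap_fraction: float = 0.4


@dataclass(frozen=True)
class ClassificationConfig:
    families: tuple[str, ...] = MODEL_FAMILIES
    search_budget: int = 30
    test_fraction: float = 0.2
    n_folds: int = 5

    def __post_init__(self) -> None:
        bad = [f for f in self.families if f not in MODEL_FAMILIES]
        if bad:
            raise ConfigError(f"unknown model families: {bad}")
        if not self.families:
            raise ConfigError("at least one model family is required")


@dataclass(frozen=True)
class ExplainConfig:
    background_size: int = 50
    n_permutations: int = 200
    top_k: int = 20


@dataclass(frozen=True)
class StudyConfig:
    seed: int
    output_dir: Path
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (int(global_seed) + zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)


def _build(cls, block: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    try:
        if "families" in block:
            block = {**block, "families": tuple(block["families"])}
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] block: {exc}") from exc


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a study TOML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"malformed TOML: {exc}") from exc
    if "seed" not in raw:
        raise ConfigError("config must set a global 'seed'")
    missing = [b for b in REQUIRED_BLOCKS if b not in raw]
    if missing:
        raise ConfigError(f"config is missing required blocks: {missing}")
    output_dir = Path(raw.get("output_dir", "voicecog_out"))
    if not output_dir.is_absolute():
        output_dir = path.parent / output_dir
    return StudyConfig(
        seed=int(raw["seed"]),
        output_dir=output_dir,
        synthesis=_build(SynthesisConfig, raw["synthesis"], "synthesis"),
        features=_build(FeatureConfig, raw["features"], "features"),
        classification=_build(ClassificationConfig, raw["classification"], "classification"),
        explain=_build(ExplainConfig, raw["explain"], "explain"),
    )
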