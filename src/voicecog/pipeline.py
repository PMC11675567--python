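"""End-to-end study orchestration: synthesize -> extract -> demographics ->
classify -> explain, with deterministic per-stage seeds and a run manifest.

Each stage writes flat CSV/WAV/text artifacts into the configured output
directory; the manifest records a SHA-256 digest per artifact so two runs
with the same config and seed can be compared byte-for-byte (timestamps
excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ModelSpec,
    SplitConfig,
    TrainedModel,
    evaluate,
    make_tasks,
    stratified_split,
    task_data,
    tune_and_train,
)
from .cohort import Subject, demographic_report, read_roster_csv, write_roster_csv
from .config import StudyConfig, stage_seed
from .explain import ShapleyProblem, explain_instances, rank_features
from .features import (
    FeatureConfig,
    TaskRecording,
    VOWEL_TASKS,
    TASK_IDS,
    build_feature_table,
    read_feature_table_csv,
    write_feature_table_csv,
)
from .synthesis import (
    DDKSynthesisParams,
    VoiceSynthesisParams,
    generate_roster,
    synthesize_ddk,
    synthesize_vowel,
)
from .waveform import read_wav, write_wav

__all__ = ["StageError", "RunManifest", "run_study", "synthesize_cohort_audio",
           "extract_stage", "demographics_stage", "classify_stage", "explain_stage"]

log = logging.getLogger("voicecog")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: dict  # stage -> {artifact path -> sha256}
    started_at: float
    finished_at: float
    versions: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_tree(paths: Sequence[Path], root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _digest(p) for p in sorted(paths)}


# --------------------------------------------------------------------------
# Stage 1: synthesis
# --------------------------------------------------------------------------

#: Stand-in per-group voice degradation levels (jitter %, shimmer %, SNR dB).
#: Invented effect sizes -- they create learnable group structure, nothing more.
GROUP_VOICE_LEVELS: Mapping[str, tuple[float, float, float]] = {
    "severe": (2.8, 7.0, 10.0),
    "mild": (1.8, 4.5, 15.0),
    "normal": (0.8, 2.5, 22.0),
}

#: Vowel-dependent formant presets (centre Hz, bandwidth Hz).
TASK_FORMANTS: Mapping[str, tuple[tuple[float, float], ...]] = {
    "a": ((730, 90), (1090, 110), (2440, 160), (3400, 200)),
    "i": ((350, 80), (1900, 120), (2600, 160), (3500, 200)),
    "u": ((380, 80), (950, 100), (2400, 160), (3300, 200)),
}
TASK_FORMANTS = {
    **TASK_FORMANTS,
    "a_prolonged": TASK_FORMANTS["a"],
    "puh": TASK_FORMANTS["a"],
    "tuh": TASK_FORMANTS["a"],
    "kuh": TASK_FORMANTS["a"],
    "puhtuhkuh": TASK_FORMANTS["a"],
}


def _subject_voice_params(
    subject: Subject, task: str, config: StudyConfig, rng: np.random.Generator
) -> VoiceSynthesisParams:
    jitter, shimmer, snr = GROUP_VOICE_LEVELS[subject.group.value]
    wobble = rng.lognormal(0.0, 0.25, size=3)
    f0 = rng.normal(115.0, 12.0) if subject.sex == "male" else rng.normal(200.0, 18.0)
    synth = config.synthesis
    duration = (
        synth.prolonged_duration_s if task == "a_prolonged" else synth.vowel_duration_s
    )
    return VoiceSynthesisParams(
        f0_hz=float(np.clip(f0, 80.0, 320.0)),
        duration_s=duration,
        sample_rate_hz=synth.sample_rate_hz,
        jitter_pct=float(jitter * wobble[0]),
        shimmer_pct=float(shimmer * wobble[1]),
        noise_snr_db=float(snr + rng.normal(0.0, 2.0)),
        formants_hz=TASK_FORMANTS[task],
    )


def synthesize_cohort_audio(
    config: StudyConfig, out_dir: Path
) -> tuple[list[Subject], list[Path]]:
    """Stage 1: roster CSV plus one WAV per subject per task."""
    seed = stage_seed(config.seed, "synth")
    synth = config.synthesis
    roster = generate_roster(
        (synth.n_severe, synth.n_mild, synth.n_normal), seed
    )
    wav_dir = out_dir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed + 1)
    paths = []
    for subject in roster:
        for task in TASK_IDS:
            params = _subject_voice_params(subject, task, config, rng)
            wav_seed = int(rng.integers(0, 2**31 - 1))
            if task in VOWEL_TASKS:
                wave = synthesize_vowel(params, wav_seed)
            else:
                wave = synthesize_ddk(
                    DDKSynthesisParams(
                        base=params,
                        syllable_rate_hz=synth.ddk_syllable_rate_hz,
                        n_syllables=synth.ddk_n_syllables,
                        gap_fraction=synth.ddk_gap_fraction,
                    ),
                    wav_seed,
                )
            path = wav_dir / f"{subject.subject_id}__{task}.wav"
            write_wav(path, wave)
            paths.append(path)
    roster_path = out_dir / "roster.csv"
    write_roster_csv(roster_path, roster)
    log.info("synth: %d subjects, %d recordings", len(roster), len(paths))
    return roster, paths + [roster_path]


# --------------------------------------------------------------------------
# Stage 2: extraction
# --------------------------------------------------------------------------


def extract_stage(
    wav_dir: Path, out_path: Path, feature_config: FeatureConfig
) -> pd.DataFrame:
    """Stage 2: read ``<subject>__<task>.wav`` files into the 184-column table."""
    wavs = sorted(Path(wav_dir).glob("*.wav"))
    if not wavs:
        raise StageError(f"extract: no WAV files in {wav_dir}")
    recordings = []
    for path in wavs:
        stem = path.stem
        subject_id, sep, task = stem.partition("__")
        if not sep:
            raise StageError(
                f"extract: cannot parse subject/task from file name {path.name!r}"
            )
        recordings.append(
            TaskRecording(task_id=task, waveform=read_wav(path), subject_id=subject_id)
        )
    table = build_feature_table(recordings, feature_config)
    write_feature_table_csv(out_path, table)
    log.info("extract: %d subjects x %d indicators", *table.shape)
    return table


# --------------------------------------------------------------------------
# Stage 3: demographics
# --------------------------------------------------------------------------


def demographics_stage(roster: Sequence[Subject], out_dir: Path) -> list[Path]:
    """Stage 3: demographic report as text plus machine-readable CSV."""
    report = demographic_report(roster)
    text_path = out_dir / "demographics.txt"
    text_path.write_text(report.to_text() + "\n")
    rows = []
    for var, (h, p, df) in report.kruskal.items():
        rows.append({"variable": var, "test": "kruskal_wallis", "statistic": h, "p": p, "df": df})
    chi2, p, df = report.chi_square_sex
    rows.append({"variable": "sex", "test": "chi_square", "statistic": chi2, "p": p, "df": df})
    for var, pairs in report.posthoc.items():
        for (a, b), pp in pairs.items():
            rows.append(
                {"variable": var, "test": f"mannwhitney_bonferroni:{a}_vs_{b}",
                 "statistic": float("nan"), "p": pp, "df": float("nan")}
            )
    csv_path = out_dir / "demographics.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return [text_path, csv_path]


# --------------------------------------------------------------------------
# Stage 4: classification
# --------------------------------------------------------------------------


def classify_stage(
    table: pd.DataFrame,
    roster: Sequence[Subject],
    config: StudyConfig,
    out_dir: Path,
) -> tuple[list[Path], dict]:
    """Stage 4: three tasks x configured families; returns eval artifacts
    plus the per-task best model context needed by the explain stage."""
    seed = stage_seed(config.seed, "classify")
    cls_cfg = config.classification
    split_cfg = SplitConfig(
        test_fraction=cls_cfg.test_fraction, n_folds=cls_cfg.n_folds, seed=seed
    )
    tasks = make_tasks(roster)
    if not tasks:
        raise StageError("classify: no classification task has both classes")
    rows = []
    best_ctx: dict[str, dict] = {}
    model_dir = out_dir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for task in tasks:
        X, y = task_data(task, table, roster)
        try:
            train_idx, test_idx = stratified_split(y, split_cfg)
        except ValueError as exc:
            raise StageError(f"classify[{task.name}]: {exc}") from exc
        best: tuple[float, str, TrainedModel] | None = None
        for f_i, family in enumerate(cls_cfg.families):
            spec = ModelSpec(
                family=family, search_budget=cls_cfg.search_budget, seed=seed + 17 * f_i
            )
            trained = tune_and_train(X.iloc[train_idx], y[train_idx], spec, split_cfg)
            report = evaluate(trained, X.iloc[test_idx], y[test_idx], task.counts)
            rows.append(
                {
                    "task": task.name,
                    "family": family,
                    "pr_auc": report.pr_auc,
                    "auc": report.auc,
                    "accuracy": report.accuracy,
                    "f1": report.f1,
                    "precision": report.precision,
                    "recall": report.recall,
                    "baseline_pr_auc": report.baseline_pr_auc,
                    "improvement_pct": report.improvement_pct,
                    "cv_pr_auc": trained.best_cv_pr_auc,
                }
            )
            log.info(
                "classify[%s/%s]: PR-AUC %.3f (baseline %.3f)",
                task.name, family, report.pr_auc, report.baseline_pr_auc,
            )
            if best is None or report.pr_auc > best[0]:
                best = (report.pr_auc, family, trained)
        assert best is not None
        model_path = model_dir / f"{task.name}.pkl"
        with open(model_path, "wb") as fh:
            pickle.dump(best[2], fh)
        best_ctx[task.name] = {
            "family": best[1],
            "trained": best[2],
            "X_train": X.iloc[train_idx],
            "X_test": X.iloc[test_idx],
            "y_test": y[test_idx],
        }
    eval_path = out_dir / "evaluation.csv"
    pd.DataFrame(rows).to_csv(eval_path, index=False)
    paths.append(eval_path)
    return paths, best_ctx


# --------------------------------------------------------------------------
# Stage 5: explanation
# --------------------------------------------------------------------------


def explain_stage(best_ctx: dict, config: StudyConfig, out_dir: Path) -> list[Path]:
    """Stage 5: sampled Shapley attributions on each task's test split."""
    seed = stage_seed(config.seed, "explain")
    exp_cfg = config.explain
    paths: list[Path] = []
    for task_name, ctx in best_ctx.items():
        trained: TrainedModel = ctx["trained"]
        X_train: pd.DataFrame = ctx["X_train"]
        X_test: pd.DataFrame = ctx["X_test"]
        background = X_train.to_numpy(dtype=float)[: exp_cfg.background_size]
        problem = ShapleyProblem(
            model_fn=lambda m, p=trained.pipeline: p.predict_proba(m)[:, 1],
            feature_names=tuple(X_train.columns),
            background=background,
        )
        explanation = explain_instances(
            problem,
            X_test.to_numpy(dtype=float),
            n_permutations=exp_cfg.n_permutations,
            seed=seed,
        )
        ranking = rank_features(
            explanation, X_test.to_numpy(dtype=float), top_k=exp_cfg.top_k
        )
        attr = pd.DataFrame(
            explanation.phi, index=X_test.index, columns=list(X_test.columns)
        )
        attr_path = out_dir / f"shap_{task_name}.csv"
        attr.to_csv(attr_path)
        rank_path = out_dir / f"ranking_{task_name}.csv"
        ranking.to_frame().to_csv(rank_path, index=False)
        paths.extend([attr_path, rank_path])
        log.info("explain[%s]: top feature %s", task_name, ranking.features[0])
    return paths


# --------------------------------------------------------------------------
# Full study
# --------------------------------------------------------------------------


def _config_digest(config: StudyConfig) -> str:
    blob = repr(config).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def run_study(config: StudyConfig) -> RunManifest:
    """Execute all five stages and write a manifest; stage failures raise
    :class:`StageError` tagged with the stage name."""
    started = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "settings in effect: f0 range %.0f-%.0f Hz, voicing threshold %.2f, "
        "search budget %d, families %s, test fraction %.2f, folds %d, "
        "shap background %d, permutations %d",
        config.features.f0_min, config.features.f0_max,
        config.features.voicing_threshold, config.classification.search_budget,
        ",".join(config.classification.families), config.classification.test_fraction,
        config.classification.n_folds, config.explain.background_size,
        config.explain.n_permutations,
    )
    stages: dict[str, dict[str, str]] = {}

    def run_stage(name: str, fn):
        log.info("stage %s: start", name)
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(f"{name}: {exc}") from exc

    roster, synth_paths = run_stage("synth", lambda: synthesize_cohort_audio(config, out))
    stages["synth"] = _digest_tree(synth_paths, out)

    features_path = out / "features.csv"
    table = run_stage(
        "extract", lambda: extract_stage(out / "wav", features_path, config.features)
    )
    stages["extract"] = _digest_tree([features_path], out)

    demo_paths = run_stage("demographics", lambda: demographics_stage(roster, out))
    stages["demographics"] = _digest_tree(demo_paths, out)

    classify_paths, best_ctx = run_stage(
        "classify", lambda: classify_stage(table, roster, config, out)
    )
    stages["classify"] = _digest_tree(classify_paths, out)

    explain_paths = run_stage("explain", lambda: explain_stage(best_ctx, config, out))
    stages["explain"] = _digest_tree(explain_paths, out)

    import sklearn

    manifest = RunManifest(
        config_digest=_config_digest(config),
        seed=config.seed,
        stages=stages,
        started_at=started,
        finished_at=time.time(),
        versions={
            "voicecog": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
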