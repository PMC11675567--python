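"""Cohort grouping and demographic statistics.

Subjects are assigned to cognitive-status groups from their K-MMSE score
(0-19 severe, 20-23 mild, 24-30 normal) and compared demographically with
non-parametric tests: Kruskal-Wallis for continuous variables, Pearson
chi-square for sex, pairwise Mann-Whitney with Bonferroni correction post
hoc, plus Shapiro-Wilk / Levene assumption checks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupLabel",
    "Subject",
    "DemographicReport",
    "assign_group",
    "kruskal_wallis",
    "chi_square_independence",
    "posthoc_pairwise",
    "normality_and_variance_checks",
    "demographic_report",
    "roster_to_frame",
    "read_roster_csv",
    "write_roster_csv",
]

GROUP_ORDER = ("severe", "mild", "normal")

#: Inclusive K-MMSE score ranges per group.
KMMSE_RANGES: Mapping[str, tuple[int, int]] = {
    "severe": (0, 19),
    "mild": (20, 23),
    "normal": (24, 30),
}


class GroupLabel(str, enum.Enum):
    SEVERE = "severe"
    MILD = "mild"
    NORMAL = "normal"


@dataclass(frozen=True)
class Subject:
    """One study participant."""

    subject_id: str
    age: float
    education: float
    sex: str  # "male" | "female"
    kmmse: int

    def __post_init__(self) -> None:
        if not 0 <= self.kmmse <= 30:
            raise ValueError(f"kmmse must be in [0, 30], got {self.kmmse}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.education < 0:
            raise ValueError("education must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def group(self) -> GroupLabel:
        return assign_group(self.kmmse)


def assign_group(kmmse: int) -> GroupLabel:
    """Map a K-MMSE score to its cognitive-status group.

    0-19 -> severe, 20-23 -> mild, 24-30 -> normal.
    """
    score = int(kmmse)
    if score != kmmse or not 0 <= score <= 30:
        raise ValueError(f"K-MMSE score must be an integer in [0, 30], got {kmmse}")
    if score <= 19:
        return GroupLabel.SEVERE
    if score <= 23:
        return GroupLabel.MILD
    return GroupLabel.NORMAL


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, int]:
    """Tie-corrected Kruskal-Wallis H test across k groups.

    Returns ``(H, p, df)`` with p from the chi-square distribution with
    k - 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p), len(arrays) - 1


def chi_square_independence(table: Sequence[Sequence[float]]) -> tuple[float, float, int]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(chi2, p, df)`` with df = (r-1)(c-1).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p), int(df)


def posthoc_pairwise(
    groups: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], float]:
    """Bonferroni-corrected pairwise two-sided Mann-Whitney comparisons.

    Each raw p-value is multiplied by the number of comparisons and capped
    at 1. Pairs with a group smaller than 2 observations map to NaN
    (untestable).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.size < 2 or xb.size < 2:
            out[(a, b)] = float("nan")
            continue
        _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out[(a, b)] = min(1.0, float(p) * m)
    return out


def normality_and_variance_checks(
    groups: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Shapiro-Wilk p per group and a single Levene p across groups."""
    shapiro_p: dict[str, float] = {}
    arrays = []
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            raise ValueError(f"group {name!r} needs >= 3 observations")
        shapiro_p[name] = float(stats.shapiro(x).pvalue)
        arrays.append(x)
    levene_p = float(stats.levene(*arrays).pvalue)
    return shapiro_p, levene_p


@dataclass(frozen=True)
class DemographicReport:
    """Group-comparison results for age, education and sex."""

    group_sizes: dict[str, int]
    kruskal: dict[str, tuple[float, float, int]]  # variable -> (H, p, df)
    chi_square_sex: tuple[float, float, int]
    sex_table: pd.DataFrame  # groups x {male, female}
    posthoc: dict[str, dict[tuple[str, str], float]]  # variable -> pair -> p
    shapiro: dict[str, dict[str, float]]  # variable -> group -> p
    levene: dict[str, float]  # variable -> p

    def to_text(self) -> str:
        lines = ["Demographic group comparisons", "=" * 34]
        sizes = ", ".join(f"{g}={n}" for g, n in self.group_sizes.items())
        lines.append(f"Group sizes: {sizes}")
        for var, (h, p, df) in self.kruskal.items():
            lines.append(f"{var}: Kruskal-Wallis H = {h:.2f} (df={df}), p = {p:.3g}")
            for (a, b), pp in self.posthoc[var].items():
                lines.append(f"  post hoc {a} vs {b}: corrected p = {pp:.3g}")
        chi2, p, df = self.chi_square_sex
        lines.append(f"sex: chi-square = {chi2:.2f} (df={df}), p = {p:.3g}")
        lines.append(self.sex_table.to_string())
        return "\n".join(lines)


def roster_to_frame(roster: Sequence[Subject]) -> pd.DataFrame:
    """Roster as a DataFrame with a derived ``group`` column."""
    frame = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in roster],
            "age": [s.age for s in roster],
            "education": [s.education for s in roster],
            "sex": [s.sex for s in roster],
            "kmmse": [s.kmmse for s in roster],
        }
    )
    frame["group"] = [s.group.value for s in roster]
    return frame


def demographic_report(roster: Sequence[Subject]) -> DemographicReport:
    """Full demographic comparison across the groups present in *roster*."""
    frame = roster_to_frame(roster)
    present = [g for g in GROUP_ORDER if (frame["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need subjects from at least two groups")

    group_sizes = {g: int((frame["group"] == g).sum()) for g in present}
    kruskal: dict[str, tuple[float, float, int]] = {}
    posthoc: dict[str, dict[tuple[str, str], float]] = {}
    shapiro: dict[str, dict[str, float]] = {}
    levene: dict[str, float] = {}
    for var in ("age", "education"):
        samples = {g: frame.loc[frame["group"] == g, var].to_numpy() for g in present}
        kruskal[var] = kruskal_wallis(list(samples.values()))
        posthoc[var] = posthoc_pairwise(samples)
        shapiro[var], levene[var] = normality_and_variance_checks(samples)

    sex_table = pd.DataFrame(
        {
            sex: [int(((frame["group"] == g) & (frame["sex"] == sex)).sum()) for g in present]
            for sex in ("male", "female")
        },
        index=present,
    )
    chi = chi_square_independence(sex_table.to_numpy())
    return DemographicReport(
        group_sizes=group_sizes,
        kruskal=kruskal,
        chi_square_sex=chi,
        sex_table=sex_table,
        posthoc=posthoc,
        shapiro=shapiro,
        levene=levene,
    )


ROSTER_COLUMNS = ["subject_id", "age", "education", "sex", "kmmse"]


def write_roster_csv(path, roster: Sequence[Subject]) -> None:
    roster_to_frame(roster)[ROSTER_COLUMNS].to_csv(path, index=False)


def read_roster_csv(path) -> list[Subject]:
    frame = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"roster CSV is missing columns: {missing}")
    return [
        Subject(
            subject_id=str(row.subject_id),
            age=float(row.age),
            education=float(row.education),
            sex=str(row.sex),
            kmmse=int(row.kmmse),
        )
        for row in frame.itertuples(index=False)
    ]
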