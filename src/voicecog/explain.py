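"""Shapley-value feature attribution.

The coalition value v(S) is the interventional (marginal) expectation: the
mean model score over a background sample with the coalition's features
pinned to the explained instance. :func:`exact_shapley` evaluates the
Shapley sum literally over all coalitions (feasible up to 15 features);
:func:`sampled_shapley` is the seeded permutation-sampling estimator with
Monte-Carlo standard errors, usable at full dimension. Rankings order
features by mean |phi| with a value-vs-phi correlation as the direction
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShapleyProblem",
    "ShapExplanation",
    "ImportanceRanking",
    "exact_shapley",
    "sampled_shapley",
    "explain_instances",
    "rank_features",
]

EXACT_ENUMERATION_LIMIT = 15


@dataclass(frozen=True)
class ShapleyProblem:
    """A model, its feature names and a background sample."""

    model_fn: Callable[[np.ndarray], np.ndarray]  # (m, d) -> (m,) scores
    feature_names: tuple[str, ...]
    background: np.ndarray  # (b, d)

    def __post_init__(self) -> None:
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", background)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if background.ndim != 2 or background.shape[0] == 0:
            raise ValueError("background must be a non-empty (b, d) array")
        if background.shape[1] != len(self.feature_names):
            raise ValueError("background width must match feature_names")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def base_value(self) -> float:
        return float(np.mean(self.model_fn(self.background)))


@dataclass(frozen=True)
class ShapExplanation:
    """Per-sample, per-feature attributions with the shared base value."""

    feature_names: tuple[str, ...]
    phi: np.ndarray  # (n_samples, d)
    base_value: float
    predictions: np.ndarray  # (n_samples,)
    standard_errors: np.ndarray | None = None  # sampled estimator only

    def additivity_residuals(self) -> np.ndarray:
        """prediction - (base_value + sum(phi)) per sample."""
        return self.predictions - (self.base_value + self.phi.sum(axis=1))


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by mean |phi|, ties broken lexicographically."""

    features: tuple[str, ...]
    mean_abs_phi: tuple[float, ...]
    direction: tuple[float, ...]  # corr(feature value, phi) per feature
    truncated: bool = False  # True when top_k exceeded the feature count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "mean_abs_phi": self.mean_abs_phi,
                "direction": self.direction,
            }
        )


def _coalition_values(problem: ShapleyProblem, instance: np.ndarray) -> np.ndarray:
    """v(S) for every bitmask S, by brute-force marginal expectation."""
    n = problem.n_features
    background = problem.background
    values = np.empty(1 << n)
    for mask in range(1 << n):
        data = background.copy()
        for j in range(n):
            if mask >> j & 1:
                data[:, j] = instance[j]
        values[mask] = float(np.mean(problem.model_fn(data)))
    return values


def exact_shapley(problem: ShapleyProblem, instance: Sequence[float]) -> np.ndarray:
    """Shapley values by full coalition enumeration.

    phi_i = sum over S not containing i of
    |S|! (n - |S| - 1)! / n! * (v(S + i) - v(S)).
    Refuses above 15 features; use :func:`sampled_shapley` there.
    """
    n = problem.n_features
    if n > EXACT_ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration is limited to {EXACT_ENUMERATION_LIMIT} features "
            f"(got {n}); use sampled_shapley"
        )
    instance = np.asarray(instance, dtype=float)
    if instance.shape != (n,):
        raise ValueError("instance must be a flat vector matching the feature count")
    v = _coalition_values(problem, instance)
    weights = np.array(
        [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    )
    sizes = np.array([bin(mask).count("1") for mask in range(1 << n)])
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        without = np.flatnonzero((np.arange(1 << n) & bit) == 0)
        phi[i] = float(
            np.sum(weights[sizes[without]] * (v[without | bit] - v[without]))
        )
    return phi


def sampled_shapley(
    problem: ShapleyProblem,
    instance: Sequence[float],
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley estimate with per-feature standard errors.

    Each draw pairs a random feature order with one background row
    (cycled deterministically -- stratified over the background, which
    keeps the estimator unbiased and lowers its variance) and accumulates
    the marginal contribution of every feature along the order. Returns
    ``(phi, standard_errors)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = problem.n_features
    instance = np.asarray(instance, dtype=float)
    if instance.shape != (n,):
        raise ValueError("instance must be a flat vector matching the feature count")
    rng = np.random.default_rng(seed)
    background = problem.background
    contributions = np.empty((n_permutations, n))
    for m in range(n_permutations):
        order = rng.permutation(n)
        row = background[m % background.shape[0]]
        # prefix matrix: row k has the first k features (in this order) pinned
        prefixes = np.tile(row, (n + 1, 1))
        for k, j in enumerate(order):
            prefixes[k + 1 :, j] = instance[j]
        scores = problem.model_fn(prefixes)
        contributions[m, order] = np.diff(scores)
    phi = contributions.mean(axis=0)
    if n_permutations > 1:
        se = contributions.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    else:
        se = np.full(n, np.nan)
    return phi, se


def explain_instances(
    problem: ShapleyProblem,
    X: np.ndarray | pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
    exact: bool = False,
) -> ShapExplanation:
    """Explain a batch of instances with one shared base value."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != problem.n_features:
        raise ValueError("X must be (n_samples, n_features)")
    rng = np.random.default_rng(seed)
    phis, ses = [], []
    for row in X:
        if exact:
            phis.append(exact_shapley(problem, row))
            ses.append(np.zeros(problem.n_features))
        else:
            phi, se = sampled_shapley(
                problem, row, n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            phis.append(phi)
            ses.append(se)
    return ShapExplanation(
        feature_names=problem.feature_names,
        phi=np.vstack(phis),
        base_value=problem.base_value(),
        predictions=np.asarray(problem.model_fn(X), dtype=float),
        standard_errors=np.vstack(ses),
    )


def rank_features(
    explanation: ShapExplanation,
    X: np.ndarray | pd.DataFrame,
    top_k: int = 20,
) -> ImportanceRanking:
    """Top-k features by mean |phi| with a sign/direction readout.

    Direction is the Pearson correlation between a feature's value and its
    attribution across the explained samples (positive: high values push
    the score up). ``top_k`` beyond the feature count returns everything,
    flagged truncated=False/True accordingly.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != explanation.phi.shape:
        raise ValueError("X must align with the explanation's phi matrix")
    names = explanation.feature_names
    mean_abs = np.abs(explanation.phi).mean(axis=0)
    directions = np.zeros(len(names))
    for j in range(len(names)):
        x, p = X[:, j], explanation.phi[:, j]
        if x.size > 1 and np.std(x) > 0 and np.std(p) > 0:
            directions[j] = float(np.corrcoef(x, p)[0, 1])
    order = sorted(range(len(names)), key=lambda j: (-mean_abs[j], names[j]))
    truncated = top_k > len(names)
    order = order[: min(top_k, len(names))]
    return ImportanceRanking(
        features=tuple(names[j] for j in order),
        mean_abs_phi=tuple(float(mean_abs[j]) for j in order),
        direction=tuple(float(directions[j]) for j in order),
        truncated=truncated,
    )
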