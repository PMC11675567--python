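"""Cycle-to-cycle perturbation measures: the jitter and shimmer families.

All relative variants are percentages of the mean period / mean amplitude;
``absolute`` jitter is in seconds and ``local_db`` shimmer in dB. With
these definitions ddp == 3 * rap and dda == 3 * apq3 identically.
"""

from __future__ import annotations

import numpy as np

from .._missing import MissingValue
from .periods import PeriodSequence

__all__ = [
    "JITTER_VARIANTS",
    "SHIMMER_VARIANTS",
    "compute_jitter",
    "compute_shimmer",
]

JITTER_VARIANTS = ("local", "absolute", "rap", "ppq5", "ddp")
SHIMMER_VARIANTS = ("local", "local_db", "apq3", "apq5", "apq11", "dda")

_JITTER_MIN_CYCLES = {"local": 2, "absolute": 2, "rap": 3, "ppq5": 5, "ddp": 3}
_SHIMMER_MIN_CYCLES = {
    "local": 2,
    "local_db": 2,
    "apq3": 3,
    "apq5": 5,
    "apq11": 11,
    "dda": 3,
}


def _mean_abs_diff(values: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(values))))


def _perturbation_quotient(values: np.ndarray, k: int) -> float:
    """Mean |x_i - k-point centred moving mean| over the valid range."""
    half = k // 2
    windows = np.lib.stride_tricks.sliding_window_view(values, k)
    centres = values[half : values.size - half]
    return float(np.mean(np.abs(centres - windows.mean(axis=1))))


def compute_jitter(
    seq: PeriodSequence, variant: str = "local"
) -> float | MissingValue:
    """Jitter of a cycle sequence.

    ``local``: mean |P_i - P_{i-1}| / mean(P) * 100.
    ``absolute``: mean |P_i - P_{i-1}| (seconds).
    ``rap``: mean |P_i - 3-point moving mean| / mean(P) * 100.
    ``ppq5``: 5-point analogue of rap.
    ``ddp``: mean |(P_{i+1}-P_i) - (P_i-P_{i-1})| / mean(P) * 100.
    """
    if variant not in _JITTER_MIN_CYCLES:
        raise ValueError(f"unknown jitter variant {variant!r}")
    if seq.unvoiced:
        return MissingValue("unvoiced")
    if seq.n < _JITTER_MIN_CYCLES[variant]:
        return MissingValue(f"too_few_cycles:{seq.n}")
    p = seq.periods
    mean_p = seq.mean_period
    if variant == "absolute":
        return _mean_abs_diff(p)
    if variant == "local":
        return _mean_abs_diff(p) / mean_p * 100.0
    if variant == "rap":
        return _perturbation_quotient(p, 3) / mean_p * 100.0
    if variant == "ppq5":
        return _perturbation_quotient(p, 5) / mean_p * 100.0
    # ddp: mean absolute second difference
    return float(np.mean(np.abs(np.diff(p, n=2)))) / mean_p * 100.0


def compute_shimmer(
    seq: PeriodSequence, variant: str = "local"
) -> float | MissingValue:
    """Shimmer of a cycle sequence.

    ``local``: mean |A_i - A_{i-1}| / mean(A) * 100.
    ``local_db``: mean |20 log10(A_i / A_{i-1})| (dB).
    ``apq3/5/11``: mean |A_i - k-point moving mean| / mean(A) * 100.
    ``dda``: mean |(A_{i+1}-A_i) - (A_i-A_{i-1})| / mean(A) * 100.
    """
    if variant not in _SHIMMER_MIN_CYCLES:
        raise ValueError(f"unknown shimmer variant {variant!r}")
    if seq.unvoiced:
        return MissingValue("unvoiced")
    if seq.n < _SHIMMER_MIN_CYCLES[variant]:
        return MissingValue(f"too_few_cycles:{seq.n}")
    a = seq.amplitudes
    mean_a = seq.mean_amplitude
    if mean_a == 0:
        return MissingValue("zero_amplitude")
    if variant == "local":
        return _mean_abs_diff(a) / mean_a * 100.0
    if variant == "local_db":
        if np.any(a == 0):
            return MissingValue("zero_amplitude")
        return float(np.mean(np.abs(20.0 * np.diff(np.log10(a)))))
    if variant == "dda":
        return float(np.mean(np.abs(np.diff(a, n=2)))) / mean_a * 100.0
    k = {"apq3": 3, "apq5": 5, "apq11": 11}[variant]
    return _perturbation_quotient(a, k) / mean_a * 100.0
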