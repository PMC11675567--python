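"""Missing-value marker used by feature computations.

Operations that cannot produce a value (too few cycles, unvoiced input,
zero amplitudes, ...) return a :class:`MissingValue` carrying a machine
readable reason code instead of raising, so that a partially analysable
recording still yields a feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MissingValue", "is_missing", "as_float"]


@dataclass(frozen=True)
class MissingValue:
    """Sentinel for a feature that could not be computed."""

    reason: str

    def __float__(self) -> float:
        return float("nan")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MissingValue({self.reason!r})"


def is_missing(value: object) -> bool:
    """True if *value* is a :class:`MissingValue`."""
    return isinstance(value, MissingValue)


def as_float(value: float | MissingValue) -> float:
    """Coerce a feature value to float, mapping missing to NaN."""
    return float(value)
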