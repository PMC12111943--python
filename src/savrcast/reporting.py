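"""Centralized report rounding.

All user-facing rounding happens here: whole persons for populations and
surgery counts, 2 decimals for rates and prevalences (percent), 1
decimal for demographic indices and per-year surgery increments.
Computation elsewhere always carries full precision.
"""

from __future__ import annotations


def persons(x: float) -> int:
    """Population or surgery count, nearest whole person."""
    return round(x)


def rate(x: float) -> float:
    """Growth rate, percent/year, 2 decimals."""
    return round(x, 2)


def index_value(x: float) -> float:
    """Aging/longevity index, 1 decimal."""
    return round(x, 1)


def prevalence(x: float) -> float:
    """Decade prevalence, percent, 2 decimals."""
    return round(x, 2)


def per_year(x: float) -> float:
    """Per-year surgery increment, 1 decimal."""
    return round(x, 1)
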