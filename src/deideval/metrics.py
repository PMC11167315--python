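"""Precision, recall and F-beta from TP/FP/FN counts.

All metrics return ``None`` — deliberately neither 0 nor 1 — when their
denominator is zero: a system that emits nothing has no meaningful
precision, and imputing a number would hide that. Undefined values are
skipped (and counted) by the macro average.

Micro averages are obtained for free by summing :class:`CountTriple`
objects before computing metrics; :func:`macro_average` provides the
unweighted mean over per-group values. The two generally differ and both
are exposed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotations import CountTriple
from .errors import UsageError

__all__ = ["precision", "recall", "f_beta", "macro_average", "MacroResult"]

MetricValue = Optional[float]  # None encodes "undefined"


def precision(c: CountTriple) -> MetricValue:
    """tp / (tp + fp); None when the system emitted nothing."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def recall(c: CountTriple) -> MetricValue:
    """tp / (tp + fn); None when the reference is empty. Also called sensitivity."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def f_beta(c: CountTriple, beta: float = 1.0) -> MetricValue:
    """(1 + beta^2) P R / (beta^2 P + R).

    beta > 1 weights recall above precision (F2 is the conventional choice
    when a missed PII span is costlier than an over-redaction). Undefined
    when either constituent is undefined or both are zero.
    """
    if beta <= 0:
        raise UsageError(f"beta must be positive, got {beta}")
    p, r = precision(c), recall(c)
    if p is None or r is None:
        return None
    denom = beta * beta * p + r
    if denom == 0.0:
        return None
    return (1.0 + beta * beta) * p * r / denom


@dataclass(frozen=True)
class MacroResult:
    """Unweighted mean over defined inputs, with the undefined count kept visible."""

    value: MetricValue
    n_skipped: int


def macro_average(values: Iterable[MetricValue]) -> MacroResult:
    """Mean of the defined values; undefined inputs are skipped and counted."""
    defined = []
    skipped = 0
    for v in values:
        if v is None:
            skipped += 1
        else:
            defined.append(v)
    if not defined:
        return MacroResult(None, skipped)
    return MacroResult(sum(defined) / len(defined), skipped)
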