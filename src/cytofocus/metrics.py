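"""Binary-classification metrics and repeat-measurement statistics.

The evaluation paths of the toolkit (focus-point validity, per-cell
sharpness classification, repeat-scan reproducibility) all reduce to a
2x2 contingency table against a manual reference, or to a coefficient of
variation over repeated scores.  This module owns those computations so
every report uses identical definitions.

Percentages are kept at full precision internally; rounding to one
decimal place happens only at presentation (``format_metrics``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "ContingencyTable",
    "classification_metrics",
    "coefficient_of_variation",
    "format_metrics",
    "metrics_report_json",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows are the algorithm's call, columns the manual reference.

    ``tp`` counts algorithm-positive/reference-positive, ``fn``
    algorithm-negative/reference-positive, ``fp``
    algorithm-positive/reference-negative, ``tn`` both negative.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _ratio_pct(num: int, den: int) -> float | None:
    """num/den as a percentage; None (undefined) when the denominator is 0."""
    if den == 0:
        return None
    return 100.0 * num / den


def classification_metrics(table: ContingencyTable) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV of a 2x2 table, in %.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.

    Returns
    -------
    dict with keys ``sensitivity``, ``specificity``, ``accuracy``, ``ppv``,
    ``npv``; values are percentages at full float precision.
    """
    t = table
    return {
        "sensitivity": _ratio_pct(t.tp, t.tp + t.fn),
        "specificity": _ratio_pct(t.tn, t.tn + t.fp),
        "accuracy": _ratio_pct(t.tp + t.tn, t.total),
        "ppv": _ratio_pct(t.tp, t.tp + t.fp),
        "npv": _ratio_pct(t.tn, t.tn + t.fn),
    }


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation of repeated scores, in percent.

    CV = sample standard deviation (n-1 denominator) / mean * 100.  Requires
    at least two values and a nonzero mean.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = sum(vals) / len(vals)
    if mean == 0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return math.sqrt(var) / mean * 100.0


def format_metrics(metrics: dict[str, float | None], ndigits: int = 1) -> dict[str, str]:
    """Render a metrics dict for presentation (one decimal place by default)."""
    out: dict[str, str] = {}
    for k, v in metrics.items():
        out[k] = "undefined" if v is None else f"{v:.{ndigits}f}%"
    return out


def metrics_report_json(table: ContingencyTable, indent: int = 2) -> str:
    """JSON report bundling the raw counts with their derived metrics."""
    payload = {
        "counts": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
        "total": table.total,
        "metrics_pct": classification_metrics(table),
        "metrics_display": format_metrics(classification_metrics(table)),
    }
    return json.dumps(payload, indent=indent)
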