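"""Validation metrics over CP / FP / FN / CN confusion counts.

With ``total = CP + FP + FN + CN``:

* accuracy      = (CP + CN) / total x 100
* error %       = (FP + FN) / total x 100
* sensitivity   = CP / (CP + FN) x 100
* specificity   = CN / (CN + FP) x 100
* precision     = CP / (CP + FP) x 100
* % correct pos = CP / total x 100

Specificity follows the standard definition CN / (CN + FP): it reproduces
the published field-study values in both wrong-location policies, whereas
the alternative reading CN / (FN + CP) does not match them in either.
Precision and % correct positive carry no printed formula in the source
tables; the definitions above are the field-standard interpretation.
Values are kept at full precision; rounding (half-up, one decimal) happens
only at presentation.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .matcher import ConfusionCounts

METRIC_NAMES = ("accuracy", "error_pct", "sensitivity", "specificity", "precision", "pct_correct_positive")


@dataclass(frozen=True)
class MetricSet:
    """Six validation percentages; a metric with a zero denominator is
    undefined and reported as None, never as 0."""

    accuracy: float | None
    error_pct: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    pct_correct_positive: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Half-up presentation rounding, as in the published tables."""
        q = Decimal(10) ** -ndigits
        return {
            k: (float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP)) if v is not None else None)
            for k, v in self.as_dict().items()
        }


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    total = c.total
    if total <= 0:
        raise ValueError("confusion counts are empty (total = 0)")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den * 100.0

    return MetricSet(
        accuracy=ratio(c.CP + c.CN, total),
        error_pct=ratio(c.FP + c.FN, total),
        sensitivity=ratio(c.CP, c.CP + c.FN),
        specificity=ratio(c.CN, c.CN + c.FP),
        precision=ratio(c.CP, c.CP + c.FP),
        pct_correct_positive=ratio(c.CP, total),
    )


def metrics_report(counts: dict[str, ConfusionCounts] | list[tuple[str, ConfusionCounts]]) -> pd.DataFrame:
    """One row per named count set (e.g. per reference mode and policy),
    input order preserved; raw counts and the six metrics side by side."""
    items = counts.items() if isinstance(counts, dict) else counts
    rows = []
    for name, c in items:
        row = {"name": name, **c.as_dict(), **compute_metrics(c).as_dict()}
        rows.append(row)
    if not rows:
        raise ValueError("metrics_report needs at least one ConfusionCounts")
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for m in METRIC_NAMES:
        out[m] = out[m].map(lambda v: None if pd.isna(v) else float(
            Decimal(repr(v)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)))
    out.to_csv(path, index=False)
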