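"""Segmentation evaluation: confusion counts and the TP/TN/ACC metrics.

The vessel-segmentation literature reports three percentages per image:
the TP rate (sensitivity, 100*tp/(tp+fn)), the TN rate (specificity,
100*tn/(tn+fp)) and accuracy (100*(tp+tn)/total). Counting may optionally
be restricted to a field-of-view (FOV) mask; by default every pixel is
evaluated, and reports state which convention was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .core import require_binary_mask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    """TP rate, TN rate and accuracy, as percentages in [0, 100].

    A rate whose denominator is zero (no positive, or no negative, truth
    pixels) is reported as ``None`` — absent, not 0.
    """

    tp_rate: Optional[float]
    tn_rate: Optional[float]
    accuracy: float


def confusion_counts(pred, truth, fov=None) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted mask against ground truth.

    Counts are taken over the pixels where ``fov`` is true, or over every
    pixel when no FOV mask is given. All masks must share one shape.
    """
    p = require_binary_mask(pred, "pred")
    t = require_binary_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if fov is not None:
        f = require_binary_mask(fov, "fov")
        if f.shape != p.shape:
            raise ValueError(f"shape mismatch: fov {f.shape} vs pred {p.shape}")
        p, t = p[f], t[f]
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy (percent) from counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    return Metrics(
        tp_rate=100.0 * c.tp / pos if pos else None,
        tn_rate=100.0 * c.tn / neg if neg else None,
        accuracy=100.0 * (c.tp + c.tn) / c.total,
    )


def metrics_table(rows: Iterable[Tuple[str, ConfusionCounts]]) -> pd.DataFrame:
    """Per-image metrics plus an aggregate row over pooled counts.

    Each input row is ``(image_id, counts)``; the output frame has columns
    image_id, tp, fp, tn, fn, tp_rate, tn_rate, accuracy, with a final
    ``"aggregate"`` row computed from the summed counts.
    """
    records = []
    pooled: Optional[ConfusionCounts] = None
    for image_id, c in rows:
        m = metrics(c)
        records.append(
            {
                "image_id": image_id,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "tp_rate": m.tp_rate,
                "tn_rate": m.tn_rate,
                "accuracy": m.accuracy,
            }
        )
        pooled = c if pooled is None else pooled + c
    if pooled is None:
        raise ValueError("metrics_table needs at least one row")
    if len(records) > 1:
        m = metrics(pooled)
        records.append(
            {
                "image_id": "aggregate",
                "tp": pooled.tp,
                "fp": pooled.fp,
                "tn": pooled.tn,
                "fn": pooled.fn,
                "tp_rate": m.tp_rate,
                "tn_rate": m.tn_rate,
                "accuracy": m.accuracy,
            }
        )
    return pd.DataFrame.from_records(records)


def summary(df: pd.DataFrame, fov_used: bool = False) -> str:
    """Human-readable summary of a metrics table."""
    lines = [f"evaluated {len(df)} row(s); FOV mask: {'yes' if fov_used else 'no'}"]
    for _, row in df.iterrows():
        tp_rate = "n/a" if pd.isna(row.tp_rate) else f"{row.tp_rate:6.2f}"
        tn_rate = "n/a" if pd.isna(row.tn_rate) else f"{row.tn_rate:6.2f}"
        lines.append(
            f"  {row.image_id}: TP {tp_rate}  TN {tn_rate}  ACC {row.accuracy:6.2f}"
        )
    return "\n".join(lines)
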