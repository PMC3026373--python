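"""Agreement metrics between automatic and manual lesion masks.

Per-pixel confusion counts (TP/TN/FP/FN) feed three metrics:

    border error = 100 · Area(auto ⊕ manual) / Area(manual)
                 = 100 · (FP + FN) / (TP + FN)      [percent, unbounded above]
    precision    = TP / (TP + FP)
    recall       = TP / (TP + FN)

where ⊕ is pixel-wise exclusive-or and Area() counts positive pixels.
Batch evaluation emits one row per image plus an unweighted mean row,
the layout used for per-image benchmark tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import BinaryMask

__all__ = [
    "EvaluationRecord",
    "confusion_counts",
    "border_error",
    "precision_recall",
    "evaluate_pair",
    "batch_evaluate",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationRecord:
    """One benchmark-table row: counts plus the three metrics.

    Undefined metrics (zero denominators) are carried as NaN, never
    clamped to 0 or 1.
    """

    image_id: str
    tp: int
    tn: int
    fp: int
    fn: int
    border_error: float  # percent
    precision: float  # fraction in [0, 1], NaN if undefined
    recall: float  # fraction in [0, 1], NaN if undefined


def confusion_counts(
    auto: BinaryMask, manual: BinaryMask
) -> tuple[int, int, int, int]:
    """Per-pixel (tp, tn, fp, fn) counts; the four sum to H·W."""
    if auto.shape != manual.shape:
        raise ValueError(f"shape mismatch: {auto.shape} vs {manual.shape}")
    a, m = auto.values, manual.values
    tp = int(np.sum(a & m))
    fp = int(np.sum(a & ~m))
    fn = int(np.sum(~a & m))
    tn = a.size - tp - fp - fn
    return tp, tn, fp, fn


def border_error(auto: BinaryMask, manual: BinaryMask) -> float:
    """100 · Area(auto XOR manual) / Area(manual), in percent."""
    if auto.shape != manual.shape:
        raise ValueError(f"shape mismatch: {auto.shape} vs {manual.shape}")
    area_manual = manual.positive_count
    if area_manual == 0:
        raise ValueError("border error undefined: manual mask is empty")
    xor = int(np.sum(auto.values ^ manual.values))
    return 100.0 * xor / area_manual


def precision_recall(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    """(precision, recall) from (tp, tn, fp, fn); NaN marks undefined."""
    tp, _tn, fp, fn = counts
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    return precision, recall


def evaluate_pair(image_id: str, auto: BinaryMask, manual: BinaryMask) -> EvaluationRecord:
    tp, tn, fp, fn = confusion_counts(auto, manual)
    err = 100.0 * (fp + fn) / (tp + fn) if tp + fn > 0 else math.nan
    precision, recall = precision_recall((tp, tn, fp, fn))
    return EvaluationRecord(
        image_id=image_id, tp=tp, tn=tn, fp=fp, fn=fn,
        border_error=err, precision=precision, recall=recall,
    )


def batch_evaluate(
    pairs: Iterable[tuple[str, BinaryMask, BinaryMask]]
) -> pd.DataFrame:
    """Evaluate (image_id, auto, manual) pairs into a table with a mean row.

    The aggregate row (image_id ``"mean"``) holds the unweighted
    per-image mean of each metric; undefined (NaN) metrics are excluded
    from their column's mean and their count is logged.
    """
    records = [evaluate_pair(i, a, m) for i, a, m in pairs]
    if not records:
        raise ValueError("batch_evaluate needs at least one pair")
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "border_error_pct": [r.border_error for r in records],
            "precision": [r.precision for r in records],
            "recall": [r.recall for r in records],
        }
    )
    for col in ("border_error_pct", "precision", "recall"):
        n_missing = int(df[col].isna().sum())
        if n_missing:
            logger.warning("%d image(s) with undefined %s excluded from mean", n_missing, col)
    mean_row = pd.DataFrame(
        {
            "image_id": ["mean"],
            "border_error_pct": [df["border_error_pct"].mean()],
            "precision": [df["precision"].mean()],
            "recall": [df["recall"].mean()],
        }
    )
    return pd.concat([df, mean_row], ignore_index=True)


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write the benchmark table as CSV (border error and P/R at 2 decimals)."""
    out = table.copy()
    out["border_error_pct"] = out["border_error_pct"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}"
    )
    for col in ("precision", "recall"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out.to_csv(Path(path), index=False)
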