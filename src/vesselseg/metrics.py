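"""Confusion-count accounting and Dice / precision / recall evaluation.

For binary masks (1 = vessel/lesion, 0 = background) the three scores are

    Dice      = 2·TP / (FP + 2·TP + FN)
    precision = TP / (FP + TP)
    recall    = TP / (FN + TP)

Edge cases are explicit: when both masks are empty Dice is defined as 1.0
(perfect agreement on emptiness, with a warning); an undefined precision or
recall (zero denominator) is returned as NaN, never silently as 0.  Scores
are aggregated per image then averaged (mean ± SD across images), matching
the usual mean ± SD presentation of segmentation studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise tallies of a binary prediction against a binary reference."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricValues:
    dice: float
    precision: float
    recall: float


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    uniq = np.unique(arr)
    if not np.isin(uniq, [0, 1]).all():
        raise MetricsError(f"{name} must be binary (0/1), found values {uniq[:8]}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between a predicted and a reference binary mask."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise MetricsError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice_coefficient(counts: ConfusionCounts) -> float:
    """Dice = 2·TP / (FP + 2·TP + FN); both-empty masks score 1.0."""
    denom = counts.fp + 2 * counts.tp + counts.fn
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * counts.tp / denom


def precision_score(counts: ConfusionCounts) -> float:
    """precision = TP / (FP + TP); NaN when no positive prediction exists."""
    denom = counts.fp + counts.tp
    if denom == 0:
        warnings.warn("no positive predictions: precision undefined (NaN)", stacklevel=2)
        return float("nan")
    return counts.tp / denom


def recall_score(counts: ConfusionCounts) -> float:
    """recall = TP / (FN + TP); NaN when the reference has no foreground."""
    denom = counts.fn + counts.tp
    if denom == 0:
        warnings.warn("reference has no foreground: recall undefined (NaN)", stacklevel=2)
        return float("nan")
    return counts.tp / denom


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricValues:
    """All three scores for one predicted/reference mask pair."""
    c = confusion_counts(pred, truth)
    return MetricValues(
        dice=dice_coefficient(c), precision=precision_score(c), recall=recall_score(c)
    )


def benchmark_report(
    algorithms: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> pd.DataFrame:
    """Per-algorithm mean ± SD of Dice/precision/recall over a dataset.

    ``algorithms`` maps a display name to a segmenter ``image -> binary mask``.
    Per-image failures are recorded (row of NaNs) rather than aborting the run.
    Returns the summary table; optionally writes the CSV summary and a JSON
    twin carrying the per-image values.
    """
    if not algorithms:
        raise MetricsError("at least one algorithm required")
    if len(images) == 0 or len(images) != len(truths):
        raise MetricsError("need equal, non-zero numbers of images and truth masks")

    rows = []
    per_image: dict[str, list[dict]] = {}
    for name, segment in algorithms.items():
        records = []
        for i, (img, truth) in enumerate(zip(images, truths)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = evaluate_masks(segment(img), truth)
                records.append({"image": i, "dice": m.dice, "precision": m.precision, "recall": m.recall})
            except Exception as exc:  # noqa: BLE001 - per-image failures are data, not fatal
                records.append(
                    {"image": i, "dice": np.nan, "precision": np.nan, "recall": np.nan, "error": str(exc)}
                )
        per_image[name] = records
        df = pd.DataFrame(records)
        row = {"algorithm": name, "n_images": len(images)}
        for metric in ("dice", "precision", "recall"):
            row[f"{metric}_mean"] = float(np.nanmean(df[metric]))
            row[f"{metric}_sd"] = float(np.nanstd(df[metric], ddof=0))
        rows.append(row)

    table = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.round(6).to_csv(out_csv, index=False, lineterminator="\n")
    if out_json is not None:
        Path(out_json).parent.mkdir(parents=True, exist_ok=True)
        Path(out_json).write_text(json.dumps(per_image, indent=2, default=float) + "\n")
    return table
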