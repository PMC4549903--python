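"""Key-position-only classification and the four evaluation metrics.

Prediction uses only the selected key positions: the score of a sequence is
the learned linear score with every non-key weight removed,
s = sum_{p in keys} w[p] * x[p] + b, thresholded at 0 by default.

Metrics follow the standard confusion-matrix definitions, reported on the
x100 scale with one decimal (an MCC of 0.666 prints as 66.6).  Confusion
counts may be fractional: per-fold means of the 9-1 protocol are legal
inputs because every metric is invariant to rescaling all four counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diad_profile import DiadPartition, diad_codes, sequences_to_codes
from .key_positions import KeyPositionSet
from .oligo_io import OligoRecord
from .position_weights import PositionWeightVector

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "score_sequence",
    "classify",
    "confusion",
    "metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion tally; fractional values allowed (per-fold means)."""

    TP: float
    FP: float
    TN: float
    FN: float

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    """Acc/Sen/PPV/MCC on the x100 one-decimal reporting scale.

    ``raw`` holds the unrounded fractions (MCC in [-1, 1]); an undefined
    metric (zero denominator) is NaN in both forms, never an exception.
    """

    acc: float
    sen: float
    ppv: float
    mcc: float
    raw: tuple[float, float, float, float] = (math.nan,) * 4

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sen": self.sen, "ppv": self.ppv, "mcc": self.mcc}


def score_sequence(
    record: OligoRecord,
    weights: PositionWeightVector,
    keys: KeyPositionSet,
    partition: DiadPartition,
) -> float:
    """Linear score restricted to key positions (plus the intercept)."""
    d = len(weights.weights)
    if len(record.sequence) - 1 != d:
        raise ValueError(
            f"record length {len(record.sequence)} inconsistent with "
            f"{d} weight positions"
        )
    if keys.positions and keys.positions[-1] > d:
        raise ValueError(f"key position {keys.positions[-1]} exceeds {d}")
    table = partition.class_table()
    x = table[diad_codes(sequences_to_codes([record.sequence]))[0]].astype(float)
    idx = np.asarray(keys.positions, dtype=int) - 1
    return float(weights.weights[idx] @ x[idx] + weights.bias)


def classify(score: float, threshold: float = 0.0) -> int:
    """+1 iff score strictly exceeds the threshold, else -1."""
    if not math.isfinite(score):
        raise ValueError("non-finite score")
    return 1 if score > threshold else -1


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Tally a 2x2 confusion matrix from +1/-1 predictions and labels."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionCounts(
        TP=float(np.sum((pred == 1) & (lab == 1))),
        FP=float(np.sum((pred == 1) & (lab == -1))),
        TN=float(np.sum((pred == -1) & (lab == -1))),
        FN=float(np.sum((pred == -1) & (lab == 1))),
    )


def metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, positive predictive value and Matthews
    correlation from a confusion tally.

    Acc = (TP+TN)/total;  Sen = TP/(TP+FN);  PPV = TP/(TP+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)).
    Reported x100, one decimal; a zero denominator yields NaN for that
    metric only.
    """
    if c.total <= 0:
        raise ValueError("empty confusion matrix")

    def safe_div(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    acc = safe_div(c.TP + c.TN, c.total)
    sen = safe_div(c.TP, c.TP + c.FN)
    ppv = safe_div(c.TP, c.TP + c.FP)
    mcc_den = math.sqrt(
        (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    )
    mcc = safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den)
    raw = (acc, sen, ppv, mcc)
    rounded = tuple(
        round(100 * v, 1) if math.isfinite(v) else math.nan for v in raw
    )
    return MetricReport(*rounded, raw=raw)


def metrics_table(
    reports: dict[str, MetricReport], key_sets: dict[str, KeyPositionSet] | None = None
) -> pd.DataFrame:
    """Run-summary rows (partition, key positions, Acc, Sen, PPV, MCC)."""
    rows = []
    for name, rep in reports.items():
        keys = ""
        if key_sets and name in key_sets:
            keys = ",".join(map(str, key_sets[name].positions))
        rows.append({"partition": name, "key_positions": keys, **rep.as_dict()})
    return pd.DataFrame(rows)
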