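"""Scoring: candidate labeling against ground truth and confusion metrics.

Detections are matched to annotations channel-by-channel with a time
tolerance, one-to-one and nearest-first — each annotation can validate at
most one candidate.  Classifier output is then summarized as

    AC = (TN + TP) / (TN + FN + TP + FP) * 100
    SE = TP / (FN + TP) * 100
    SP = TN / (TN + FP) * 100

with zero-denominator cases reported as NaN.  Repeated runs pool by
summing confusion matrices first and applying the formulas to the pooled
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .synth import AnnotationSet


@dataclass(frozen=True)
class Metrics:
    """Confusion matrix counts plus accuracy / sensitivity / specificity."""

    TN: int
    FP: int
    FN: int
    TP: int

    def __post_init__(self):
        if min(self.TN, self.FP, self.FN, self.TP) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    @property
    def AC(self) -> float:
        return self._pct(self.TN + self.TP, self.TN + self.FN + self.TP + self.FP)

    @property
    def SE(self) -> float:
        return self._pct(self.TP, self.FN + self.TP)

    @property
    def SP(self) -> float:
        return self._pct(self.TN, self.TN + self.FP)

    def as_dict(self) -> dict:
        return {"TN": self.TN, "FP": self.FP, "FN": self.FN, "TP": self.TP,
                "AC": self.AC, "SE": self.SE, "SP": self.SP}

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.TN + other.TN, self.FP + other.FP,
                       self.FN + other.FN, self.TP + other.TP)


def label_candidates(candidates, annotations: AnnotationSet,
                     tolerance_ms: float = 60.0) -> np.ndarray:
    """Binary truth labels for candidates: 1 iff an annotation on the same
    channel lies within the tolerance of the candidate apex, matched
    one-to-one nearest-first."""
    labels = np.zeros(len(candidates), dtype=int)
    by_channel: dict[str, list[int]] = {}
    for j, c in enumerate(candidates):
        by_channel.setdefault(c.av_channel, []).append(j)

    for channel, cand_idx in by_channel.items():
        if channel is None:
            continue
        ann = annotations.for_channel(channel)
        if ann.size == 0:
            continue
        pairs = []
        for j in cand_idx:
            c = candidates[j]
            tol = tolerance_ms * c.fs / 1000.0
            dt = np.abs(ann - c.apex_index)
            for a in np.flatnonzero(dt <= tol):
                pairs.append((float(dt[a]), int(a), j))
        pairs.sort()
        used_ann: set[int] = set()
        used_cand: set[int] = set()
        for _, a, j in pairs:
            if a in used_ann or j in used_cand:
                continue
            used_ann.add(a)
            used_cand.add(j)
            labels[j] = 1
    return labels


def compute_metrics(labels: np.ndarray, predictions: np.ndarray) -> Metrics:
    """Confusion counts of binary predictions against binary truth."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ConfigError(
            f"labels and predictions differ in shape: "
            f"{labels.shape} vs {predictions.shape}"
        )
    return Metrics(
        TN=int(((labels == 0) & (predictions == 0)).sum()),
        FP=int(((labels == 0) & (predictions == 1)).sum()),
        FN=int(((labels == 1) & (predictions == 0)).sum()),
        TP=int(((labels == 1) & (predictions == 1)).sum()),
    )


def aggregate_runs(runs: list[Metrics]) -> tuple[Metrics, pd.DataFrame]:
    """Pool runs by summing confusion matrices; also return the per-run table
    (with a mean/sd summary available via DataFrame.describe)."""
    if not runs:
        raise ConfigError("need at least one run to aggregate")
    pooled = runs[0]
    for m in runs[1:]:
        pooled = pooled + m
    table = pd.DataFrame([m.as_dict() for m in runs])
    return pooled, table
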