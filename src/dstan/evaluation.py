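"""Splitting, confusion counts, metrics and the ablation harness.

The positive class is MCI (label 1).  Accuracy, sensitivity and
specificity are reported as percentages; a zero denominator yields NaN
with a warning rather than a silent 0.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .model import DstanModel, ModelConfig
from .training import TrainConfig, train
from .types import (ConfusionCounts, LabeledDataset, MetricReport,
                    NormalizedAdjacency)

logger = logging.getLogger(__name__)

__all__ = ["split_dataset", "confusion", "metrics", "evaluate_model",
           "run_ablation"]


def split_dataset(data: LabeledDataset, ratio: float, seed: int,
                  stratified: bool = True
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Random train/test split with train fraction ``ratio``.

    Stratified by default: the test set takes ``ceil((1-ratio) * n_c)``
    subjects from each class c, so both classes are represented even in
    small cohorts.  Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    y = data.labels
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    if stratified:
        for c in (0, 1):
            members = np.flatnonzero(y == c)
            if members.size == 0:
                raise ValueError(f"class {c} has no subjects")
            n_test = int(np.ceil((1.0 - ratio) * members.size))
            test_idx.extend(rng.permutation(members)[:n_test].tolist())
    else:
        n_test = int(np.ceil((1.0 - ratio) * len(data)))
        test_idx = rng.permutation(len(data))[:n_test].tolist()
    test_set = set(test_idx)
    train_idx = [i for i in range(len(data)) if i not in test_set]
    return data.subset(train_idx), data.subset(sorted(test_set))


def confusion(scores: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Tabulate argmax predictions against labels (ties -> class 0)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must align")
    pred = (scores[:, 1] > scores[:, 0]).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN",
                       name)
        return float("nan")
    return 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity (TP rate on MCI) and specificity (TN rate
    on controls), in percent."""
    if c.total == 0:
        raise ValueError("no subjects evaluated")
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"))


def evaluate_model(model: DstanModel, data: LabeledDataset,
                   S: NormalizedAdjacency) -> tuple[MetricReport,
                                                    ConfusionCounts]:
    scores, _ = model.forward(data.as_array(), S)
    counts = confusion(scores.data, data.labels)
    return metrics(counts), counts


def run_ablation(train_set: LabeledDataset, test_set: LabeledDataset,
                 S: NormalizedAdjacency, mcfg: ModelConfig,
                 tcfg: TrainConfig) -> pd.DataFrame:
    """Train the full model and the attention-free variant from one
    call and report both test-set metric rows.

    The No-Att arm fixes the attention map at the constant 1 vector and
    drops the attention term from the objective; everything else is
    shared.
    """
    rows = []
    for name, use_att in (("No-Att", False), ("DSTAN", True)):
        cfg = dataclasses.replace(mcfg, use_attention=use_att)
        model, _ = train(train_set, S, cfg, tcfg)
        report, counts = evaluate_model(model, test_set, S)
        rows.append({"method": name, "accuracy": report.accuracy,
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity,
                     "tp": counts.tp, "fp": counts.fp,
                     "tn": counts.tn, "fn": counts.fn})
    return pd.DataFrame(rows)
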