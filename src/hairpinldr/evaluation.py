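"""Imbalance-aware evaluation: confusion counts, SE/SP/Gm, stratified CV.

With roughly 1 positive per 13 negatives, raw accuracy is misleading — a
classifier that always predicts "negative" is ~93% accurate and useless.
The geometric mean Gm = sqrt(SE * SP) of sensitivity SE = TP/(TP+FN) and
specificity SP = TN/(TN+FP) is the headline score instead: it collapses
to 0 as soon as either class is ignored.

Cross-validation is stratified k-fold: every fold preserves the overall
class ratio (per-class counts differ from perfect proportionality by at
most one).  All fitting — standardization, mapping bookkeeping,
projection, classifier — happens on the training folds only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable
from .pipeline import PipelineConfig, apply_pipeline, fit_pipeline

__all__ = [
    "ConfusionCounts",
    "CVSummary",
    "confusion",
    "sensitivity",
    "specificity",
    "geometric_mean",
    "stratified_folds",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the positive class = pre-microRNA (label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError(
            f"label vectors differ in length: {y.shape} vs {p.shape}"
        )
    for arr, name in ((y, "true"), (p, "predicted")):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """SE = TP / (TP + FN); 0 with a warning if there are no positives."""
    denom = c.tp + c.fn
    if denom == 0:
        warnings.warn("no positive samples: sensitivity defined as 0", stacklevel=2)
        return 0.0
    return c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """SP = TN / (TN + FP); 0 with a warning if there are no negatives."""
    denom = c.tn + c.fp
    if denom == 0:
        warnings.warn("no negative samples: specificity defined as 0", stacklevel=2)
        return 0.0
    return c.tn / denom


def geometric_mean(se: float, sp: float) -> float:
    """Gm = sqrt(SE * SP)."""
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("SE and SP must be fractions in [0, 1]")
    return math.sqrt(se * sp)


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Fold id (0..k-1) per sample; stratified, shuffled, seed-reproducible.

    Each class must have at least k members.  k = 1 returns a single fold
    containing every sample.
    """
    y = np.asarray(labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.zeros(y.size, dtype=int)
    for lab in (0, 1):
        n_c = int(np.sum(y == lab))
        if n_c < k:
            raise ValueError(
                f"class {lab} has {n_c} samples, fewer than k={k} folds"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[test_idx] = fold_id
    return assignment


@dataclass
class CVSummary:
    """Per-fold and aggregate metrics of one cross-validated pipeline."""

    fold_se: list[float]
    fold_sp: list[float]
    fold_gm: list[float]
    fold_confusions: list[ConfusionCounts]
    fold_model_hashes: list[str]
    seed: int
    config_hash: str

    @property
    def k(self) -> int:
        return len(self.fold_gm)

    # per-fold mean +- std is the headline aggregate
    @property
    def mean_se(self) -> float:
        return float(np.mean(self.fold_se))

    @property
    def mean_sp(self) -> float:
        return float(np.mean(self.fold_sp))

    @property
    def mean_gm(self) -> float:
        return float(np.mean(self.fold_gm))

    @property
    def std_gm(self) -> float:
        return float(np.std(self.fold_gm))

    @property
    def pooled_confusion(self) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0, 0)
        for c in self.fold_confusions:
            total = total + c
        return total

    @property
    def pooled_gm(self) -> float:
        c = self.pooled_confusion
        return geometric_mean(sensitivity(c), specificity(c))

    def to_frame(self) -> pd.DataFrame:
        """One row per fold plus mean/std summary rows."""
        rows = [
            {
                "fold": i,
                "SE": self.fold_se[i],
                "SP": self.fold_sp[i],
                "Gm": self.fold_gm[i],
                "TP": c.tp,
                "TN": c.tn,
                "FP": c.fp,
                "FN": c.fn,
            }
            for i, c in enumerate(self.fold_confusions)
        ]
        frame = pd.DataFrame(rows)
        summary = pd.DataFrame(
            [
                {"fold": "mean", "SE": self.mean_se, "SP": self.mean_sp,
                 "Gm": self.mean_gm},
                {"fold": "std", "SE": float(np.std(self.fold_se)),
                 "SP": float(np.std(self.fold_sp)), "Gm": self.std_gm},
            ]
        )
        return pd.concat([frame, summary], ignore_index=True)

    def write_report(self, path, sep: str = "\t") -> None:
        frame = self.to_frame()
        frame.insert(0, "config_hash", self.config_hash)
        frame.insert(1, "fold_seed", self.seed)
        frame.to_csv(path, sep=sep, index=False)


def cross_validate(table: FeatureTable, config: PipelineConfig) -> CVSummary:
    """Stratified k-fold CV of one pipeline configuration.

    For every fold the pipeline (standardization, explicit map, LDR
    projection, Bayes classifier) is fitted on the k-1 training folds and
    applied to the held-out fold; no test row influences any fitted
    parameter.  Fully deterministic given the config's seeds.
    """
    names = list(config.features) if config.features else table.feature_names
    X = table.matrix(names)
    y = table.labels
    assignment = stratified_folds(y, config.folds, config.fold_seed)

    fold_se, fold_sp, fold_gm, fold_conf, fold_hashes = [], [], [], [], []
    for fold_id in range(config.folds):
        test = assignment == fold_id
        train = ~test if config.folds > 1 else test
        try:
            fit = fit_pipeline(X[train], y[train], config, feature_names=names)
            pred, _ = apply_pipeline(fit, X[test])
        except Exception as exc:
            raise type(exc)(f"fold {fold_id}: {exc}") from exc
        c = confusion(y[test], pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se, sp = sensitivity(c), specificity(c)
        fold_se.append(se)
        fold_sp.append(sp)
        fold_gm.append(geometric_mean(se, sp))
        fold_conf.append(c)
        fold_hashes.append(fit.state_hash())

    return CVSummary(
        fold_se=fold_se,
        fold_sp=fold_sp,
        fold_gm=fold_gm,
        fold_confusions=fold_conf,
        fold_model_hashes=fold_hashes,
        seed=config.fold_seed,
        config_hash=config.config_hash(),
    )
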