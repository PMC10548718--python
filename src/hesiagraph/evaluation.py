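"""Binary-classifier metrics, the cross-validation harness, and drug ranking.

Metrics reported per evaluation: accuracy, AUC-ROC (trapezoid over the exact
ROC step curve, i.e. the Mann-Whitney concordance statistic), AUC-PR (step
interpolation over all distinct score thresholds), Brier score (mean squared
difference between predicted probabilities and labels), Matthews correlation
coefficient, and F1. Hard calls use the strict rule: positive iff the
probability exceeds the threshold.

The F1 convention: standard harmonic mean ``2PR/(P+R)`` by default; a
``paper_variant`` flag computes the unnormalized ``PR/(P+R)`` for
compatibility with sources that print the formula without the factor 2.

Cross-validation follows the fixed-test-set protocol: the held-out test pairs
never move; each repeat re-partitions the remaining pairs into ``folds``
stratified subsets, each fold in turn serving as the validation monitor while
the rest (after rebalancing) trains the network, and every trained model is
scored on the same fixed test set. Repeats × folds metric reports are
aggregated as mean ± sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureBlock, PairSet, pairs_to_features, rebalance
from .embedding import EmbeddingTable, OOVError
from .hesianet import (ModelConfig, SiameseModel, TrainConfig, init_model,
                       train)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CVReport",
    "confusion",
    "metrics",
    "cross_validate",
    "rank_drugs",
]

METRIC_NAMES = ("acc", "auc_roc", "auc_pr", "brier", "mcc", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels: Sequence[int], probs: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Count the confusion cells under the strict ``prob > threshold`` call."""
    y = np.asarray(labels)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have equal length")
    calls = p > threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(calls & pos)), TN=int(np.sum(~calls & ~pos)),
        FP=int(np.sum(calls & ~pos)), FN=int(np.sum(~calls & pos)))


@dataclass(frozen=True)
class MetricReport:
    acc: float
    auc_roc: float
    auc_pr: float
    brier: float
    mcc: float
    f1: float
    n: int
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {"n": self.n}


def metrics(labels: Sequence[int], probs: Sequence[float],
            threshold: float = 0.5, paper_variant: bool = False) -> MetricReport:
    """Compute the full metric panel on one label/probability vector.

    With a single class present, the rank metrics (AUC-ROC, AUC-PR) and MCC
    are undefined: they come back as NaN and are listed in
    ``report.undefined``; the threshold metrics are still returned.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have equal length")
    if len(y) == 0:
        raise ValueError("cannot score an empty prediction set")
    cm = confusion(y, p, threshold)
    acc = (cm.TP + cm.TN) / cm.total
    brier = float(np.mean((y - p) ** 2))

    undefined: list[str] = []
    if len(np.unique(y)) < 2:
        auc_roc = auc_pr = mcc = float("nan")
        undefined += ["auc_roc", "auc_pr", "mcc"]
    else:
        auc_roc = float(roc_auc_score(y, p))
        auc_pr = float(average_precision_score(y, p))
        denom = math.sqrt(float(cm.TP + cm.FP) * (cm.TP + cm.FN)
                          * (cm.TN + cm.FP) * (cm.TN + cm.FN))
        mcc = (cm.TP * cm.TN - cm.FN * cm.FP) / denom if denom else 0.0

    precision = cm.TP / (cm.TP + cm.FP) if cm.TP + cm.FP else 0.0
    recall = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else 0.0
    if precision + recall:
        f1 = precision * recall / (precision + recall)
        if not paper_variant:
            f1 *= 2.0
    else:
        f1 = 0.0
    return MetricReport(acc=float(acc), auc_roc=auc_roc, auc_pr=auc_pr,
                        brier=brier, mcc=float(mcc), f1=float(f1),
                        n=len(y), undefined=tuple(undefined))


class CVReport:
    """Per-(repeat, fold) metric table with mean/std aggregation."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def mean(self) -> pd.Series:
        return self.frame[list(METRIC_NAMES)].mean()

    def std(self) -> pd.Series:
        return self.frame[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> str:
        mu, sd = self.mean(), self.std()
        lines = [f"{name:>8}: {mu[name]:.4f} +/- {0.0 if np.isnan(sd[name]) else sd[name]:.4f}"
                 for name in METRIC_NAMES]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def cross_validate(pairset: PairSet, table: EmbeddingTable,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   folds: int = 5, repeats: int = 4, seed: int = 0,
                   balance: str = "SORU", smote_ratio: float = 0.9,
                   k_neighbors: int = 5, threshold: float = 0.5) -> CVReport:
    """Repeated stratified CV with a fixed test set.

    ``pairset`` must already carry the test split (pairs with role ``test``);
    those pairs are scored by every fold's model while the remaining pairs
    rotate through train/validation duty. Rebalancing touches only the
    training portion. The whole procedure is deterministic in ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    test_pairs = pairset.with_role("test")
    rest = [p for p in pairset.pairs if p.role != "test"]
    if not test_pairs or not rest:
        raise ValueError("pairset must contain both test and non-test pairs")

    test_block = pairs_to_features(test_pairs, table)
    rest_block = pairs_to_features(rest, table)
    k = table.vector_size

    rows = []
    for repeat in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + repeat)
        for fold, (tr_idx, va_idx) in enumerate(
                skf.split(rest_block.X, rest_block.y)):
            fold_seed = seed + 9973 * repeat + 101 * fold
            tr = FeatureBlock(rest_block.X[tr_idx], rest_block.y[tr_idx])
            va = FeatureBlock(rest_block.X[va_idx], rest_block.y[va_idx])
            tr = rebalance(tr, balance, smote_ratio=smote_ratio,
                           k_neighbors=k_neighbors, seed=fold_seed)
            model = init_model(model_cfg, seed=fold_seed)
            model, _ = train(model, tr, va, train_cfg.replace(seed=fold_seed))
            probs, _, _ = model.forward_batch(test_block.X[:, :k],
                                              test_block.X[:, k:])
            rep = metrics(test_block.y, probs, threshold)
            rows.append({"repeat": repeat, "fold": fold, **rep.to_dict()})
    return CVReport(pd.DataFrame(rows))


def rank_drugs(model: SiameseModel, table: EmbeddingTable, disease: str,
               drugs: Sequence[str], top_n: int = 10
               ) -> list[tuple[str, float]]:
    """Rank candidate drugs for a query disease by association probability.

    Descending by probability with lexicographic drug-id tie-break; returns
    at most ``top_n`` entries.
    """
    if f"disease:{disease}" not in table:
        raise OOVError(f"disease:{disease}")
    Xp = table.lookup(f"disease:{disease}")
    Xr = table.lookup_many(f"drug:{d}" for d in drugs)
    probs, _, _ = model.forward_batch(Xr, np.tile(Xp, (len(Xr), 1)))
    ranked = sorted(zip(drugs, map(float, probs)), key=lambda t: (-t[1], t[0]))
    return ranked[:top_n]
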