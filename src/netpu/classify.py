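"""Supervised classification over the five labels and the evaluation protocols.

Three protocols mirror how a labeling of this kind is validated:

* out-of-sample multi-class classification (stratified 70/30 split or
  stratified k-fold CV) of a random forest / SVM / MLP trained on the
  feature matrix with the propagated labels as targets;
* seed masking: hide a fraction of seed genes from the whole pipeline
  (features AND labeling) in non-overlapping folds and tally which class
  each hidden seed lands in — a good pipeline rediscovers them as LP;
* ranked candidate evaluation: precision/recall/F1 of the top-k of the
  g_inf ranking against a held-out gold-positive set.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, assemble_features
from .labeling import LABELS, LabelAssignment, label_genes
from .network import Network, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport", "RediscoveryReport", "train_eval", "cross_validate",
    "pooled_mean_sd", "mask_and_rediscover", "rank_candidates", "evaluate_ranking",
]

_MODELS = {
    "rf": lambda seed: RandomForestClassifier(random_state=seed),
    "svm": lambda seed: SVC(random_state=seed),
    "mlp": lambda seed: MLPClassifier(random_state=seed, max_iter=1000),
}


@dataclass(frozen=True)
class EvalReport:
    """Per-class precision/recall/F1, 5x5 confusion counts, averages, accuracy."""

    per_class: Mapping[str, tuple[float, float, float]]
    confusion: np.ndarray  # rows: true label, cols: predicted, order LABELS
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_class": {c: list(v) for c, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "macro_avg": list(self.macro_avg),
            "weighted_avg": list(self.weighted_avg),
            "accuracy": self.accuracy,
            "labels": list(LABELS),
        }


@dataclass(frozen=True)
class RediscoveryReport:
    """Per-fold class counts of masked seeds and per-class score statistics."""

    per_fold: tuple[Mapping[str, int], ...]
    score_stats: Mapping[str, dict]  # label -> {mean, median, mode, n}
    masked: tuple[tuple[str, ...], ...]  # the fold partitions of the seed set

    def total_counts(self) -> dict[str, int]:
        out = {c: 0 for c in LABELS}
        for fold in self.per_fold:
            for c, k in fold.items():
                out[c] += k
        return out

    def percent(self, cls: str) -> float:
        tot = sum(self.total_counts().values())
        return 100.0 * self.total_counts()[cls] / tot if tot else 0.0


def _report(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    labels = list(LABELS)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    mp, mr, mf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    wp, wr, wf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return EvalReport(
        per_class={c: (float(p[i]), float(r[i]), float(f1[i])) for i, c in enumerate(labels)},
        confusion=cm,
        macro_avg=(float(mp), float(mr), float(mf1)),
        weighted_avg=(float(wp), float(wr), float(wf1)),
        accuracy=float((y_true == y_pred).mean()),
    )


def _xy(F: FeatureMatrix, labels: LabelAssignment) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([labels.label[g] for g in F.order])
    return F.X, y


def train_eval(
    F: FeatureMatrix,
    labels: LabelAssignment,
    model: str = "rf",
    test_fraction: float = 0.3,
    seed: int = 0,
) -> EvalReport:
    """Stratified train/test split (default 70/30), fit, report on the test split."""
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    X, y = _xy(F, labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"cannot stratify: class(es) {small} have fewer than 2 members")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed)
    clf = _MODELS[model](seed)
    clf.fit(X_tr, y_tr)
    return _report(y_te, clf.predict(X_te))


def cross_validate(
    F: FeatureMatrix,
    labels: LabelAssignment,
    model: str = "rf",
    k: int = 5,
    seed: int = 0,
) -> list[EvalReport]:
    """Stratified k-fold cross-validation; one report per fold."""
    if k < 2:
        raise ValueError("k must be at least 2")
    X, y = _xy(F, labels)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        # stratification impossible (e.g. leave-one-out); plain shuffled folds
        logger.warning("k=%d exceeds the smallest class (%d); using unstratified folds",
                       k, counts.min())
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for tr, te in skf.split(X, y):
        clf = _MODELS[model](seed)
        clf.fit(X[tr], y[tr])
        reports.append(_report(y[te], clf.predict(X[te])))
    return reports


def pooled_mean_sd(reports: Sequence[EvalReport]) -> dict:
    """Mean +/- sd of every metric over a list of reports (population-style ddof=1)."""
    def agg(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    out: dict = {"per_class": {}, "accuracy": agg([r.accuracy for r in reports])}
    for c in LABELS:
        out["per_class"][c] = {
            name: agg([r.per_class[c][i] for r in reports])
            for i, name in enumerate(("precision", "recall", "f1"))
        }
    for avg in ("macro_avg", "weighted_avg"):
        out[avg] = {
            name: agg([getattr(r, avg)[i] for r in reports])
            for i, name in enumerate(("precision", "recall", "f1"))
        }
    return out


def _mode_2dp(values: Sequence[float]) -> float:
    """Mode of scores rounded to 2 decimals; smallest value on ties."""
    rounded = [round(v, 2) for v in values]
    counts: dict[float, int] = {}
    for v in rounded:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return min(v for v, k in counts.items() if k == best)


def mask_and_rediscover(
    net: Network,
    seeds: SeedSet,
    mask_fraction: float = 0.2,
    n_folds: int = 5,
    *,
    seed: int = 0,
    feature_params: Mapping | None = None,
    label_params: Mapping | None = None,
) -> RediscoveryReport:
    """Hide seed genes in non-overlapping folds and see where the pipeline puts them.

    The seed set is shuffled once with ``seed`` and cut into ``n_folds``
    contiguous blocks of ``mask_fraction * |seeds|`` genes.  For each fold
    the masked genes are treated as plain unlabeled nodes in BOTH the
    feature computation and the labeling (the graph itself never changes),
    and the class each masked gene receives is tallied, together with the
    mean/median/mode of the association scores landing in each class.
    """
    if mask_fraction < 0 or mask_fraction * n_folds > 1.0 + 1e-9:
        raise ValueError("mask_fraction * n_folds must not exceed 1")
    feature_params = dict(feature_params or {})
    label_params = dict(label_params or {})
    rng = np.random.default_rng(seed)
    members = list(seeds.members)
    rng.shuffle(members)
    per_mask = int(round(mask_fraction * len(members)))
    folds = [tuple(sorted(members[i * per_mask:(i + 1) * per_mask])) for i in range(n_folds)]
    per_fold: list[dict[str, int]] = []
    landed: dict[str, list[float]] = {c: [] for c in LABELS}
    for masked in folds:
        if not masked:
            per_fold.append({c: 0 for c in LABELS})
            continue
        visible = [g for g in seeds.members if g not in set(masked)]
        if len(visible) < 2:
            raise ValueError("masking leaves fewer than 2 seed genes")
        sub = seeds.restrict(visible)
        F = assemble_features(net, sub, **feature_params)
        assignment = label_genes(F, sub.members, **label_params)
        counts = {c: 0 for c in LABELS}
        for g in masked:
            cls = assignment.label[g]
            counts[cls] += 1
            landed[cls].append(seeds.scores[g])
        per_fold.append(counts)
    stats = {}
    for c in LABELS:
        vals = landed[c]
        stats[c] = {
            "n": len(vals),
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "median": float(np.median(vals)) if vals else float("nan"),
            "mode": _mode_2dp(vals) if vals else float("nan"),
        }
    return RediscoveryReport(per_fold=tuple(per_fold), score_stats=stats,
                             masked=tuple(folds))


def rank_candidates(labels: LabelAssignment) -> tuple[str, ...]:
    """All non-P genes by g_inf descending: the LP ranking extended through WN/LN/RN."""
    vals = labels.g_inf
    non_p = [g for g in vals if labels.label[g] != "P"]
    non_p.sort(key=lambda g: (-vals[g], g))
    return tuple(non_p)


def evaluate_ranking(
    ranking: Sequence[str],
    gold: set[str] | Sequence[str],
    ks: Sequence[int],
) -> list[tuple[int, float, float, float]]:
    """Precision/recall/F1 of the top-k prefix against a gold-positive set."""
    gold = set(gold)
    if not gold:
        raise ValueError("gold set is empty")
    out = []
    for k in ks:
        top = set(ranking[:k])
        tp = len(top & gold)
        prec = tp / k if k else 0.0
        rec = tp / len(gold)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out.append((int(k), prec, rec, f1))
    return out
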