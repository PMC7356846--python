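"""Molecule-level evaluation of per-image predictions.

Each molecule is photographed from many angles and scored per image; the
median of its per-image probabilities is the molecule's representative
score. The classification cutoff is chosen by maximizing the Youden index
J = sensitivity + specificity - 1 over observed thresholds, and performance
is summarized by ROC AUC, balanced accuracy (BAC), accuracy (%), F-measure
and the Matthews correlation coefficient (MCC), averaged over replicates
with a standard error.

MCC uses the standard definition with the square root over the denominator
product,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

since the radical-free variant is not scale-consistent. When a confusion
denominator is zero, MCC and F report a sentinel 0 instead of NaN.

The cutoff is, by default, chosen on the scores being evaluated themselves
(optimistic for small test sets); pass an externally derived cutoff to
:func:`confusion_metrics` for an honest held-out estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

LABEL_POS = "active"


@dataclass
class MoleculeScore:
    compound_id: str
    median_probability: float
    label: str  # active | inactive


@dataclass
class MetricsReport:
    auc: float
    bac: float
    acc_percent: float
    f_measure: float
    mcc: float
    cutoff: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int
    replicate: str = ""

    METRICS = ("auc", "bac", "acc_percent", "f_measure", "mcc")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def aggregate_median(table: pd.DataFrame) -> list[MoleculeScore]:
    """Median per-image probability per compound (mean of central pair when
    the image count is even)."""
    if len(table) == 0:
        raise ValueError("empty prediction table")
    out = []
    grouped = table.groupby("compound_id", sort=True)
    for cid, grp in grouped:
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"compound {cid} has conflicting labels")
        out.append(MoleculeScore(
            compound_id=str(cid),
            median_probability=float(grp["probability_active"].median()),
            label=str(labels[0])))
    return out


def _split_scores(scores: Sequence[MoleculeScore]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.label == LABEL_POS for s in scores], dtype=int)
    p = np.array([s.median_probability for s in scores], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y, p


def roc_auc(scores: Sequence[MoleculeScore]) -> float:
    """ROC AUC; equals the Mann-Whitney probability that a random active
    outscores a random inactive, ties counting one half."""
    y, p = _split_scores(scores)
    return float(roc_auc_score(y, p))


def youden_cutoff(scores: Sequence[MoleculeScore]) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 over observed
    thresholds, with prediction rule "active iff score >= cutoff".

    Returns (cutoff, J); J is clipped into [0, 1] only in the sense that a
    useless classifier yields J = 0 (the trivial all-negative threshold is
    always among the candidates).
    """
    y, p = _split_scores(scores)
    # candidate cutoffs: every observed score plus one above the maximum
    # (the all-negative rule), so J >= 0 always has a witness
    candidates = np.unique(p)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    best_j, best_cut = -np.inf, candidates[-1]
    for c in candidates:
        pred = p >= c
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-15:
            best_j, best_cut = j, c
    return float(best_cut), float(best_j)


def confusion_metrics(scores: Sequence[MoleculeScore],
                      cutoff: Optional[float] = None,
                      replicate: str = "") -> MetricsReport:
    """Full metric panel at a cutoff (Youden-chosen on these scores if None).

    Molecules are predicted active iff median >= cutoff. Degenerate
    denominators in F and MCC yield 0.
    """
    y, p = _split_scores(scores)
    if cutoff is None:
        cutoff, j = youden_cutoff(scores)
    else:
        pred0 = p >= cutoff
        tpr = (pred0 & (y == 1)).sum() / y.sum()
        fpr = (pred0 & (y == 0)).sum() / (len(y) - y.sum())
        j = float(tpr - fpr)
    pred = p >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bac = (sens + spec) / 2.0
    acc = (tp + tn) / len(y) * 100.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = sens
    f = (2 * recall * precision / (recall + precision)
         if recall + precision > 0 else 0.0)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0

    return MetricsReport(auc=roc_auc(scores), bac=bac, acc_percent=acc,
                         f_measure=f, mcc=mcc, cutoff=float(cutoff),
                         youden_j=float(j), tp=tp, fp=fp, tn=tn, fn=fn,
                         replicate=replicate)


def average_replicates(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean and standard error of each metric across replicate reports."""
    if not reports:
        raise ValueError("no reports to average")
    rows = []
    for name in MetricsReport.METRICS:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        se = (vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"metric": name, "mean": vals.mean(), "se": se,
                     "n": len(vals)})
    return pd.DataFrame(rows)


def roc_points(scores: Sequence[MoleculeScore]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting/export."""
    y, p = _split_scores(scores)
    fpr, tpr, thr = roc_curve(y, p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_replicate(prediction_table: pd.DataFrame,
                       replicate: str = "",
                       cutoff: Optional[float] = None) -> MetricsReport:
    """Median aggregation followed by the full metric panel."""
    return confusion_metrics(aggregate_median(prediction_table),
                             cutoff=cutoff, replicate=replicate)
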