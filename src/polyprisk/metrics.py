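"""Classification metrics, FIT baseline, Kruskal-Wallis screening, score summaries.

The Matthews correlation coefficient (MCC) is the pipeline's sole selection
objective; it is computed from the confusion counts
``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` and defined as 0
whenever a marginal is empty. AUC, ROC curves and the Kruskal-Wallis H test
go through scikit-learn and scipy respectively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve, auc as _auc
from statsmodels.stats.multitest import multipletests

from .cohort import PatientRecord
from .kde import fit_density, silverman_bandwidth


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Defined as 0 when any marginal (row or column sum) is zero.
    """
    for c in (tp, tn, fp, fn):
        if c < 0:
            raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("confusion counts sum to zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class MetricsReport:
    """Confusion counts and derived binary-classification metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.tn, self.fp, self.fn)

    @property
    def normalized_confusion(self) -> np.ndarray:
        """2x2 matrix normalized per true class (rows: true no/yes; sum to 1)."""
        m = np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=float)
        sums = m.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return m / sums

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int], scores: Optional[Sequence[float]] = None
    ) -> "MetricsReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        auc_val = None
        if scores is not None and len(set(y_true.tolist())) == 2:
            auc_val = roc_auc(y_true, scores)[0]
        return cls(tp, tn, fp, fn, auc=auc_val)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "mcc": self.mcc,
            "normalized_confusion": self.normalized_confusion.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, pd.DataFrame]:
    """AUC plus ROC curve points; ties contribute 1/2 (Mann-Whitney convention)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(_auc(fpr, tpr)), curve


def predictions_from_scores(scores: Sequence[float], cutoff: float = 0.5) -> np.ndarray:
    """Binarize polyp scores at the default 0.5 operating point."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def fit_baseline_metrics(
    records: Sequence[PatientRecord], threshold_mm: int
) -> tuple[MetricsReport, int]:
    """FIT as a classifier: positive result predicts "yes" at the given
    polyp-size threshold. Records with a missing FIT result are excluded;
    their count is returned alongside the report."""
    cut = max(threshold_mm, 1)
    known = [r for r in records if r.fit_result != "missing"]
    n_missing = len(records) - len(known)
    y_true = [1 if r.max_polyp_mm >= cut else 0 for r in known]
    y_pred = [1 if r.fit_result == "positive" else 0 for r in known]
    return MetricsReport.from_predictions(y_true, y_pred), n_missing


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def kruskal_wallis_screen(X: pd.DataFrame, y: Sequence) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis screening against a grouping variable.

    Raw p-values are reported (no correction is applied for screening);
    a Benjamini-Hochberg column is emitted for reference.
    """
    rows = []
    y = np.asarray(y)
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        h, p = kruskal_wallis(v[ok], y[ok])
        rows.append({"feature": name, "H": h, "p": p})
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


@dataclass
class CellSummary:
    count: int
    q1: Optional[float] = None
    median: Optional[float] = None
    q3: Optional[float] = None
    kde_grid: list = field(default_factory=list)
    kde_values: list = field(default_factory=list)


def score_distribution_summary(
    scores: Sequence[float], labels: Sequence[int], predictions: Sequence[int]
) -> dict[str, CellSummary]:
    """Summaries of the polyp-score distribution per confusion cell and per
    true class: counts, quartiles and a unit-max score KDE for plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    cells = {
        "TP": (labels == 1) & (predictions == 1),
        "TN": (labels == 0) & (predictions == 0),
        "FP": (labels == 0) & (predictions == 1),
        "FN": (labels == 1) & (predictions == 0),
        "yes": labels == 1,
        "no": labels == 0,
    }
    out = {}
    for key, mask in cells.items():
        s = scores[mask]
        if s.size == 0:
            out[key] = CellSummary(count=0)
            continue
        q1, med, q3 = np.quantile(s, [0.25, 0.5, 0.75])
        summary = CellSummary(count=int(s.size), q1=float(q1), median=float(med), q3=float(q3))
        if s.size >= 2 and np.ptp(s) > 0:
            h = silverman_bandwidth(s)
            grid, dens = fit_density(s, h, grid_size=128)
            summary.kde_grid = grid.tolist()
            summary.kde_values = (dens / dens.max()).tolist()
        out[key] = summary
    return out
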