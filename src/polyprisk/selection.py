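"""The optimization loop: bandwidth search, backward feature elimination,
the (threshold x transform x exponent x classifier) grid, and final
test-set selection by MCC.

All selection during optimization uses cross-validated MCC on the training
split only; the test split is touched exactly once, when the best-k
candidates are compared (:func:`select_best`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import LabeledDataset, PatientRecord, make_labels, split_train_test
from .estimator import CLASSIFIER_ABBREV, ZOO, PolypRiskClassifier, cv_mcc
from .kde import silverman_bandwidth
from .metrics import MetricsReport
from .schema import FeatureSchema

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0, 6, 8, 10)
DEFAULT_MODES = ("none", "kde", "sigmoid_kde")
DEFAULT_EXPONENTS = (1, 2, 3, 4)


@dataclass
class ThresholdData:
    """Train/test split of one sex's cohort at one polyp-size threshold."""

    threshold_mm: int
    train: LabeledDataset
    test: LabeledDataset


@dataclass
class CandidateModel:
    """One point of the optimization grid."""

    sex: str
    threshold_mm: int
    mode: str
    exponent: Optional[int]
    classifier: str
    features: tuple[str, ...]
    cv_mcc: float
    seed: int = 0
    bandwidth: object = "silverman"
    direction: object = "auto"

    def estimator(self) -> PolypRiskClassifier:
        return PolypRiskClassifier(
            classifier=self.classifier,
            mode=self.mode,
            exponent=self.exponent if self.exponent is not None else 1,
            bandwidth=self.bandwidth,
            direction=self.direction,
            features=list(self.features),
            random_state=self.seed,
        )

    def name(self) -> str:
        """Compact model label, e.g. ``0 S-SKDE-4E-GP``."""
        abbr = CLASSIFIER_ABBREV[self.classifier]
        if self.mode == "none":
            return f"{self.threshold_mm} S-NoKDE-{abbr}"
        tag = "SKDE" if self.mode == "sigmoid_kde" else "KDE"
        return f"{self.threshold_mm} S-{tag}-{self.exponent}E-{abbr}"

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "threshold_mm": self.threshold_mm,
            "mode": self.mode,
            "exponent": self.exponent,
            "classifier": self.classifier,
            "features": list(self.features),
            "cv_mcc": self.cv_mcc,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateModel":
        return cls(
            sex=d["sex"],
            threshold_mm=d["threshold_mm"],
            mode=d["mode"],
            exponent=d["exponent"],
            classifier=d["classifier"],
            features=tuple(d["features"]),
            cv_mcc=d["cv_mcc"],
            seed=d.get("seed", 0),
        )


def prepare_threshold_data(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    sex: str,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> dict[int, ThresholdData]:
    """Label and split one sex's cohort at each polyp-size threshold."""
    out = {}
    for t in thresholds:
        ds = make_labels(records, t, schema, sex=sex)
        train, test = split_train_test(ds, test_fraction, seed)
        out[t] = ThresholdData(t, train, test)
    return out


def optimize_bandwidth(
    train: LabeledDataset,
    feature: str,
    estimator: PolypRiskClassifier,
    h_grid: Optional[Sequence[float]] = None,
    cv: int = 5,
    seed: int = 0,
) -> float:
    """Coordinate-wise bandwidth search for one feature.

    Scans ``h_grid`` (default: Silverman's rule x {0.25, 0.5, 1, 2, 4} on
    the positive-class training values) and returns the width maximizing the
    full model's cross-validated MCC, other features' bandwidths held fixed.
    Ties break toward the smallest width. A zero-variance feature is flagged
    and gets the Silverman default.
    """
    vy = train.X.loc[train.y == 1, feature].to_numpy(dtype=float)
    vy = vy[~np.isnan(vy)]
    if vy.size < 2 or np.ptp(vy) == 0:
        warnings.warn(f"feature {feature!r} degenerate; returning Silverman default")
        return silverman_bandwidth(vy) if vy.size >= 2 else 1e-6
    h0 = silverman_bandwidth(vy)
    if h_grid is None:
        h_grid = [h0 * f for f in (0.25, 0.5, 1.0, 2.0, 4.0)]
    if len(h_grid) == 0:
        raise ValueError("h_grid must be non-empty")
    base = estimator.get_params()["bandwidth"]
    fixed = dict(base) if isinstance(base, Mapping) else {}
    best_h, best_score = None, -np.inf
    for h in sorted(h_grid):
        est = estimator.__class__(**{**estimator.get_params(), "bandwidth": {**fixed, feature: h}})
        score = cv_mcc(est, train.X, train.y, cv=cv, seed=seed)
        if score > best_score:  # strict: ties keep the smaller h
            best_h, best_score = h, score
    return float(best_h)


def backward_eliminate(
    train: LabeledDataset,
    estimator: PolypRiskClassifier,
    cv: int = 5,
    seed: int = 0,
    floor: int = 3,
) -> list[CandidateModel]:
    """Backward feature elimination driven by cross-validated MCC.

    At each iteration every feature's removal is trialled by refitting the
    model without it; the feature whose removal yields the highest CV MCC —
    the most harmful or least helpful one — is eliminated. One candidate is
    recorded per iteration (the first holds the full feature set) until
    ``floor`` features remain. Ties break by schema (column) order.
    """
    feats = list(estimator.features) if estimator.features is not None else list(train.X.columns)
    if len(feats) < floor:
        raise ValueError(f"need at least {floor} features, got {len(feats)}")
    params = estimator.get_params()

    def _cand(subset: list[str]) -> CandidateModel:
        est = PolypRiskClassifier(**{**params, "features": subset})
        score = cv_mcc(est, train.X, train.y, cv=cv, seed=seed)
        return CandidateModel(
            sex=train.sex,
            threshold_mm=train.threshold_mm,
            mode=params["mode"],
            exponent=params["exponent"] if params["mode"] != "none" else None,
            classifier=params["classifier"],
            features=tuple(subset),
            cv_mcc=score,
            seed=seed,
            bandwidth=params["bandwidth"],
            direction=params["direction"],
        )

    path = [_cand(feats)]
    current = feats
    while len(current) > floor:
        best_feat, best_score = None, -np.inf
        for f in current:  # schema order; strict > keeps the earliest on ties
            trial = [g for g in current if g != f]
            est = PolypRiskClassifier(**{**params, "features": trial})
            score = cv_mcc(est, train.X, train.y, cv=cv, seed=seed)
            if score > best_score:
                best_feat, best_score = f, score
        current = [g for g in current if g != best_feat]
        path.append(_cand(current))
    return path


def run_grid(
    data: Mapping[int, ThresholdData],
    sex: str = "all",
    modes: Sequence[str] = DEFAULT_MODES,
    exponents: Sequence[int] = DEFAULT_EXPONENTS,
    zoo: Sequence[str] = ZOO,
    cv: int = 5,
    seed: int = 0,
    eliminate: bool = False,
    floor: int = 3,
) -> tuple[list[CandidateModel], pd.DataFrame]:
    """Evaluate every (threshold, mode, exponent, classifier) combination.

    Returns all candidates (every elimination iteration when ``eliminate``)
    plus a table with one row per combination holding its best CV MCC over
    the elimination path. ``exponent`` is ignored for mode "none".
    """
    candidates: list[CandidateModel] = []
    rows = []
    for t, td in data.items():
        if len(np.unique(td.train.y)) < 2:
            logger.warning("threshold %s: a class is empty after relabelling; skipped", t)
            continue
        for mode in modes:
            exps: Sequence[Optional[int]] = [None] if mode == "none" else exponents
            for e in exps:
                for clf in zoo:
                    est = PolypRiskClassifier(
                        classifier=clf,
                        mode=mode,
                        exponent=e if e is not None else 1,
                        random_state=seed,
                    )
                    if eliminate:
                        path = backward_eliminate(td.train, est, cv=cv, seed=seed, floor=floor)
                    else:
                        feats = list(td.train.X.columns)
                        score = cv_mcc(est, td.train.X, td.train.y, cv=cv, seed=seed)
                        path = [
                            CandidateModel(
                                sex=sex,
                                threshold_mm=t,
                                mode=mode,
                                exponent=e,
                                classifier=clf,
                                features=tuple(feats),
                                cv_mcc=score,
                                seed=seed,
                            )
                        ]
                    for c in path:
                        c.sex = sex
                    candidates.extend(path)
                    best = max(path, key=lambda c: c.cv_mcc)
                    rows.append(
                        {
                            "sex": sex,
                            "threshold_mm": t,
                            "mode": mode,
                            "exponent": e,
                            "classifier": clf,
                            "n_features": len(best.features),
                            "cv_mcc": best.cv_mcc,
                        }
                    )
    return candidates, pd.DataFrame(rows)


@dataclass
class SelectionResult:
    best: CandidateModel
    estimator: PolypRiskClassifier  # refit on the full training split
    report: MetricsReport
    evaluated: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_best(
    candidates: Sequence[CandidateModel],
    data: Mapping[int, ThresholdData],
    k: int = 6,
) -> SelectionResult:
    """Refit the top-k candidates (by CV MCC) on their full training split and
    pick the test-MCC argmax; ties break by CV MCC, then zoo order."""
    if len(candidates) == 0:
        raise ValueError("no candidates to select from")
    if k > len(candidates):
        warnings.warn(f"k={k} exceeds {len(candidates)} candidates; using all")
        k = len(candidates)
    top = sorted(candidates, key=lambda c: -c.cv_mcc)[:k]
    rows, fitted = [], []
    for c in top:
        td = data[c.threshold_mm]
        est = c.estimator().fit(td.train.X, td.train.y)
        scores = est.polyp_score(td.test.X)
        pred = est.predict(td.test.X)
        rep = MetricsReport.from_predictions(td.test.y, pred, scores)
        fitted.append((c, est, rep))
        rows.append(
            {
                "model": c.name(),
                "sex": c.sex,
                "threshold_mm": c.threshold_mm,
                "mode": c.mode,
                "exponent": c.exponent,
                "classifier": c.classifier,
                "n_features": len(c.features),
                "cv_mcc": c.cv_mcc,
                "test_sensitivity": rep.sensitivity,
                "test_specificity": rep.specificity,
                "test_accuracy": rep.accuracy,
                "test_auc": rep.auc,
                "test_mcc": rep.mcc,
            }
        )
    best_c, best_est, best_rep = max(
        fitted, key=lambda t: (t[2].mcc, t[0].cv_mcc, -ZOO.index(t[0].classifier))
    )
    return SelectionResult(best_c, best_est, best_rep, pd.DataFrame(rows))


def predict_polyp_score(estimator: PolypRiskClassifier, X) -> np.ndarray:
    """Scores in [0, 1] for new records (thin wrapper over the estimator)."""
    return estimator.polyp_score(X)
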