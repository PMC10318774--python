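"""The risk-model estimator: KDE transform + a fixed-hyperparameter classifier.

:class:`PolypRiskClassifier` is a scikit-learn classifier that (1) median-
imputes missing values from its training data, (2) optionally applies the
per-feature KDE probability transform fit on the positive training class,
and (3) fits one of a fixed zoo of classifiers. Its ``polyp_score`` is the
class-1 probability when available, otherwise the decision function min-max
scaled to [0, 1] using the training-score extremes.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.utils.validation import check_is_fitted

from .kde import KDETransformer
from .metrics import mcc as _mcc

#: canonical order of the classifier zoo (used for tie-breaking)
ZOO = (
    "adaboost",
    "bernoulli_nb",
    "gaussian_process",
    "gradient_boost",
    "lda",
    "linear_svc",
    "logistic_regression",
    "mlp",
    "ridge",
    "svc",
)

CLASSIFIER_ABBREV = {
    "adaboost": "AB",
    "bernoulli_nb": "BNB",
    "gaussian_process": "GP",
    "gradient_boost": "GB",
    "lda": "LDA",
    "linear_svc": "LSVC",
    "logistic_regression": "LR",
    "mlp": "MLP",
    "ridge": "RIDGE",
    "svc": "SVC",
}


def make_classifier(classifier_id: str, seed: Optional[int] = None):
    """Instantiate a zoo member with its fixed hyperparameters."""
    if classifier_id == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if classifier_id == "bernoulli_nb":
        return BernoulliNB(binarize=0.5)
    if classifier_id == "gaussian_process":
        # fixed RBF kernel: features are (0,1] after the KDE transform
        return GaussianProcessClassifier(
            kernel=ConstantKernel(1.0) * RBF(1.0), optimizer=None, random_state=seed
        )
    if classifier_id == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed)
    if classifier_id == "lda":
        return LinearDiscriminantAnalysis()
    if classifier_id == "linear_svc":
        return LinearSVC(C=1.0, dual="auto", max_iter=5000, random_state=seed)
    if classifier_id == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=1000)
    if classifier_id == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=500, random_state=seed)
    if classifier_id == "ridge":
        return RidgeClassifier()
    if classifier_id == "svc":
        return SVC(C=1.0, kernel="rbf", random_state=seed)
    raise ValueError(f"unknown classifier id {classifier_id!r}; choose from {ZOO}")


class PolypRiskClassifier(ClassifierMixin, BaseEstimator):
    """KDE-transform + classifier risk model.

    Parameters
    ----------
    classifier : str
        Zoo member id (see :data:`ZOO`).
    mode : {"none", "kde", "sigmoid_kde"}
        Feature-transform mode.
    exponent : int in {1..4}
        KDE sharpening exponent (ignored for mode "none").
    bandwidth, direction, grid_size
        Passed to :class:`~polyprisk.kde.KDETransformer`.
    features : sequence of str, optional
        Restrict the model to a feature subset (column names).
    random_state : int, optional
        Seeds any stochastic classifier.
    """

    def __init__(
        self,
        classifier: str = "logistic_regression",
        mode: str = "sigmoid_kde",
        exponent: int = 1,
        bandwidth: Union[str, float, Mapping[str, float]] = "silverman",
        direction: Union[str, Mapping[str, str]] = "auto",
        grid_size: int = 512,
        features: Optional[Sequence[str]] = None,
        random_state: Optional[int] = None,
    ):
        self.classifier = classifier
        self.mode = mode
        self.exponent = exponent
        self.bandwidth = bandwidth
        self.direction = direction
        self.grid_size = grid_size
        self.features = features
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _prepare(self, X, fitting: bool) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        if self.features is not None:
            X = X[list(self.features)]
        if fitting:
            self.medians_ = X.median(numeric_only=True)
        return X.fillna(self.medians_)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y) -> "PolypRiskClassifier":
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("PolypRiskClassifier is a binary classifier")
        X = self._prepare(X, fitting=True)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.transformer_ = KDETransformer(
            mode=self.mode,
            exponent=self.exponent,
            bandwidth=self.bandwidth,
            direction=self.direction,
            grid_size=self.grid_size,
        ).fit(X, y)
        Xt = self.transformer_.transform(X).to_numpy(dtype=float)
        self.classifier_ = make_classifier(self.classifier, self.random_state)
        self.classifier_.fit(Xt, y)
        if not hasattr(self.classifier_, "predict_proba"):
            d = self.classifier_.decision_function(Xt)
            self.score_lo_, self.score_hi_ = float(np.min(d)), float(np.max(d))
        return self

    def _transformed(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        X = self._prepare(X, fitting=False)
        return self.transformer_.transform(X).to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        return self.classifier_.predict(self._transformed(X))

    def polyp_score(self, X) -> np.ndarray:
        """Per-patient score in [0, 1] expressing polyp likelihood."""
        Xt = self._transformed(X)
        if hasattr(self.classifier_, "predict_proba"):
            return self.classifier_.predict_proba(Xt)[:, 1]
        d = self.classifier_.decision_function(Xt)
        span = self.score_hi_ - self.score_lo_
        if span <= 0:
            return np.full(d.shape, 0.5)
        return np.clip((d - self.score_lo_) / span, 0.0, 1.0)

    def decision_function(self, X) -> np.ndarray:
        return self.polyp_score(X)


def cv_mcc(
    estimator: PolypRiskClassifier,
    X: pd.DataFrame,
    y: Sequence[int],
    cv: int = 5,
    seed: int = 0,
    return_folds: bool = False,
):
    """Mean stratified-k-fold MCC of an (unfitted) estimator.

    The full pipeline — imputation, KDE fit on the positive class, classifier
    — is refit inside every training fold, so no test-fold information leaks
    into the transform.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv:
        raise ValueError(
            f"cannot build {cv} stratified folds: minority class has {counts.min()} members"
        )
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    fold_mccs, folds = [], []
    for train_idx, test_idx in skf.split(X, y):
        est = clone(estimator)
        est.fit(X.iloc[train_idx], y[train_idx])
        pred = est.predict(X.iloc[test_idx])
        yt = y[test_idx]
        tp = int(np.sum((yt == 1) & (pred == 1)))
        tn = int(np.sum((yt == 0) & (pred == 0)))
        fp = int(np.sum((yt == 0) & (pred == 1)))
        fn = int(np.sum((yt == 1) & (pred == 0)))
        fold_mccs.append(_mcc(tp, tn, fp, fn))
        folds.append({"test_idx": test_idx, "y_true": yt, "y_pred": pred})
    mean = float(np.mean(fold_mccs))
    if return_folds:
        return mean, fold_mccs, folds
    return mean
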