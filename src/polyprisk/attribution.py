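"""Shapley-value feature attribution and per-patient risk reports.

Attributions explain the model's polyp score per record as a sum of
per-feature contributions around a base value (the mean score over a
background sample), satisfying the additivity identity
``base + sum_j phi_j = score(x)`` exactly.

Two estimators are provided: exact enumeration over all feature coalitions
(used automatically for p <= 12) and permutation sampling with a fixed
background sample, both with marginal features drawn from the background
(interventional expectation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import FeatureSchema

EXACT_MAX_FEATURES = 12


class CapabilityError(RuntimeError):
    """The model lacks a capability the report requires."""


@dataclass
class AttributionReport:
    """Per-feature importances and per-record attributions."""

    feature_importance: pd.Series  # mean |attribution| per feature, descending
    attributions: pd.DataFrame  # one row per explained record
    base_value: float
    scores: np.ndarray  # model scores of the explained records

    def check_additivity(self, atol: float = 1e-6) -> None:
        total = self.base_value + self.attributions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(total, self.scores, atol=atol)

    def top_features(self, m: int = 3) -> list[str]:
        return list(self.feature_importance.index[:m])

    def to_dict(self) -> dict:
        return {
            "feature_importance": self.feature_importance.to_dict(),
            "attributions": self.attributions.to_dict(orient="list"),
            "base_value": self.base_value,
            "scores": self.scores.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _exact_shapley(
    score_fn: Callable[[pd.DataFrame], np.ndarray],
    background: pd.DataFrame,
    explain: pd.DataFrame,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by coalition enumeration (interventional v)."""
    cols = list(background.columns)
    p = len(cols)
    m, n = len(background), len(explain)
    bg = background.to_numpy(dtype=float)
    ex = explain.to_numpy(dtype=float)

    # v[mask, i] = mean_b score(x_i on mask, b elsewhere)
    v = np.empty((1 << p, n))
    tiled_bg = np.tile(bg, (n, 1))  # n blocks of m background rows
    for mask in range(1 << p):
        z = tiled_bg.copy()
        for j in range(p):
            if mask >> j & 1:
                z[:, j] = np.repeat(ex[:, j], m)
        s = score_fn(pd.DataFrame(z, columns=cols))
        v[mask] = np.asarray(s, dtype=float).reshape(n, m).mean(axis=1)

    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros((n, p))
    for mask in range(1 << p):
        size = bin(mask).count("1")
        w = fact[size] * fact[p - size - 1] / fact[p]
        for j in range(p):
            if not mask >> j & 1:
                phi[:, j] += w * (v[mask | (1 << j)] - v[mask])
    return phi, float(v[0].mean())


def _sampled_shapley(
    score_fn: Callable[[pd.DataFrame], np.ndarray],
    background: pd.DataFrame,
    explain: pd.DataFrame,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimate; additivity holds exactly."""
    cols = list(background.columns)
    p = len(cols)
    n = len(explain)
    bg = background.to_numpy(dtype=float)
    ex = explain.to_numpy(dtype=float)
    phi = np.zeros((n, p))
    base_acc = 0.0
    for _ in range(n_samples):
        b = bg[rng.integers(len(bg))]
        perm = rng.permutation(p)
        z = np.tile(b, (n, 1))
        prev = np.asarray(score_fn(pd.DataFrame(z, columns=cols)), dtype=float)
        base_acc += float(prev.mean())
        for j in perm:
            z[:, j] = ex[:, j]
            cur = np.asarray(score_fn(pd.DataFrame(z, columns=cols)), dtype=float)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_samples
    # base = mean score of the sampled background rows; note prev at the start
    # of each permutation is the same for all records, so use its mean
    return phi, base_acc / n_samples


def shapley_importance(
    model,
    background: pd.DataFrame,
    explain: pd.DataFrame,
    n_samples: int = 256,
    seed: int = 0,
    exact: Optional[bool] = None,
    max_background: int = 100,
) -> AttributionReport:
    """Shapley attributions of the model's polyp score.

    Parameters
    ----------
    model
        Fitted estimator exposing ``polyp_score(X)``.
    background
        Reference sample defining the marginal feature distributions; at most
        ``max_background`` rows are used (subsampled deterministically).
    explain
        Records to explain.
    n_samples
        Number of sampled permutations (sampling route only); must be at
        least twice the feature count.
    exact
        Force exact enumeration (or sampling); default: exact iff p <= 12.
    """
    if len(background) == 0:
        raise ValueError("background data must be non-empty")
    feats = list(model.feature_names_in_)
    background = pd.DataFrame(background)[feats]
    explain = pd.DataFrame(explain)[feats]
    p = len(feats)
    rng = np.random.default_rng(seed)
    if len(background) > max_background:
        idx = rng.choice(len(background), size=max_background, replace=False)
        background = background.iloc[np.sort(idx)]
    if exact is None:
        exact = p <= EXACT_MAX_FEATURES

    def score_fn(df: pd.DataFrame) -> np.ndarray:
        return model.polyp_score(df)

    if exact:
        phi, base = _exact_shapley(score_fn, background, explain)
    else:
        if n_samples < 2 * p:
            raise ValueError(f"n_samples must be >= 2*p = {2 * p}, got {n_samples}")
        phi, base = _sampled_shapley(score_fn, background, explain, n_samples, rng)

    attributions = pd.DataFrame(phi, columns=feats, index=explain.index)
    importance = attributions.abs().mean(axis=0).sort_values(ascending=False)
    scores = np.asarray(model.polyp_score(explain), dtype=float)
    return AttributionReport(importance, attributions, base, scores)


def patient_risk_report(
    model,
    record: pd.Series | dict,
    schema: FeatureSchema,
    background: pd.DataFrame,
    flag_threshold: float = 0.9,
    seed: int = 0,
) -> dict:
    """Per-patient biomarker report for counseling.

    Requires a sigmoid-KDE model: each feature's transformed value is a
    monotone risk-saturation score in (0, 1], and values close to 1 (>=
    ``flag_threshold``) flag biomarkers worth acting on. Also reports the
    polyp score and the top-3 Shapley contributors.
    """
    if getattr(model, "mode", None) != "sigmoid_kde":
        raise CapabilityError(
            "patient_risk_report requires a sigmoid_kde model: only the "
            "monotone clamped transform gives per-feature values readable "
            "as saturating risk scores"
        )
    row = pd.Series(record)
    feats = list(model.feature_names_in_)
    X = pd.DataFrame([row])[feats]
    X_imputed = X.fillna(model.medians_)
    transformed = {
        name: float(model.transformer_.densities_[name].transform(X_imputed[name].to_numpy())[0])
        for name in feats
    }
    flags = sorted(name for name, v in transformed.items() if v >= flag_threshold)
    score = float(model.polyp_score(X)[0])
    attr = shapley_importance(model, background, X, seed=seed, exact=len(feats) <= 12,
                              n_samples=max(256, 2 * len(feats)))
    top = attr.attributions.iloc[0].sort_values(ascending=False).index[:3].tolist()
    return {
        "polyp_score": score,
        "transformed_values": transformed,
        "flagged_features": flags,
        "flag_threshold": flag_threshold,
        "top_contributors": top,
    }


def format_patient_report(report: dict, schema: FeatureSchema) -> str:
    """Human-readable rendering of :func:`patient_risk_report` output."""
    lines = [f"Polyp score: {report['polyp_score']:.3f}", ""]
    lines.append(f"Biomarkers near risk saturation (>= {report['flag_threshold']}):")
    if report["flagged_features"]:
        for name in report["flagged_features"]:
            units = schema[name].units if name in schema else ""
            val = report["transformed_values"][name]
            lines.append(f"  - {name} ({units}): transformed value {val:.3f}")
    else:
        lines.append("  (none)")
    lines.append("")
    lines.append("Top contributing features: " + ", ".join(report["top_contributors"]))
    return "\n".join(lines)
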