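"""Per-feature KDE probability-like transform.

The transform at the heart of the pipeline: for each feature, a Gaussian
kernel density estimate is fit on the polyp-positive training patients only,
rescaled to a unit maximum, and raised to an integer exponent e in {1..4}
that sharpens the class contrast. The "sigmoid-like" variant additionally
clamps the density to 1 on one side of its maximum (the side on which risk
saturates), yielding a monotone risk curve. Transformed values live in
(0, 1] and act as probability-like risk scores per biomarker.

:class:`KDETransformer` packages the per-feature models as a scikit-learn
transformer; :func:`fit_density` / :func:`normalize_and_power` /
:func:`sigmoidize` expose the individual steps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

EXPONENTS = (1, 2, 3, 4)
MODES = ("none", "kde", "sigmoid_kde")

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class DensityFitError(ValueError):
    """Raised when a KDE cannot be fit (too few values, zero density)."""


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Falls back to the sd-only rule when the IQR is degenerate, and to a
    token positive width for constant samples.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise DensityFitError("need at least 2 values for a bandwidth")
    sd = v.std(ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * spread * n ** (-0.2)
    return h if h > 0 else 1e-6


def fit_density(values: Sequence[float], h: float, grid_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel-sum density on an even grid spanning [min-3h, max+3h].

    Returns ``(grid, density)`` with ``density[k] = (1/nh) sum_i
    phi((grid[k]-x_i)/h)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise DensityFitError("need at least 2 values to fit a density")
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * _SQRT_2PI)
    return grid, dens


@dataclass
class DensityModel:
    """A fitted, normalized, exponentiated (optionally clamped) feature KDE."""

    feature: str
    grid: np.ndarray
    values: np.ndarray  # transformed values on the grid, in (0, 1]
    bandwidth: float
    exponent: int = 1
    mode: str = "kde"  # kde | sigmoid_kde
    direction: Optional[str] = None  # higher | lower (sigmoid mode only)

    @property
    def argmax_x(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])

    def transform(self, x) -> np.ndarray:
        """Evaluate by linear interpolation; out-of-grid x clamps to the ends."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "grid": self.grid.tolist(),
            "values": self.values.tolist(),
            "bandwidth": self.bandwidth,
            "exponent": self.exponent,
            "mode": self.mode,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityModel":
        return cls(
            feature=d["feature"],
            grid=np.asarray(d["grid"], dtype=float),
            values=np.asarray(d["values"], dtype=float),
            bandwidth=d["bandwidth"],
            exponent=d["exponent"],
            mode=d["mode"],
            direction=d.get("direction"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "DensityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def normalize_and_power(
    feature: str, grid: np.ndarray, raw: np.ndarray, h: float, e: int = 1
) -> DensityModel:
    """Rescale a raw density to unit maximum and raise it to exponent e."""
    if e not in EXPONENTS:
        raise ValueError(f"exponent must be one of {EXPONENTS}, got {e}")
    raw = np.asarray(raw, dtype=float)
    peak = raw.max()
    if peak <= 0:
        raise DensityFitError("density is identically zero; cannot normalize")
    vals = (raw / peak) ** e
    return DensityModel(feature, np.asarray(grid, dtype=float), vals, h, exponent=e, mode="kde")


def sigmoidize(model: DensityModel, direction: str) -> DensityModel:
    """Clamp the KDE to 1 on one side of its maximum, producing a monotone curve.

    ``direction="higher"``: risk saturates for high feature values, so every
    grid value at or above the argmax becomes 1 and the curve rises toward
    it. ``"lower"`` is the mirror image. A monotone envelope (running
    maximum toward the clamped side) guarantees monotonicity even for
    multimodal densities; for unimodal densities it leaves the rising limb
    untouched. The exponent is applied after clamping (clamped points are 1
    and unaffected).
    """
    if model.mode != "kde":
        raise ValueError("sigmoidize expects a model in 'kde' mode")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    base = model.values ** (1.0 / model.exponent)  # back to the e=1 curve
    idx = int(np.argmax(base))
    out = base.copy()
    if direction == "higher":
        out = np.maximum.accumulate(out)
        out[idx:] = 1.0
    else:
        out = np.maximum.accumulate(out[::-1])[::-1]
        out[: idx + 1] = 1.0
    out = out ** model.exponent
    return DensityModel(
        model.feature,
        model.grid,
        out,
        model.bandwidth,
        exponent=model.exponent,
        mode="sigmoid_kde",
        direction=direction,
    )


def transform_value(model: DensityModel, x) -> np.ndarray:
    """Evaluate a fitted density model at new points (thin wrapper)."""
    return model.transform(x)


def infer_direction(values_yes: Sequence[float], values_no: Sequence[float]) -> str:
    """Resolve direction='auto' from training data: side with the higher
    polyp-class median saturates."""
    return "higher" if np.nanmedian(values_yes) >= np.nanmedian(values_no) else "lower"


def fit_feature_model(
    values_yes: Sequence[float],
    h: float,
    *,
    feature: str = "",
    exponent: int = 1,
    mode: str = "kde",
    direction: str = "higher",
    grid_size: int = 512,
) -> DensityModel:
    """Convenience: kernel sum -> unit-max normalization -> optional clamp."""
    grid, raw = fit_density(values_yes, h, grid_size)
    model = normalize_and_power(feature, grid, raw, h, exponent)
    if mode == "sigmoid_kde":
        model = sigmoidize(model, direction)
    return model


class KDETransformer(TransformerMixin, BaseEstimator):
    """Per-feature KDE probability transform as a scikit-learn transformer.

    Parameters
    ----------
    mode : {"none", "kde", "sigmoid_kde"}
        "none" passes features through unchanged.
    exponent : int in {1, 2, 3, 4}
        Power applied to the unit-max density.
    bandwidth : "silverman", float, or mapping feature -> float
        Kernel width per feature; Silverman's rule on the positive-class
        training values by default.
    direction : "auto" or mapping feature -> {"higher", "lower"}
        Side of the density maximum on which risk saturates (sigmoid mode).
        "auto" compares class medians on the training data.
    grid_size : int
        Number of evaluation grid points.

    The densities are always fit on the positive-class rows of the training
    data only; test rows are merely interpolated.
    """

    def __init__(
        self,
        mode: str = "kde",
        exponent: int = 1,
        bandwidth: Union[str, float, Mapping[str, float]] = "silverman",
        direction: Union[str, Mapping[str, str]] = "auto",
        grid_size: int = 512,
    ):
        self.mode = mode
        self.exponent = exponent
        self.bandwidth = bandwidth
        self.direction = direction
        self.grid_size = grid_size

    def _resolve_bandwidth(self, name: str, values_yes: np.ndarray) -> float:
        if isinstance(self.bandwidth, Mapping):
            h = self.bandwidth.get(name, "silverman")
        else:
            h = self.bandwidth
        if isinstance(h, str):
            if h != "silverman":
                raise ValueError(f"unknown bandwidth rule {h!r}")
            return silverman_bandwidth(values_yes)
        return float(h)

    def _resolve_direction(self, name: str, yes: np.ndarray, no: np.ndarray) -> str:
        if isinstance(self.direction, Mapping):
            d = self.direction.get(name, "auto")
        else:
            d = self.direction
        if d == "auto":
            return infer_direction(yes, no)
        if d not in ("higher", "lower"):
            raise ValueError(f"direction for {name!r} must be 'higher', 'lower' or 'auto'")
        return d

    def fit(self, X: pd.DataFrame, y=None) -> "KDETransformer":
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.densities_ = {}
        if self.mode == "none":
            return self
        if y is None:
            raise ValueError("y is required: densities are fit on the positive class")
        y = np.asarray(y)
        if self.exponent not in EXPONENTS:
            raise ValueError(f"exponent must be one of {EXPONENTS}")
        pos = X.loc[y == 1]
        neg = X.loc[y == 0]
        for name in X.columns:
            vy = pos[name].to_numpy(dtype=float)
            vy = vy[~np.isnan(vy)]
            if vy.size >= 2 and np.ptp(vy) == 0:
                warnings.warn(f"feature {name!r} is degenerate in the positive class")
            h = self._resolve_bandwidth(name, vy)
            direction = self._resolve_direction(
                name, vy, neg[name].to_numpy(dtype=float)
            )
            self.densities_[name] = fit_feature_model(
                vy,
                h,
                feature=name,
                exponent=self.exponent,
                mode=self.mode,
                direction=direction,
                grid_size=self.grid_size,
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "densities_")
        X = pd.DataFrame(X)
        if self.mode == "none":
            return X.copy()
        out = {}
        for name in X.columns:
            out[name] = self.densities_[name].transform(X[name].to_numpy(dtype=float))
        return pd.DataFrame(out, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_in_")
        return self.feature_names_in_
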