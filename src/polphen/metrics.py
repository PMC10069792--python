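"""Regression reporting metrics and feature standardisation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RegressionReport:
    """R^2 (squared Pearson), least-squares slope/intercept of predictions
    regressed on labels, and mean squared error."""

    r2: float
    slope: float
    intercept: float
    mse: float


def regression_metrics(labels, predictions) -> RegressionReport:
    """Least-squares regression of predictions on labels plus R^2 and MSE.

    R^2 is the squared Pearson correlation between predictions and labels.
    Constant labels leave the regression undefined and raise.
    """
    y = np.asarray(labels, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    if y.size < 2:
        raise ValueError("need at least 2 samples for regression metrics")
    if np.allclose(y, y[0]):
        raise ValueError("labels are constant; R^2 is undefined")
    res = stats.linregress(y, p)
    r2 = float(res.rvalue ** 2)
    mse = float(np.mean((p - y) ** 2))
    return RegressionReport(r2=r2, slope=float(res.slope),
                            intercept=float(res.intercept), mse=mse)


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data, applied identically
    at train and predict time.  Constant features get unit scale."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean
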