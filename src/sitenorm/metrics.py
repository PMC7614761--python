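"""Predictive performance measures for normative models.

Conventions: SRMSE is RMSE divided by the mean observed value, so it must be
evaluated on the original mm scale (coefficient-of-variation scaling); the
pointwise log-likelihood is the per-point mean Gaussian log-density so values
compare across test-set sizes; MSLL standardizes the log-loss by the trivial
train-mean/train-variance predictor (exactly 0 for that predictor, negative
when the model beats it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_rho", "srmse", "explained_variance", "pointwise_loglik",
    "msll", "variance_retention", "metric_report",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    keep = np.isfinite(y) & np.isfinite(yhat)
    return y[keep], yhat[keep]


def pearson_rho(y, yhat) -> float:
    """Product-moment correlation; NaN when either side has zero variance."""
    y, yhat = _pair(y, yhat)
    if len(y) < 3 or y.std() == 0 or yhat.std() == 0:
        return float("nan")
    return float(stats.pearsonr(y, yhat).statistic)


def srmse(y, yhat) -> float:
    """RMSE standardized by mean(y); use original (mm) scale values."""
    y, yhat = _pair(y, yhat)
    mean_y = y.mean()
    if mean_y == 0:
        raise ValueError("mean(y) is zero; SRMSE must be computed on the "
                         "original measurement scale")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / mean_y)


def explained_variance(y, yhat) -> float:
    """EV = 1 - var(y - yhat)/var(y)."""
    y, yhat = _pair(y, yhat)
    var_y = y.var()
    if var_y == 0:
        raise ValueError("var(y) is zero")
    return float(1.0 - (y - yhat).var() / var_y)


def _total_var(pred, n):
    if hasattr(pred, "total_var"):
        mean = np.asarray(pred.mean, dtype=float)
        var = np.asarray(pred.total_var, dtype=float)
    else:
        mean, var = pred
        mean = np.asarray(mean, dtype=float)
        var = np.broadcast_to(np.asarray(var, dtype=float), (n,)).copy()
    return mean, var


def pointwise_loglik(y, pred) -> float:
    """Mean Gaussian log-density of y under N(mean, total variance).

    ``pred`` is a PredictiveDistribution or a (mean, variance) pair.
    """
    y = np.asarray(y, dtype=float).ravel()
    mean, var = _total_var(pred, len(y))
    keep = np.isfinite(y)
    y, mean, var = y[keep], mean[keep], var[keep]
    if np.any(var <= 0):
        raise ValueError("non-positive predictive variance")
    ll = -0.5 * (np.log(2 * np.pi * var) + (y - mean) ** 2 / var)
    return float(ll.mean())


def msll(y_test, pred, train_mean: float, train_var: float) -> float:
    """Mean standardized log-loss against the trivial train-based predictor.

    mean over test points of [-log N(y | mean, var) + log N(y | train_mean,
    train_var)]; 0 for the trivial predictor itself, negative iff the model
    predicts better than the training mean.
    """
    if train_var <= 0:
        raise ValueError("train_var must be positive")
    y = np.asarray(y_test, dtype=float).ravel()
    model_ll = pointwise_loglik(y, pred)
    trivial_ll = pointwise_loglik(
        y, (np.full(len(y), train_mean), train_var))
    return float(-model_ll + trivial_ll)


def variance_retention(y, yhat) -> float:
    """var(predictions) / var(observations), in percent."""
    y, yhat = _pair(y, yhat)
    var_y = y.var()
    if var_y == 0:
        raise ValueError("var(y) is zero")
    return float(100.0 * yhat.var() / var_y)


def metric_report(y_mm, pred_mm, y_std, pred_std, train_mean_std: float,
                  train_var_std: float) -> dict:
    """All scalar metrics for one (region, model, split) cell.

    Mean-accuracy metrics use the mm scale; the likelihood-based metrics use
    the standardized scale (both invariant choices are documented per metric).
    """
    return {
        "rho": pearson_rho(y_mm, pred_mm.mean),
        "srmse": srmse(y_mm, pred_mm.mean),
        "ev": explained_variance(y_mm, pred_mm.mean),
        "ll": pointwise_loglik(y_std, pred_std),
        "msll": msll(y_std, pred_std, train_mean_std, train_var_std),
        "variance_retention": variance_retention(y_mm, pred_mm.mean),
    }
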