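"""Shared machinery for the Bayesian normative regression estimators.

All models regress a single region's thickness on an intercept, age (years)
and sex (1 = male), optionally with a dummy-coded site matrix Z (unit row
sums) carrying partially pooled random intercepts.  Estimators follow the
scikit-learn protocol: hyperparameters in ``__init__``, data only in
``fit(X, y)`` where ``X`` is a DataFrame with ``age``/``sex`` (and ``site``
for the hierarchical models) columns, fitted state in trailing-underscore
attributes.

Priors (weak, intended for standardized response scales but usable on mm):

* fixed effects        beta_j ~ N(0, beta_scale^2)
* site offsets         u_s | sigma_u ~ N(0, sigma_u^2),
                       sigma_u^2 ~ InverseGamma(2, 2)
* noise sd             sigma ~ HalfNormal(sigma_scale)
* GP signal sd         sigma_f ~ HalfNormal(sigmaf_scale)
* GP lengthscale       l ~ Uniform(lengthscale_bounds) in years

Positive scales are sampled on the log scale with the Jacobian included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._sampling import convergence_report, group_chains, run_ensemble

__all__ = ["PredictiveDistribution", "DeviationScores", "build_design",
           "zscores", "BayesianNormativeRegression"]

_COVARIATES = ("age", "sex")


def build_design(X: pd.DataFrame, site_registry: list[str] | None = None):
    """Build (X_mat, Z, sites) from a covariate frame.

    X_mat columns are [intercept, age, sex] in fixed order.  Z is the n x q
    dummy site matrix (unit row sums) over ``site_registry``; when a registry
    is given (prediction time) unknown site labels raise, since transfer to
    unseen sites is out of scope.  Returns Z=None when X has no site column.
    """
    for col in _COVARIATES:
        if col not in X.columns:
            raise ValueError(f"covariate column {col!r} missing")
    age = np.asarray(X["age"], dtype=float)
    sex = np.asarray(X["sex"], dtype=float)
    if not (np.isfinite(age).all() and np.isfinite(sex).all()):
        raise ValueError("age/sex must be finite and non-missing")
    X_mat = np.column_stack([np.ones_like(age), age, sex])
    if "site" not in X.columns:
        return X_mat, None, None
    site = X["site"].astype(str).to_numpy()
    if site_registry is None:
        site_registry = sorted(set(site))
    unknown = set(site) - set(site_registry)
    if unknown:
        raise ValueError(
            f"unknown site labels {sorted(unknown)}; prediction is only "
            "supported for sites present in training data")
    index = {s: k for k, s in enumerate(site_registry)}
    Z = np.zeros((len(site), len(site_registry)))
    Z[np.arange(len(site)), [index[s] for s in site]] = 1.0
    return X_mat, Z, list(site_registry)


@dataclass
class PredictiveDistribution:
    """Per-subject posterior predictive summary.

    ``mean`` is the across-draw mean of f*, ``epistemic_var`` the across-draw
    variance of f* (for the GP model f* includes the latent-trend conditional
    per draw), and ``noise_var`` the posterior mean of sigma^2.
    """
    mean: np.ndarray
    epistemic_var: np.ndarray
    noise_var: float
    index: np.ndarray | None = None

    @property
    def total_var(self) -> np.ndarray:
        return self.epistemic_var + self.noise_var

    @property
    def total_sd(self) -> np.ndarray:
        return np.sqrt(self.total_var)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "mean": self.mean,
            "epistemic_var": self.epistemic_var,
            "noise_var": self.noise_var,
        })
        if self.index is not None:
            out.insert(0, "subject_id", self.index)
        return out


@dataclass
class DeviationScores:
    """z-scores of deviation and the |z| > threshold atypicality flags."""
    z: np.ndarray
    threshold: float = 1.96
    index: np.ndarray | None = None

    @property
    def atypical(self) -> np.ndarray:
        return np.abs(self.z) > self.threshold

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"z": self.z, "atypical": self.atypical})
        if self.index is not None:
            out.insert(0, "subject_id", self.index)
        return out


def zscores(y, pred: PredictiveDistribution,
            threshold: float = 1.96) -> DeviationScores:
    """z_i = (y_i - f_i) / sqrt(sigma^2 + sigma*_i^2).

    A zero denominator is only allowed where y equals the predictive mean
    (z = 0 there); otherwise it is an error.
    """
    y = np.asarray(y, dtype=float)
    resid = y - pred.mean
    total = np.asarray(pred.total_var, dtype=float)
    zero = total <= 0
    if np.any(zero & (resid != 0)):
        raise ValueError("zero predictive variance with nonzero residual")
    z = np.zeros_like(resid)
    np.divide(resid, np.sqrt(total), out=z, where=~zero)
    return DeviationScores(z=z, threshold=threshold, index=pred.index)


def _halfnormal_logpdf(x, scale):
    return -0.5 * (x / scale) ** 2 + np.log(2.0) - 0.5 * np.log(
        2 * np.pi * scale ** 2)


def _invgamma_logpdf(v, a, b):
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(v) - b / v


class BayesianNormativeRegression(BaseEstimator):
    """Base class; subclasses define the parameter block layout and the
    likelihood.  Not intended for direct use."""

    _uses_site = False

    def __init__(self, draws=800, warmup=800, n_walkers=32, thin=3,
                 n_chains=4, beta_scale=5.0, sigma_scale=2.5,
                 predict_draws=200, random_state=0):
        self.draws = draws
        self.warmup = warmup
        self.n_walkers = n_walkers
        self.thin = thin
        self.n_chains = n_chains
        self.beta_scale = beta_scale
        self.sigma_scale = sigma_scale
        self.predict_draws = predict_draws
        self.random_state = random_state

    # ----- subclass hooks -------------------------------------------------
    def _param_blocks(self, q: int) -> list[tuple[str, int]]:
        raise NotImplementedError

    def _log_post(self, theta: np.ndarray) -> float:
        raise NotImplementedError

    def _init_center(self) -> np.ndarray:
        raise NotImplementedError

    def _predictive_draws(self, X_mat, Z, ages, draws, rng) -> np.ndarray:
        """(n_draws, n_subjects) matrix of f* draws."""
        raise NotImplementedError

    # ----- shared fit/predict --------------------------------------------
    def _validate_fit_inputs(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        keep = np.isfinite(y)
        X = X.loc[np.asarray(keep)]
        y = y[keep]
        if len(y) < 4:
            raise ValueError("need at least 4 complete observations")
        return X, y

    def fit(self, X: pd.DataFrame, y):
        X, y = self._validate_fit_inputs(X, y)
        X_mat, Z, sites = build_design(X)
        if self._uses_site:
            if Z is None:
                raise ValueError("this model requires a 'site' column")
            if Z.shape[1] < 2:
                raise ValueError(
                    "only one site present; use BayesianLinearModel")
        else:
            Z, sites = None, None
        self._train = {"X": X_mat, "Z": Z, "y": y,
                       "ages": np.asarray(X["age"], dtype=float)}
        self.sites_ = sites
        self.n_obs_ = len(y)

        blocks = self._param_blocks(0 if Z is None else Z.shape[1])
        ndim = sum(size for _, size in blocks)
        names, slices, pos = [], {}, 0
        for name, size in blocks:
            names.append(name)
            slices[name] = slice(pos, pos + size)
            pos += size
        self._blocks, self._slices = blocks, slices

        rng = np.random.default_rng(self.random_state)
        center = self._init_center()
        p0 = center + 0.05 * rng.standard_normal((self.n_walkers, ndim))
        chain, accept = run_ensemble(
            self._log_post, p0, warmup=self.warmup, draws=self.draws,
            seed=int(self.random_state) + 1, thin=self.thin)
        grouped = group_chains(chain, self.n_chains)
        self.posterior_ = self._unpack_chain(grouped)
        self.acceptance_fraction_ = accept
        self.convergence_ = convergence_report(
            self.posterior_, acceptance=accept)
        return self

    def _unpack_chain(self, grouped: np.ndarray) -> dict:
        post = {}
        for name, size in self._blocks:
            block = grouped[:, :, self._slices[name]]
            if name.startswith("log_"):
                post[name[4:]] = (np.exp(block[:, :, 0]) if size == 1
                                  else np.exp(block))
            else:
                post[name] = block[:, :, 0] if size == 1 else block
        return post

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    def _flat_posterior(self, name: str) -> np.ndarray:
        arr = self.posterior_[name]
        return arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.ravel()

    def _draw_indices(self, rng) -> np.ndarray:
        total = self._flat_posterior("sigma").shape[0]
        k = min(self.predict_draws, total)
        return rng.choice(total, size=k, replace=False)

    def predict_dist(self, X: pd.DataFrame) -> PredictiveDistribution:
        self._check_fitted()
        X_mat, Z, _ = build_design(X, site_registry=self.sites_)
        if self._uses_site and Z is None:
            raise ValueError("prediction requires a 'site' column")
        rng = np.random.default_rng(int(self.random_state) + 2)
        idx = self._draw_indices(rng)
        f_draws = self._predictive_draws(
            X_mat, Z, np.asarray(X["age"], dtype=float), idx, rng)
        sigma = self._flat_posterior("sigma")[idx]
        index = (X["subject_id"].to_numpy()
                 if "subject_id" in X.columns else None)
        return PredictiveDistribution(
            mean=f_draws.mean(axis=0),
            epistemic_var=f_draws.var(axis=0, ddof=1),
            noise_var=float(np.mean(sigma ** 2)),
            index=index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_dist(X).mean

    def score(self, X: pd.DataFrame, y) -> float:
        """Proportion of variance explained on (X, y)."""
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(y)
        pred = self.predict(X.loc[np.asarray(keep)])
        resid = y[keep] - pred
        return 1.0 - resid.var() / y[keep].var()

    # ----- shared prior pieces -------------------------------------------
    def _lp_beta(self, beta):
        return -0.5 * np.sum(beta ** 2) / self.beta_scale ** 2

    def _lp_log_sigma(self, log_sigma):
        sigma = np.exp(log_sigma)
        return _halfnormal_logpdf(sigma, self.sigma_scale) + log_sigma

    def _lp_site(self, u, log_sigma_u):
        v = np.exp(2.0 * log_sigma_u)
        lp = _invgamma_logpdf(v, 2.0, 2.0) + np.log(2.0 * v)  # prior + Jacobian
        lp += -0.5 * np.sum(u ** 2) / v - 0.5 * len(u) * np.log(
            2 * np.pi * v)
        return lp
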