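"""Bayesian linear normative models, with and without site random effects.

``BayesianLinearModel`` is the simple model f = X beta used downstream of the
harmonization baselines (and on raw data); it ignores site entirely.
``HierarchicalBayesianLinearModel`` adds dummy-coded site intercepts u_s with
a shared N(0, sigma_u^2) prior and an InverseGamma(2, 2) hyperprior on
sigma_u^2 — partial pooling: small sites are shrunk toward the common mean
harder than large ones.
"""

from __future__ import annotations

import numpy as np

from .base import BayesianNormativeRegression

__all__ = ["BayesianLinearModel", "HierarchicalBayesianLinearModel"]


def _gauss_loglik(resid, sigma):
    n = len(resid)
    return (-0.5 * np.sum(resid ** 2) / sigma ** 2
            - n * np.log(sigma) - 0.5 * n * np.log(2 * np.pi))


class BayesianLinearModel(BayesianNormativeRegression):
    """f = X beta with homoscedastic Gaussian noise; no site term.

    Parameters are beta (intercept, age, sex) and the noise sd sigma.
    """

    _uses_site = False

    def _param_blocks(self, q):
        return [("beta", 3), ("log_sigma", 1)]

    def _init_center(self):
        X, y = self._train["X"], self._train["y"]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = max(resid.std(), 1e-3)
        return np.concatenate([beta, [np.log(sd)]])

    def _log_post(self, theta):
        beta = theta[self._slices["beta"]]
        log_sigma = theta[self._slices["log_sigma"]][0]
        if abs(log_sigma) > 20:
            return -np.inf
        sigma = np.exp(log_sigma)
        resid = self._train["y"] - self._train["X"] @ beta
        return (_gauss_loglik(resid, sigma)
                + self._lp_beta(beta) + self._lp_log_sigma(log_sigma))

    def _predictive_draws(self, X_mat, Z, ages, idx, rng):
        beta = self._flat_posterior("beta")[idx]
        return beta @ X_mat.T


class HierarchicalBayesianLinearModel(BayesianNormativeRegression):
    """f = X beta + Z u with partially pooled site intercepts.

    u_s | sigma_u ~ N(0, sigma_u^2), sigma_u^2 ~ InverseGamma(2, 2).
    Requires >= 2 sites; predictions are restricted to training sites.
    """

    _uses_site = True

    def _param_blocks(self, q):
        return [("beta", 3), ("u", q), ("log_sigma", 1), ("log_sigma_u", 1)]

    def _init_center(self):
        X, Z, y = self._train["X"], self._train["Z"], self._train["y"]
        design = np.column_stack([X, Z[:, 1:]])  # drop one site: identifiable OLS
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        beta = coef[:3]
        u = np.concatenate([[0.0], coef[3:]])
        u -= u.mean()
        beta = beta.copy()
        beta[0] += (coef[3:].sum() / Z.shape[1])
        resid = y - X @ beta - Z @ u
        sd = max(resid.std(), 1e-3)
        sd_u = max(u.std(), 0.05)
        return np.concatenate([beta, u, [np.log(sd)], [np.log(sd_u)]])

    def _log_post(self, theta):
        sl = self._slices
        beta = theta[sl["beta"]]
        u = theta[sl["u"]]
        log_sigma = theta[sl["log_sigma"]][0]
        log_sigma_u = theta[sl["log_sigma_u"]][0]
        if abs(log_sigma) > 20 or abs(log_sigma_u) > 20:
            return -np.inf
        sigma = np.exp(log_sigma)
        resid = (self._train["y"] - self._train["X"] @ beta
                 - self._train["Z"] @ u)
        return (_gauss_loglik(resid, sigma) + self._lp_beta(beta)
                + self._lp_site(u, log_sigma_u)
                + self._lp_log_sigma(log_sigma))

    def _predictive_draws(self, X_mat, Z, ages, idx, rng):
        beta = self._flat_posterior("beta")[idx]
        u = self._flat_posterior("u")[idx]
        return beta @ X_mat.T + u @ Z.T

    def site_offset_summary(self):
        """Posterior mean and sd of each site's random intercept."""
        import pandas as pd
        self._check_fitted()
        u = self.posterior_["u"].reshape(-1, len(self.sites_))
        return pd.DataFrame({
            "site": self.sites_,
            "mean": u.mean(axis=0),
            "sd": u.std(axis=0, ddof=1),
        })
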