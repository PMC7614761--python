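"""Hierarchical Bayesian model with a Gaussian-process age trend.

The model is f = X beta + Z u + gamma(age) with gamma ~ GP(0, k) and the
squared-exponential kernel

    k(x, x') = sigma_f^2 * exp(-(x - x')^2 / (2 l^2)),

age in years, one lengthscale (the GP has a single input).  The latent trend
is marginalized in the likelihood, y ~ N(X beta + Z u, K + sigma^2 I), so the
sampler only walks over (beta, u, sigma, sigma_u, sigma_f, l); at prediction
time gamma* is drawn per retained draw from its exact Gaussian conditional
given the data and that draw's parameters (the Gaussian-conditional algebra
of the joint train/test covariance), so across-draw spread of f* carries the
full latent-trend uncertainty.

``gp_conditional_exact`` is the closed-form conditional at fixed
hyperparameters,

    mean* = k*^T (K + sigma^2 I)^-1 y
    var*  = k** - k*^T (K + sigma^2 I)^-1 k*,

and ``sample_gp_latent`` an MCMC route over the latent function values,
kept as an independent cross-check of the sampled predictions.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from ._sampling import group_chains, run_ensemble
from .base import BayesianNormativeRegression, _halfnormal_logpdf
from .linear import HierarchicalBayesianLinearModel

__all__ = ["se_kernel", "gp_conditional_exact", "sample_gp_latent",
           "HierarchicalBayesianGPModel"]


def se_kernel(x1, x2, sigma_f: float, lengthscale: float) -> np.ndarray:
    """Squared-exponential covariance over a single input (age, years)."""
    d = np.subtract.outer(np.asarray(x1, float), np.asarray(x2, float))
    return sigma_f ** 2 * np.exp(-0.5 * (d / lengthscale) ** 2)


def gp_conditional_exact(x_train, y_train, x_test, sigma: float,
                         sigma_f: float, lengthscale: float,
                         jitter: float = 1e-8):
    """Closed-form GP conditional at fixed (sigma, sigma_f, l).

    ``y_train`` are noisy observations of the zero-mean GP.  Returns
    (mean, var) per test point.  Serves as the oracle for sampled GP
    predictions.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    K = se_kernel(x_train, x_train, sigma_f, lengthscale)
    A = K + (sigma ** 2 + jitter) * np.eye(len(x_train))
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite kernel matrix")
    try:
        fac = cho_factor(A, lower=True)
    except LinAlgError as err:
        raise ValueError(
            "K + sigma^2 I is not positive definite after jitter") from err
    k_star = se_kernel(x_train, x_test, sigma_f, lengthscale)
    mean = k_star.T @ cho_solve(fac, y_train)
    var = sigma_f ** 2 - np.einsum(
        "ij,ij->j", k_star, cho_solve(fac, k_star))
    return mean, np.maximum(var, 0.0)


def sample_gp_latent(x_train, y_train, x_test, sigma: float, sigma_f: float,
                     lengthscale: float, warmup: int = 1500,
                     draws: int = 1500, n_walkers: int = 64, seed: int = 0,
                     jitter: float = 1e-8) -> dict:
    """MCMC over the latent GP values at fixed hyperparameters.

    Samples gamma (the latent function at the training inputs) from
    p(gamma | y) by ensemble MCMC, then projects each draw to the test
    inputs through the noise-free kernel conditional.  Returns a dict with
    ``cond_means`` of shape (chains, draws, n_test), the fixed conditional
    variance ``cond_var`` given gamma, and the closed-form reference.
    Intended for small n only.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    n = len(x_train)
    K = se_kernel(x_train, x_train, sigma_f, lengthscale)
    K[np.diag_indices_from(K)] += jitter
    # the SE prior is severely ill-conditioned in gamma; sample the whitened
    # coordinates xi with gamma = L xi so the prior is standard normal
    L = cholesky(K, lower=True)

    def log_post(xi):
        gamma = L @ xi
        return (-0.5 * xi @ xi
                - 0.5 * np.sum((y_train - gamma) ** 2) / sigma ** 2)

    # start near the whitened conditional mean of gamma given y
    m0 = K @ np.linalg.solve(K + sigma ** 2 * np.eye(n), y_train)
    xi0 = np.linalg.solve(L, m0)
    rng = np.random.default_rng(seed)
    p0 = xi0 + 0.1 * rng.standard_normal((n_walkers, n))
    chain, _ = run_ensemble(log_post, p0, warmup=warmup, draws=draws,
                            seed=seed + 1, thin=1)
    grouped = group_chains(chain, 4)                   # (4, d, n) whitened
    k_star = se_kernel(x_train, x_test, sigma_f, lengthscale)
    # k*^T K^-1 (L xi) = (L^-1 k*)^T xi, stable in the whitened coordinates
    W = np.linalg.solve(L, k_star)                     # (n, n_test)
    cond_means = grouped @ W                           # (4, d, n_test)
    cond_var = sigma_f ** 2 - np.einsum("ij,ij->j", W, W)
    exact_mean, exact_var = gp_conditional_exact(
        x_train, y_train, x_test, sigma, sigma_f, lengthscale, jitter)
    return {
        "cond_means": cond_means,
        "cond_var": np.maximum(cond_var, 0.0),
        "exact_mean": exact_mean,
        "exact_var": exact_var,
    }


class HierarchicalBayesianGPModel(HierarchicalBayesianLinearModel):
    """Site random intercepts plus a GP age trend (marginalized likelihood).

    Extra hyperparameters: sigma_f ~ HalfNormal(sigmaf_scale) and the
    lengthscale l ~ Uniform(lengthscale_bounds) in years.  Dense Cholesky per
    posterior evaluation: O(n^3), intended for cohorts of a few hundred.
    """

    _uses_site = True

    def __init__(self, draws=400, warmup=400, n_walkers=32, thin=2,
                 n_chains=4, beta_scale=5.0, sigma_scale=2.5,
                 sigmaf_scale=1.0, lengthscale_bounds=(1.0, 8.0),
                 jitter=1e-8, predict_draws=200, random_state=0):
        super().__init__(draws=draws, warmup=warmup, n_walkers=n_walkers,
                         thin=thin, n_chains=n_chains, beta_scale=beta_scale,
                         sigma_scale=sigma_scale,
                         predict_draws=predict_draws,
                         random_state=random_state)
        self.sigmaf_scale = sigmaf_scale
        self.lengthscale_bounds = lengthscale_bounds
        self.jitter = jitter

    def _param_blocks(self, q):
        return [("beta", 3), ("u", q), ("log_sigma", 1), ("log_sigma_u", 1),
                ("log_sigma_f", 1), ("lengthscale", 1)]

    def fit(self, X, y):
        out = super().fit(X, y)
        return out

    def _init_center(self):
        base = HierarchicalBayesianLinearModel._init_center(self)
        resid_sd = np.exp(base[-2])
        lo, hi = self.lengthscale_bounds
        return np.concatenate([
            base, [np.log(max(0.3 * resid_sd, 1e-2))], [(lo + hi) / 2.0]])

    def _log_post(self, theta):
        sl = self._slices
        beta = theta[sl["beta"]]
        u = theta[sl["u"]]
        log_sigma = theta[sl["log_sigma"]][0]
        log_sigma_u = theta[sl["log_sigma_u"]][0]
        log_sigma_f = theta[sl["log_sigma_f"]][0]
        ell = theta[sl["lengthscale"]][0]
        lo, hi = self.lengthscale_bounds
        if not lo <= ell <= hi:
            return -np.inf
        if abs(log_sigma) > 20 or abs(log_sigma_u) > 20 or log_sigma_f > 20:
            return -np.inf
        sigma = np.exp(log_sigma)
        sigma_f = np.exp(log_sigma_f)
        tr = self._train
        K = sigma_f ** 2 * self._expd(ell)
        A = K + (sigma ** 2 + self.jitter) * np.eye(len(tr["y"]))
        try:
            fac = cho_factor(A, lower=True, check_finite=False)
        except LinAlgError:
            return -np.inf
        resid = tr["y"] - tr["X"] @ beta - tr["Z"] @ u
        quad = resid @ cho_solve(fac, resid, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(fac[0])))
        loglik = -0.5 * (quad + logdet + len(resid) * np.log(2 * np.pi))
        lp = (self._lp_beta(beta) + self._lp_site(u, log_sigma_u)
              + self._lp_log_sigma(log_sigma)
              + _halfnormal_logpdf(sigma_f, self.sigmaf_scale) + log_sigma_f)
        return loglik + lp

    def _expd(self, ell):
        """exp(-D^2 / (2 l^2)) over training ages, D^2 cached at fit."""
        if "D2" not in self._train:
            ages = self._train["ages"]
            self._train["D2"] = np.subtract.outer(ages, ages) ** 2
        return np.exp(-0.5 * self._train["D2"] / ell ** 2)

    def _predictive_draws(self, X_mat, Z, ages, idx, rng):
        tr = self._train
        beta = self._flat_posterior("beta")[idx]
        u = self._flat_posterior("u")[idx]
        sigma = self._flat_posterior("sigma")[idx]
        sigma_f = self._flat_posterior("sigma_f")[idx]
        ell = self._flat_posterior("lengthscale")[idx]
        n, m = len(tr["y"]), len(ages)
        D2_cross = np.subtract.outer(tr["ages"], ages) ** 2
        D2_test = np.subtract.outer(ages, ages) ** 2
        eye_n = np.eye(n)
        out = np.empty((len(idx), m))
        for d in range(len(idx)):
            K = sigma_f[d] ** 2 * self._expd(ell[d])
            A = K + (sigma[d] ** 2 + self.jitter) * eye_n
            fac = cho_factor(A, lower=True, check_finite=False)
            k_star = sigma_f[d] ** 2 * np.exp(-0.5 * D2_cross / ell[d] ** 2)
            k_test = sigma_f[d] ** 2 * np.exp(-0.5 * D2_test / ell[d] ** 2)
            resid = tr["y"] - tr["X"] @ beta[d] - tr["Z"] @ u[d]
            solved = cho_solve(fac, k_star, check_finite=False)
            g_mean = solved.T @ resid
            g_cov = k_test - k_star.T @ solved
            g_cov[np.diag_indices_from(g_cov)] += self.jitter
            L = cholesky(g_cov, lower=True, check_finite=False)
            gamma_star = g_mean + L @ rng.standard_normal(m)
            out[d] = X_mat @ beta[d] + Z @ u[d] + gamma_star
        return out
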