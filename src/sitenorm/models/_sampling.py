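"""Ensemble-MCMC plumbing shared by the Bayesian regression estimators.

Sampling uses the affine-invariant ensemble sampler (emcee).  For
convergence reporting the walkers are grouped into a small number of
pseudo-chains; split-R-hat across interacting walkers is approximate but a
useful screen, and bulk ESS is computed the standard way (arviz).  Ensemble
moves have no divergence concept, so the report carries the mean acceptance
fraction instead.
"""

from __future__ import annotations

import warnings

import emcee
import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = ["run_ensemble", "group_chains", "convergence_report"]


def run_ensemble(log_prob, p0: np.ndarray, warmup: int, draws: int,
                 seed: int, thin: int = 1):
    """Run warmup then sampling; returns ((n_walkers, draws, ndim) chain,
    mean acceptance fraction).  Deterministic in (p0, seed)."""
    n_walkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    # emcee's random_state setter silently ignores anything that is not a
    # RandomState state tuple, so build the tuple explicitly
    rstate = np.random.RandomState(int(seed) % (2**31 - 1)).get_state()
    state = emcee.State(p0, random_state=rstate)
    state = sampler.run_mcmc(state, warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, draws, thin_by=thin, progress=False)
    chain = np.swapaxes(sampler.get_chain(), 0, 1)
    return chain, float(np.mean(sampler.acceptance_fraction))


def group_chains(chain: np.ndarray, n_chains: int = 4) -> np.ndarray:
    """Group walkers into pseudo-chains: (n_walkers, d, k) -> (c, g*d, k)."""
    n_walkers, n_draws, ndim = chain.shape
    n_chains = max(1, min(n_chains, n_walkers))
    g = n_walkers // n_chains
    return (chain[: g * n_chains]
            .reshape(n_chains, g, n_draws, ndim)
            .reshape(n_chains, g * n_draws, ndim))


def _flatten_params(posterior: dict) -> dict:
    flat = {}
    for name, arr in posterior.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            flat[name] = arr
        elif arr.ndim == 3:
            for k in range(arr.shape[2]):
                flat[f"{name}[{k}]"] = arr[:, :, k]
        else:
            raise ValueError(f"unexpected posterior shape for {name!r}")
    return flat


def convergence_report(posterior: dict, rhat_max: float = 1.01,
                       ess_min: float = 400.0,
                       acceptance: float | None = None) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per scalar parameter with a pass/warn verdict.

    ``posterior`` maps parameter names to (chain, draw[, k]) arrays.  With a
    single chain R-hat is undefined and reported as NaN (verdict based on ESS
    alone).
    """
    rows = []
    for name, arr in _flatten_params(posterior).items():
        n_chains = arr.shape[0]
        if arr.std() == 0:
            rhat, ess = 1.0, float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(arr)) if n_chains >= 2 else float("nan")
                ess = float(az.ess(arr))
        ok = (np.isnan(rhat) or rhat <= rhat_max) and (
            np.isnan(ess) or ess >= ess_min)
        rows.append((name, rhat, ess, "pass" if ok else "warn"))
    report = pd.DataFrame(rows, columns=["param", "rhat", "ess", "verdict"])
    report.attrs["acceptance_fraction"] = acceptance
    return report
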