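"""Save/load fitted normative models as plain text (draws CSV + JSON meta).

The draws file is a flat table with chain/draw bookkeeping columns and one
column per scalar parameter; the meta file records the estimator class, its
hyperparameters and the site registry.  The (standardized) training data are
stored alongside because GP predictions condition on them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import MODEL_REGISTRY
from .base import build_design

__all__ = ["save_model", "load_model"]

_CLASS_KEYS = {cls.__name__: key for key, cls in MODEL_REGISTRY.items()}


def save_model(model, outdir, stem: str = "model") -> None:
    model._check_fitted()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = {}
    shape0 = None
    for name, arr in model.posterior_.items():
        arr = np.asarray(arr)
        shape0 = arr.shape[:2]
        if arr.ndim == 2:
            rows[name] = arr.reshape(-1)
        else:
            for k in range(arr.shape[2]):
                rows[f"{name}[{k}]"] = arr[:, :, k].reshape(-1)
    n_chains, n_draws = shape0
    draws = pd.DataFrame(rows)
    draws.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
    draws.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
    draws.to_csv(outdir / f"{stem}_draws.csv", index=False)

    tr = model._train
    train = pd.DataFrame({"age": tr["X"][:, 1], "sex": tr["X"][:, 2],
                          "y": tr["y"]})
    if tr["Z"] is not None:
        train["site"] = [model.sites_[k] for k in tr["Z"].argmax(axis=1)]
    train.to_csv(outdir / f"{stem}_train.csv", index=False)

    meta = {
        "class": type(model).__name__,
        "params": model.get_params(),
        "sites": model.sites_,
        "n_obs": int(model.n_obs_),
        "n_chains": int(n_chains),
        "n_draws": int(n_draws),
        "acceptance_fraction": model.acceptance_fraction_,
        "block_sizes": {name: int(np.asarray(arr).shape[2])
                        if np.asarray(arr).ndim == 3 else 1
                        for name, arr in model.posterior_.items()},
    }
    with open(outdir / f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    model.convergence_.to_csv(outdir / f"{stem}_convergence.csv", index=False)


def load_model(outdir, stem: str = "model"):
    outdir = Path(outdir)
    with open(outdir / f"{stem}_meta.json") as fh:
        meta = json.load(fh)
    key = _CLASS_KEYS[meta["class"]]
    model = MODEL_REGISTRY[key](**meta["params"])
    draws = pd.read_csv(outdir / f"{stem}_draws.csv")
    n_chains, n_draws = meta["n_chains"], meta["n_draws"]
    posterior = {}
    for name, size in meta["block_sizes"].items():
        if size == 1:
            posterior[name] = draws[name].to_numpy().reshape(
                n_chains, n_draws)
        else:
            cols = [f"{name}[{k}]" for k in range(size)]
            posterior[name] = draws[cols].to_numpy().reshape(
                n_chains, n_draws, size)
    model.posterior_ = posterior
    model.sites_ = meta["sites"]
    model.n_obs_ = meta["n_obs"]
    model.acceptance_fraction_ = meta["acceptance_fraction"]
    model.convergence_ = pd.read_csv(outdir / f"{stem}_convergence.csv")

    train = pd.read_csv(outdir / f"{stem}_train.csv")
    X_mat, Z, _ = build_design(train, site_registry=meta["sites"]
                               if "site" in train.columns else None)
    model._train = {"X": X_mat, "Z": Z, "y": train["y"].to_numpy(),
                    "ages": train["age"].to_numpy(dtype=float)}
    return model
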