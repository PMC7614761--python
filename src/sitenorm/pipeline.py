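"""End-to-end normative-modeling pipelines and the model-comparison runner.

Two designs are supported:

* single-stage — fit a hierarchical Bayesian model (site as random effect)
  directly on the standardized training data;
* two-stage — first harmonize the measures for site (residualization or a
  ComBat variant, parameters estimated on training data only), then fit the
  simple Bayesian linear model without site.

Models are always trained on the control group; predictions and deviation
z-scores are produced for every test subject (clinical subjects included),
while performance metrics are computed on test controls.  Mean-accuracy
metrics (rho, SRMSE, EV) compare predictions with the values the model was
trained to predict (harmonized thickness for two-stage pipelines) on the mm
scale; the likelihood metrics (LL, MSLL) are computed on the standardized
scale; predictive-variance retention always uses the *original* (raw)
test-set variance in its denominator, which is what makes the shrinkage of
two-stage predictions visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import make_harmonizer
from .metrics import (explained_variance, msll, pearson_rho,
                      pointwise_loglik, srmse, variance_retention)
from .models import MODEL_REGISTRY, zscores
from .preprocess import SplitResult, Standardizer, stratified_split
from .tables import CorticalTable

__all__ = ["PipelineResult", "run_pipeline", "run_two_stage", "benchmark",
           "PIPELINES"]

# the six comparison pipelines: (model, harmonizer)
PIPELINES = {
    "hblm": ("hblm", None),
    "hbgpm": ("hbgpm", None),
    "raw": ("blm", "raw"),
    "residuals": ("blm", "residuals"),
    "combat": ("blm", "combat"),
    "combat_preserve": ("blm", "combat_preserve"),
}


@dataclass
class PipelineResult:
    """Predictions, deviation scores, fitted models and metrics for one
    pipeline on one split."""
    name: str
    regions: list
    predictions: pd.DataFrame      # tidy per (subject, region, split)
    metrics: pd.DataFrame          # per (region, split)
    models: dict = field(default_factory=dict)
    harmonizer: object | None = None
    standardizer: Standardizer | None = None

    def summary(self) -> pd.Series:
        """Test-set metrics averaged over regions."""
        test = self.metrics[self.metrics["split"] == "test"]
        return test.drop(columns=["region", "split"]).mean()


def _region_seed(seed: int, r: int) -> int:
    return int((int(seed) * 10007 + 131 * r + 17) % (2**31 - 1))


def run_pipeline(train: CorticalTable, test: CorticalTable,
                 model: str = "hblm", harmonizer: str | None = None,
                 regions: list | None = None, seed: int = 0,
                 sampler: dict | None = None,
                 name: str | None = None) -> PipelineResult:
    """Fit one pipeline on a train table and evaluate it on a test table."""
    if model not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model!r}")
    regions = list(regions) if regions is not None else list(train.regions)
    sampler = dict(sampler or {})

    controls = train.subset((train.data["group"] == "control").to_numpy())
    harm = None
    if harmonizer is not None:
        harm = make_harmonizer(harmonizer)
        harm.fit(controls)
        fit_train = harm.transform(controls)
        fit_test = harm.transform(test)
    else:
        fit_train, fit_test = controls, test

    std = Standardizer().fit(fit_train)
    train_std = std.transform(fit_train)
    test_std = std.transform(fit_test)

    rows, metric_rows, models = [], [], {}
    raw_test_controls = test.data["group"] == "control"
    for r, region in enumerate(regions):
        est = MODEL_REGISTRY[model](random_state=_region_seed(seed, r),
                                    **sampler)
        y_tr = train_std.data[region]
        keep = y_tr.notna().to_numpy()
        X_tr = train_std.covariates.loc[keep]
        est.fit(X_tr, y_tr[keep])
        models[region] = est

        loc, scale = std.location_[region], std.scale_[region]
        train_mean_std = float(y_tr[keep].mean())
        train_var_std = float(y_tr[keep].var(ddof=0))
        for split, raw_tab, std_tab in (("train", controls, train_std),
                                        ("test", test, test_std)):
            y_std = std_tab.data[region].to_numpy()
            ok = np.isfinite(y_std)
            pred = est.predict_dist(
                std_tab.covariates.assign(
                    subject_id=std_tab.data["subject_id"]))
            z = np.full(len(y_std), np.nan)
            dev = zscores(y_std[ok],
                          _subset_pred(pred, ok))
            z[ok] = dev.z
            rows.append(pd.DataFrame({
                "subject_id": std_tab.data["subject_id"],
                "region": region,
                "split": split,
                "group": std_tab.data["group"],
                "y": raw_tab.data[region].to_numpy(),
                "y_model": std_tab.data[region].to_numpy() * scale + loc,
                "pred_mean": pred.mean * scale + loc,
                "pred_sd": pred.total_sd * scale,
                "z": z,
            }))
            # metrics on controls of this split
            ctrl = ((std_tab.data["group"] == "control") & ok).to_numpy()
            y_mm_model = std_tab.data[region].to_numpy()[ctrl] * scale + loc
            y_mm_raw = raw_tab.data[region].to_numpy()[ctrl]
            mean_mm = pred.mean[ctrl] * scale + loc
            pred_std_ctrl = _subset_pred(pred, ctrl)
            metric_rows.append({
                "region": region, "split": split,
                "rho": pearson_rho(y_mm_model, mean_mm),
                "srmse": srmse(y_mm_model, mean_mm),
                "ev": explained_variance(y_mm_model, mean_mm),
                "ll": pointwise_loglik(y_std[ctrl], pred_std_ctrl),
                "msll": msll(y_std[ctrl], pred_std_ctrl,
                             train_mean_std, train_var_std),
                "variance_retention": variance_retention(
                    y_mm_raw, mean_mm),
            })
    predictions = pd.concat(rows, ignore_index=True)
    metrics = pd.DataFrame(metric_rows)
    return PipelineResult(
        name=name or (model if harmonizer is None
                      else f"{model}+{harmonizer}"),
        regions=regions, predictions=predictions, metrics=metrics,
        models=models, harmonizer=harm, standardizer=std)


def _subset_pred(pred, mask):
    from .models import PredictiveDistribution
    return PredictiveDistribution(
        mean=pred.mean[mask], epistemic_var=pred.epistemic_var[mask],
        noise_var=pred.noise_var,
        index=None if pred.index is None else pred.index[mask])


def run_two_stage(table: CorticalTable, harmonizer: str,
                  split: SplitResult | None = None, seed: int = 0,
                  regions=None, sampler=None) -> PipelineResult:
    """Two-stage convenience wrapper: harmonize (train-estimated parameters)
    then fit the simple Bayesian linear model.  ``harmonizer='raw'`` is the
    raw-data baseline (identity harmonization)."""
    if split is None:
        split = stratified_split(table, seed=seed)
    return run_pipeline(split.train, split.test, model="blm",
                        harmonizer=harmonizer, regions=regions, seed=seed,
                        sampler=sampler, name=harmonizer)


def benchmark(train: CorticalTable, test: CorticalTable,
              pipelines=("hblm", "hbgpm", "raw", "residuals", "combat",
                         "combat_preserve"),
              regions=None, seed: int = 0, sampler=None,
              gp_sampler=None) -> dict:
    """Run the model-comparison pipelines on one split.

    Returns {"results": {name: PipelineResult}, "summary": DataFrame} where
    the summary holds test-set metrics averaged over regions per pipeline.
    ``gp_sampler`` overrides sampler settings for the GP model (its draws are
    much more expensive).
    """
    results = {}
    for name in pipelines:
        if name not in PIPELINES:
            raise ValueError(f"unknown pipeline {name!r}")
        model, harmonizer = PIPELINES[name]
        cfg = gp_sampler if (model == "hbgpm" and gp_sampler) else sampler
        results[name] = run_pipeline(
            train, test, model=model, harmonizer=harmonizer,
            regions=regions, seed=seed, sampler=cfg, name=name)
    summary = pd.DataFrame({name: res.summary()
                            for name, res in results.items()}).T
    summary.index.name = "pipeline"
    return {"results": results, "summary": summary}
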