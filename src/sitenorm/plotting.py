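"""Small matplotlib helpers mirroring the package's standard figures."""

from __future__ import annotations

import numpy as np
import pandas as pd


def metric_distributions(metrics: dict, metric: str = "ev", ax=None):
    """Box plots of one metric across regions for several pipelines.

    ``metrics`` maps pipeline name -> per-region metrics DataFrame (the
    ``metrics`` attribute of a PipelineResult).
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(metrics) + 2, 3.5))
    names = list(metrics)
    data = [metrics[name].loc[metrics[name]["split"] == "test", metric]
            for name in names]
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=30)
    return ax


def site_forest(values, site, ax=None, label="value"):
    """Forest-style plot of per-site means with 95% intervals: site
    heterogeneity before/after correction."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float),
                          "site": np.asarray(site).astype(str)}).dropna()
    grouped = frame.groupby("site")["value"]
    mean = grouped.mean()
    half = 1.96 * grouped.std() / np.sqrt(grouped.size())
    ypos = np.arange(len(mean))
    ax.errorbar(mean, ypos, xerr=half, fmt="o", capsize=3)
    ax.axvline(frame["value"].mean(), ls="--", c="gray", lw=1)
    ax.set_yticks(ypos, mean.index)
    ax.set_xlabel(label)
    return ax


def prevalence_bars(per_region: pd.Series, threshold_pct: float = 5.0,
                    ax=None):
    """Bar chart of per-region atypicality prevalence with the nominal
    expectation marked."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(0.35 * len(per_region) + 2, 3.5))
    ax.bar(range(len(per_region)), per_region.to_numpy())
    ax.axhline(threshold_pct, ls="--", c="k", lw=1)
    ax.set_xticks(range(len(per_region)), per_region.index, rotation=90)
    ax.set_ylabel("% |z| > 1.96")
    return ax
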