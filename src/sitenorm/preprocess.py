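"""Preprocessing: outlier screening, hemisphere averaging, stratified
splitting and train-anchored standardization.

The outlier rule is deliberately liberal — it targets impossible values, not
distributional tails: a hemisphere-level value is discarded when it lies more
than ``k`` interquartile ranges (default 2) from the mean of *all* subjects
(control and clinical pooled) for that region and hemisphere.  Screening runs
on hemisphere-level values before averaging; a single-pass filter, so
re-application may remove further points because mean and IQR change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables import HEMISPHERES, CorticalTable, HemisphereTable

__all__ = [
    "remove_outliers", "average_hemispheres", "stratified_split",
    "SplitResult", "Standardizer", "fit_standardization",
    "apply_standardization",
]


def remove_outliers(table: HemisphereTable, k: float = 2.0):
    """Mask hemisphere-level values more than ``k`` IQRs from the stratum mean.

    Mean and IQR (linear-interpolation quartiles) are computed per
    (region, hemisphere) over all non-missing subjects.  Strata with fewer
    than 4 values pass through unfiltered and are flagged in the report.

    Returns
    -------
    (HemisphereTable, pandas.DataFrame)
        The filtered table and a per-stratum report with columns
        ``region, hemisphere, n, n_removed, fraction_removed, too_few``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    data = table.data.copy()
    rows = []
    for region in table.regions:
        for hemi in HEMISPHERES:
            col = table.column(region, hemi)
            values = data[col].to_numpy(dtype=float)
            present = np.isfinite(values)
            n = int(present.sum())
            if n < 4:
                rows.append((region, hemi, n, 0, 0.0, True))
                continue
            mean = values[present].mean()
            q1, q3 = np.percentile(values[present], [25, 75])
            iqr = q3 - q1
            with np.errstate(invalid="ignore"):
                out = present & (np.abs(values - mean) > k * iqr)
            data.loc[out, col] = np.nan
            rows.append((region, hemi, n, int(out.sum()),
                         float(out.sum()) / n, False))
    report = pd.DataFrame(
        rows, columns=["region", "hemisphere", "n", "n_removed",
                       "fraction_removed", "too_few"])
    return HemisphereTable(data, regions=table.regions), report


def average_hemispheres(table: HemisphereTable) -> CorticalTable:
    """Average left and right hemisphere per (subject, region).

    If one hemisphere is missing the remaining value is used; if both are
    missing the bilateral value is missing.
    """
    out = table.data[list(table.data.columns[:5])].copy()
    for region in table.regions:
        left = table.data[table.column(region, "left")]
        right = table.data[table.column(region, "right")]
        out[region] = pd.concat([left, right], axis=1).mean(
            axis=1, skipna=True)
    return CorticalTable(out, regions=table.regions)


@dataclass
class SplitResult:
    """A stratified train/test partition with its per-stratum accounting."""
    train: CorticalTable
    test: CorticalTable
    strata_report: pd.DataFrame
    singletons: list = field(default_factory=list)


def stratified_split(table: CorticalTable, train_fraction: float = 0.7,
                     seed: int = 0, age_bins: int = 4) -> SplitResult:
    """Split preserving the joint distribution of site, sex and (binned) age.

    Strata are site x sex x age-quantile-bin, with age bin edges computed on
    the full table.  Within each stratum the train share is within one subject
    of ``train_fraction``.  Singleton strata go to the train partition (so
    every site is represented in training), and are listed in the result.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    data = table.data
    site_counts = data["site"].value_counts()
    if (site_counts < 2).any():
        small = site_counts[site_counts < 2].index.tolist()
        raise ValueError(f"sites with fewer than 2 subjects: {small}")
    if data["age"].nunique() < 2:
        age_bin = pd.Series(0, index=data.index)
    else:
        age_bin = pd.qcut(data["age"], q=age_bins, duplicates="drop",
                          labels=False)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    rows = []
    singletons = []
    # within each site, strata get floor(share) and the leftover training
    # slots go to the largest fractional remainders, so the site-level train
    # count is within one subject of train_fraction * n_site
    for site, site_grp in data.groupby("site", sort=True):
        strata = list(site_grp.groupby(
            [site_grp["sex"], age_bin.loc[site_grp.index]], sort=True))
        sizes = np.array([len(grp) for _, grp in strata])
        exact = train_fraction * sizes
        base = np.floor(exact).astype(int)
        base[sizes == 1] = 1                      # singleton strata -> train
        site_total = int(np.floor(train_fraction * sizes.sum() + 0.5))
        remainder = exact - np.floor(exact)
        remainder[sizes == 1] = -1.0
        order = np.argsort(-remainder, kind="stable")
        for k in order:
            if base.sum() >= site_total:
                break
            if base[k] < sizes[k]:
                base[k] += 1
        if base.sum() == 0:                       # keep every site in train
            base[np.argmax(sizes)] = 1
        for (key, grp), n_train in zip(strata, base):
            idx = grp.index.to_numpy()
            rng.shuffle(idx)
            if len(idx) == 1:
                singletons.append(data.loc[idx[0], "subject_id"])
            train_idx.extend(idx[:n_train])
            rows.append((site, *key, len(idx), int(n_train),
                         len(idx) - int(n_train)))
    report = pd.DataFrame(
        rows, columns=["site", "sex", "age_bin", "n", "n_train", "n_test"])
    in_train = data.index.isin(train_idx)
    train = table.subset(in_train)
    test = table.subset(~in_train)
    return SplitResult(train=train, test=test, strata_report=report,
                       singletons=singletons)


class Standardizer(BaseEstimator):
    """Region-wise location/scale standardization anchored on training data.

    Location is the training mean and scale the training sample standard
    deviation (n-1 denominator), per region; test tables are transformed with
    the stored training parameters, never re-fit.
    """

    def fit(self, table: CorticalTable) -> "Standardizer":
        loc, scale = {}, {}
        for region in table.regions:
            values = table.data[region].dropna()
            if values.nunique() < 2:
                raise ValueError(
                    f"region {region!r}: need >=2 distinct training values")
            loc[region] = float(values.mean())
            scale[region] = float(values.std(ddof=1))
            if scale[region] <= 0:
                raise ValueError(f"region {region!r}: zero training scale")
        self.location_ = pd.Series(loc)
        self.scale_ = pd.Series(scale)
        self.regions_ = list(table.regions)
        return self

    def _check(self, table):
        if not hasattr(self, "location_"):
            raise RuntimeError("Standardizer is not fitted")
        unknown = set(table.regions) - set(self.regions_)
        if unknown:
            raise ValueError(f"regions not seen at fit time: {sorted(unknown)}")

    def transform(self, table: CorticalTable) -> CorticalTable:
        self._check(table)
        data = table.data.copy()
        for region in table.regions:
            data[region] = ((data[region] - self.location_[region])
                            / self.scale_[region])
        return CorticalTable(data, regions=table.regions, raw_scale=False)

    def inverse_transform(self, table) -> CorticalTable:
        self._check(table)
        data = table.data.copy()
        for region in table.regions:
            data[region] = (data[region] * self.scale_[region]
                            + self.location_[region])
        return CorticalTable(data, regions=table.regions)


def fit_standardization(train: CorticalTable) -> Standardizer:
    return Standardizer().fit(train)


def apply_standardization(table: CorticalTable,
                          params: Standardizer) -> CorticalTable:
    return params.transform(table)
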