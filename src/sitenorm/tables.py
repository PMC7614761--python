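"""Tabular containers for multi-site morphometry data.

Two thin wrappers around :class:`pandas.DataFrame` provide the package's
common currency:

``CorticalTable``
    one row per subject, phenotype columns (``subject_id``, ``age``, ``sex``,
    ``site``, ``group``) plus one column per region holding bilateral cortical
    thickness in millimetres.

``HemisphereTable``
    the same phenotypes, but measures held separately per hemisphere in
    columns named ``<region>__left`` / ``<region>__right``.

Both validate the invariants the modeling code relies on (unique subject ids,
positive ages, positive non-missing thickness values).
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHENO_COLS = ["subject_id", "age", "sex", "site", "group"]
HEMISPHERES = ("left", "right")
HEMI_SEP = "__"

_SEX_CODES = {
    "m": 1, "male": 1, "1": 1, "1.0": 1,
    "f": 0, "female": 0, "0": 0, "0.0": 0,
}


def normalize_sex(values: pd.Series) -> pd.Series:
    """Coerce a sex column to {0, 1} integers (1 = male, the reference level
    used throughout the package)."""
    def code(v):
        if isinstance(v, (int, np.integer, float, np.floating)) and v in (0, 1):
            return int(v)
        key = str(v).strip().lower()
        if key in _SEX_CODES:
            return _SEX_CODES[key]
        raise ValueError(f"unrecognized sex code: {v!r}")

    return values.map(code).astype(int)


def _check_phenotypes(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLS if c != "group" and c not in data.columns]
    if missing:
        raise ValueError(f"phenotype columns missing: {missing}")
    data = data.copy()
    if "group" not in data.columns:
        data["group"] = "control"
    data["subject_id"] = data["subject_id"].astype(str)
    if data["subject_id"].duplicated().any():
        dups = data.loc[data["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dups[:5]}")
    data["age"] = pd.to_numeric(data["age"])
    if not (data["age"] > 0).all():
        raise ValueError("all ages must be positive")
    data["sex"] = normalize_sex(data["sex"])
    data["site"] = data["site"].astype(str)
    data["group"] = data["group"].astype(str)
    bad_group = set(data["group"]) - {"control", "clinical"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    return data


class _BaseTable:
    def __init__(self, data: pd.DataFrame, regions: Sequence[str] | None = None,
                 raw_scale: bool = True):
        """``raw_scale=True`` enforces positive thickness (mm scale);
        standardized or residualized tables set it to False."""
        data = data.reset_index(drop=True)
        data = _check_phenotypes(data)
        if regions is None:
            measure_cols = [c for c in data.columns if c not in PHENO_COLS]
            regions = self._infer_regions(measure_cols)
        self.regions = list(regions)
        self.raw_scale = bool(raw_scale)
        if not self.regions:
            raise ValueError("table has no measure columns")
        for col in self._measure_columns():
            if col not in data.columns:
                data[col] = np.nan
            data[col] = pd.to_numeric(data[col])
            values = data[col].to_numpy()
            if self.raw_scale and np.any(values[np.isfinite(values)] <= 0):
                raise ValueError(f"non-positive thickness in column {col!r}")
        self.data = data[PHENO_COLS + self._measure_columns()]

    # subclasses define the mapping regions -> measure columns
    def _measure_columns(self) -> list[str]:
        raise NotImplementedError

    @staticmethod
    def _infer_regions(measure_cols: list[str]) -> list[str]:
        raise NotImplementedError

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    @property
    def phenotypes(self) -> pd.DataFrame:
        return self.data[PHENO_COLS]

    @property
    def covariates(self) -> pd.DataFrame:
        """age/sex/site frame in the layout the model estimators expect."""
        return self.data[["age", "sex", "site"]]

    @property
    def measures(self) -> pd.DataFrame:
        return self.data[self._measure_columns()]

    def subset(self, mask) -> "_BaseTable":
        return type(self)(self.data.loc[np.asarray(mask)],
                          regions=self.regions, raw_scale=self.raw_scale)

    def copy(self) -> "_BaseTable":
        return type(self)(self.data.copy(), regions=self.regions,
                          raw_scale=self.raw_scale)

    def with_measures(self, measures: pd.DataFrame,
                      raw_scale: bool | None = None) -> "_BaseTable":
        out = self.data.copy()
        out[self._measure_columns()] = measures[self._measure_columns()].to_numpy()
        if raw_scale is None:
            raw_scale = self.raw_scale
        return type(self)(out, regions=self.regions, raw_scale=raw_scale)

    def to_csv(self, path, sep=",") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, sep=None, raw_scale=True):
        df = pd.read_csv(path, sep=sep, engine="python")
        return cls(df, raw_scale=raw_scale)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (f"{type(self).__name__}(n={self.n_subjects}, "
                f"sites={len(self.sites)}, regions={len(self.regions)})")


class CorticalTable(_BaseTable):
    """Subject-level phenotypes plus bilateral (hemisphere-averaged) regional
    thickness, one column per region."""

    def _measure_columns(self) -> list[str]:
        return list(self.regions)

    @staticmethod
    def _infer_regions(measure_cols):
        return measure_cols

    def region_values(self, region: str) -> pd.Series:
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}")
        return self.data[region]


class HemisphereTable(_BaseTable):
    """Phenotypes plus per-hemisphere regional thickness in
    ``<region>__left`` / ``<region>__right`` columns."""

    def _measure_columns(self) -> list[str]:
        return [f"{r}{HEMI_SEP}{h}" for r in self.regions for h in HEMISPHERES]

    @staticmethod
    def _infer_regions(measure_cols):
        regions: list[str] = []
        for col in measure_cols:
            if HEMI_SEP not in col:
                raise ValueError(
                    f"hemisphere column {col!r} lacks the "
                    f"'<region>{HEMI_SEP}<hemisphere>' naming")
            region, hemi = col.rsplit(HEMI_SEP, 1)
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {hemi!r} in {col!r}")
            if region not in regions:
                regions.append(region)
        return regions

    def column(self, region: str, hemi: str) -> str:
        return f"{region}{HEMI_SEP}{hemi}"


def _measures_to_wide(measures: pd.DataFrame) -> pd.DataFrame:
    """Accept long- or wide-form measure tables and return wide form."""
    cols = set(measures.columns)
    if {"region", "value"} <= cols:
        index = ["subject_id"]
        columns = ["region", "hemisphere"] if "hemisphere" in cols else ["region"]
        wide = measures.pivot_table(index=index, columns=columns,
                                    values="value", aggfunc="first")
        if isinstance(wide.columns, pd.MultiIndex):
            wide.columns = [f"{r}{HEMI_SEP}{h}" for r, h in wide.columns]
        counts = measures.groupby(["subject_id"] + columns).size()
        if (counts > 1).any():
            raise ValueError("duplicate (subject, region[, hemisphere]) rows")
        return wide.reset_index()
    return measures


def read_cohort(phenotypes, measures, sep=None,
                hemispheres: bool | None = None):
    """Read and join a phenotype table and a measure table.

    Parameters
    ----------
    phenotypes, measures : path or file-like or DataFrame
        Delimited text (comma or tab, header row; missing as empty or NA) or
        pre-loaded frames.  Measures may be wide (one column per region or per
        ``region__hemisphere``) or long (``subject_id, region[, hemisphere],
        value``).
    hemispheres : bool, optional
        Force the output container type; inferred from the column naming when
        omitted.
    """
    def load(obj):
        if isinstance(obj, pd.DataFrame):
            return obj
        return pd.read_csv(obj, sep=sep, engine="python")

    pheno = load(phenotypes)
    wide = _measures_to_wide(load(measures))
    wide = wide.copy()
    wide["subject_id"] = wide["subject_id"].astype(str)
    pheno = pheno.copy()
    pheno["subject_id"] = pheno["subject_id"].astype(str)
    joined = pheno.merge(wide, on="subject_id", how="left", validate="1:1")
    measure_cols = [c for c in joined.columns if c not in PHENO_COLS]
    if hemispheres is None:
        hemispheres = any(HEMI_SEP in c for c in measure_cols)
    cls = HemisphereTable if hemispheres else CorticalTable
    return cls(joined)
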