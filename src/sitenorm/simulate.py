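"""Synthetic multi-site cortical-thickness cohorts.

The generator mirrors the generative assumptions of the hierarchical models:
for subject ``i`` at site ``s`` and region ``r``

    y_ir = b0_r + b_age * age_i + b_sex * sex_i + u_sr + g_r(age_i)
           + scale_s * eps_i,      eps_i ~ N(0, noise_sd^2)

with additive site offsets ``u_sr`` (either supplied or drawn from
``N(0, site_offset_sd^2)``), multiplicative per-site noise scales, and an
optional smooth non-linear age trend ``g_r`` drawn once per region from a
zero-mean Gaussian process with squared-exponential covariance
(``gp_amplitude``, ``gp_lengthscale``).  Ages are uniform within each site's
window, which lets site be confounded with age (staggered windows), the
situation multi-site pooling creates in practice.

The default configuration is a 6-site cohort of 600 subjects with staggered
age windows spanning 6-40 years, ~80% male, site offset sd 0.2 mm, noise sd
0.15 mm and a linear age slope of -0.02 mm/yr — a cohort drawn from the
hierarchical linear model's own generative process.  What the generator does
not emulate: cross-region residual correlation, scanner drift within site,
non-Gaussian noise, and site-by-age interaction beyond the window confound.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CorticalTable

__all__ = [
    "CohortConfig", "GenerativeTruth", "simulate_cohort",
    "make_clinical_overlay", "default_config", "confounded_config",
    "abide_like_config",
]

_DEFAULT_WINDOWS = ((6, 16), (10, 22), (14, 26), (18, 30), (22, 34), (26, 40))


@dataclass
class CohortConfig:
    """Ground-truth parameters of a synthetic multi-site cohort.

    Units: thickness in mm, ages in years; ``beta`` is (intercept at age 0,
    age slope per year, male offset); sex coded 1 = male.
    """
    n_sites: int = 6
    site_sizes: tuple = (100,) * 6
    site_age_windows: tuple = _DEFAULT_WINDOWS
    male_fraction: float | tuple = 0.8
    beta: tuple = (3.0, -0.02, 0.1)
    n_regions: int = 5
    region_intercept_sd: float = 0.15
    site_offset_sd: float = 0.2
    site_offsets: tuple | None = None      # (n_sites,) or (n_sites, n_regions)
    site_scales: tuple | None = None       # per-site, default all 1.0
    gp_amplitude: float = 0.0              # signal sd of the smooth age trend
    gp_lengthscale: float = 5.0            # years
    noise_sd: float = 0.15
    clinical_fraction: float = 0.0
    clinical_shift: float = 0.0
    clinical_regions: tuple | None = None  # default: all regions
    seed: int = 0

    def __post_init__(self):
        if len(self.site_sizes) != self.n_sites:
            raise ValueError("site_sizes length must equal n_sites")
        if len(self.site_age_windows) != self.n_sites:
            raise ValueError("site_age_windows length must equal n_sites")
        if any(n < 1 for n in self.site_sizes):
            raise ValueError("every site must have at least one subject")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.site_scales is not None:
            if len(self.site_scales) != self.n_sites:
                raise ValueError("site_scales length must equal n_sites")
            if any(s <= 0 for s in self.site_scales):
                raise ValueError("site scales must be positive")
        if self.gp_amplitude < 0 or self.gp_lengthscale <= 0:
            raise ValueError("invalid GP trend parameters")

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("site_sizes", "site_age_windows", "beta", "site_offsets",
                    "site_scales", "clinical_regions", "male_fraction"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key])
        return cls(**raw)


@dataclass
class GenerativeTruth:
    """Realized ground-truth record, reproducible from (config, seed)."""
    beta: np.ndarray                  # (3,) shared fixed effects
    region_intercepts: np.ndarray     # (n_regions,)
    site_offsets: np.ndarray          # (n_sites, n_regions)
    site_scales: np.ndarray           # (n_sites,)
    noise_sd: float
    gp_amplitude: float
    gp_lengthscale: float
    sites: list
    regions: list
    f_noiseless: pd.DataFrame         # per-subject noiseless signal per region
    config: CohortConfig

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "region_intercepts": self.region_intercepts.tolist(),
            "site_offsets": self.site_offsets.tolist(),
            "site_scales": self.site_scales.tolist(),
            "noise_sd": self.noise_sd,
            "gp_amplitude": self.gp_amplitude,
            "gp_lengthscale": self.gp_lengthscale,
            "sites": self.sites,
            "regions": self.regions,
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _se_kernel(x1, x2, amplitude, lengthscale):
    d = np.subtract.outer(np.asarray(x1, float), np.asarray(x2, float))
    return amplitude ** 2 * np.exp(-0.5 * (d / lengthscale) ** 2)


def _draw_gp_trend(ages, amplitude, lengthscale, rng, grid_size=101,
                   jitter=1e-8):
    """One smooth age trend, realized on a dense grid and interpolated."""
    lo, hi = float(np.min(ages)), float(np.max(ages))
    grid = np.linspace(lo - 1e-6, hi + 1e-6, grid_size)
    cov = _se_kernel(grid, grid, amplitude, lengthscale)
    cov[np.diag_indices_from(cov)] += jitter
    trend = np.linalg.cholesky(cov) @ rng.standard_normal(grid_size)
    return np.interp(ages, grid, trend)


def simulate_cohort(config: CohortConfig):
    """Draw one cohort; identical (config, seed) gives identical output.

    Returns ``(CorticalTable, GenerativeTruth)``.  When
    ``config.clinical_fraction > 0`` the clinical overlay is applied on top
    (see :func:`make_clinical_overlay`).
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    sites = [f"site{idx + 1:02d}" for idx in range(n_sites)]
    regions = [f"region{idx + 1:02d}" for idx in range(config.n_regions)]
    n_total = int(sum(config.site_sizes))

    male_frac = config.male_fraction
    if np.isscalar(male_frac):
        male_frac = (float(male_frac),) * n_sites

    ages = np.empty(n_total)
    sexes = np.empty(n_total, dtype=int)
    site_idx = np.empty(n_total, dtype=int)
    pos = 0
    for s, (n_s, (lo, hi)) in enumerate(
            zip(config.site_sizes, config.site_age_windows)):
        sl = slice(pos, pos + n_s)
        ages[sl] = rng.uniform(lo, hi, n_s)
        sexes[sl] = rng.random(n_s) < male_frac[s]
        site_idx[sl] = s
        pos += n_s

    beta = np.asarray(config.beta, dtype=float)
    intercepts = beta[0] + config.region_intercept_sd * rng.standard_normal(
        config.n_regions)
    if config.site_offsets is not None:
        offsets = np.asarray(config.site_offsets, dtype=float)
        if offsets.ndim == 1:
            offsets = np.repeat(offsets[:, None], config.n_regions, axis=1)
    else:
        offsets = config.site_offset_sd * rng.standard_normal(
            (n_sites, config.n_regions))
    scales = (np.ones(n_sites) if config.site_scales is None
              else np.asarray(config.site_scales, dtype=float))

    fixed = beta[1] * ages + beta[2] * sexes
    f = np.empty((n_total, config.n_regions))
    for r in range(config.n_regions):
        f[:, r] = intercepts[r] + fixed + offsets[site_idx, r]
        if config.gp_amplitude > 0:
            f[:, r] += _draw_gp_trend(ages, config.gp_amplitude,
                                      config.gp_lengthscale, rng)
    noise = (scales[site_idx, None] * config.noise_sd
             * rng.standard_normal((n_total, config.n_regions)))
    y = f + noise

    data = pd.DataFrame({
        "subject_id": [f"sub{idx + 1:04d}" for idx in range(n_total)],
        "age": ages,
        "sex": sexes,
        "site": [sites[s] for s in site_idx],
        "group": "control",
    })
    for r, region in enumerate(regions):
        data[region] = y[:, r]

    truth = GenerativeTruth(
        beta=beta, region_intercepts=intercepts, site_offsets=offsets,
        site_scales=scales, noise_sd=config.noise_sd,
        gp_amplitude=config.gp_amplitude,
        gp_lengthscale=config.gp_lengthscale, sites=sites, regions=regions,
        f_noiseless=pd.DataFrame(f, columns=regions,
                                 index=data["subject_id"]),
        config=config)
    table = CorticalTable(data, regions=regions)
    if config.clinical_fraction > 0:
        table = make_clinical_overlay(table, config)
    return table, truth


def make_clinical_overlay(table: CorticalTable,
                          config: CohortConfig) -> CorticalTable:
    """Flag a random fraction of subjects as clinical and shift their values.

    ``clinical_shift`` (mm) is added to ``clinical_regions`` (all regions by
    default) for the flagged subjects; the overlay draw is seeded from
    ``config.seed`` so the cohort stays reproducible.
    """
    if config.clinical_fraction <= 0:
        raise ValueError("clinical_fraction must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, 0x5EED)))
    data = table.data.copy()
    flagged = rng.random(len(data)) < config.clinical_fraction
    regions = (list(config.clinical_regions)
               if config.clinical_regions is not None else list(table.regions))
    unknown = set(regions) - set(table.regions)
    if unknown:
        raise ValueError(f"unknown clinical regions: {sorted(unknown)}")
    data.loc[flagged, "group"] = "clinical"
    for region in regions:
        data.loc[flagged, region] += config.clinical_shift
    return CorticalTable(data, regions=table.regions,
                         raw_scale=table.raw_scale)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The reference 6-site/600-subject cohort from the hierarchical linear
    model's own generative process."""
    return CohortConfig(seed=seed, **overrides)


def confounded_config(seed: int = 0, **overrides) -> CohortConfig:
    """Site-age-confounded cohort with additive and multiplicative site
    effects, for harmonization comparisons: staggered age windows plus
    per-site noise scales spanning 0.8-1.25."""
    params = dict(
        site_offset_sd=0.25,
        site_scales=(0.8, 0.9, 1.0, 1.0, 1.1, 1.25),
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


# Demographic skeleton at the scale of large public multi-site releases:
# 20 sites of unequal size (13-105), site-specific age windows within 6-40
# years and mostly-male samples.
_LARGE_SITES = (
    (15, (17, 39), 0.73), (13, (20, 40), 0.77), (33, (8, 12), 0.73),
    (15, (18, 29), 1.00), (20, (12, 16), 0.75), (30, (7, 35), 0.90),
    (105, (6, 31), 0.75), (15, (8, 12), 1.00), (16, (10, 23), 0.875),
    (27, (9, 33), 0.85), (13, (20, 39), 1.00), (22, (8, 16), 0.73),
    (20, (7, 12), 0.80), (25, (12, 25), 1.00), (32, (9, 17), 0.88),
    (13, (9, 13), 0.85), (54, (8, 19), 0.69), (21, (13, 28), 0.95),
    (43, (8, 39), 1.00), (28, (7, 17), 0.71),
)


def abide_like_config(seed: int = 0, n_regions: int = 35,
                      **overrides) -> CohortConfig:
    """A 20-site, 560-subject configuration mirroring the unequal site sizes,
    staggered age windows and ~80% male composition of pooled autism
    consortium data, with 34 bilateral regions plus mean thickness."""
    sizes, windows, males = zip(*[(n, w, m) for n, w, m in _LARGE_SITES])
    params = dict(
        n_sites=len(sizes), site_sizes=sizes, site_age_windows=windows,
        male_fraction=males, n_regions=n_regions,
        site_scales=tuple(np.round(np.linspace(0.85, 1.2, len(sizes)), 3)),
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)
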