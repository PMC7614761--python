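import warnings

import numpy as np
import pandas as pd
import pytest

from sitenorm.models import HierarchicalBayesianLinearModel
from sitenorm.preprocess import stratified_split
from sitenorm.simulate import CohortConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)

# reduced sampler settings used throughout the suite (documented test config)
FAST = dict(draws=400, warmup=400, thin=1)
FAST_GP = dict(draws=200, warmup=200, thin=1)


@pytest.fixture(scope="session")
def small_cohort():
    """6 sites x 50 subjects, 3 regions, staggered age windows."""
    cfg = CohortConfig(site_sizes=(50,) * 6, n_regions=3, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    table, _ = small_cohort
    return stratified_split(table, seed=42)


@pytest.fixture(scope="session")
def fitted_hblm(small_cohort):
    """HBLM fitted (fast settings) to one region of the small cohort."""
    table, truth = small_cohort
    model = HierarchicalBayesianLinearModel(random_state=7, **FAST)
    model.fit(table.covariates, table.data["region01"])
    return model, table, truth


@pytest.fixture
def hemi_frame():
    """Small hemisphere-level table builder."""
    def build(values_left, values_right, region="region01"):
        n = len(values_left)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": np.linspace(8, 30, n),
            "sex": [i % 2 for i in range(n)],
            "site": ["siteA" if i < n // 2 else "siteB" for i in range(n)],
            "group": "control",
            f"{region}__left": values_left,
            f"{region}__right": values_right,
        })
    return build
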