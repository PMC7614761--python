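import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitenorm.preprocess import (Standardizer, average_hemispheres,
                                 fit_standardization, remove_outliers,
                                 stratified_split)
from sitenorm.tables import CorticalTable, HemisphereTable


def hemi_table(left, right, region="region01"):
    n = len(left)
    return HemisphereTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": np.linspace(8, 30, n),
        "sex": [i % 2 for i in range(n)],
        "site": ["a"] * (n // 2) + ["b"] * (n - n // 2),
        "group": "control",
        f"{region}__left": left,
        f"{region}__right": right,
    }))


def cortical(values, sites=None, ages=None, sexes=None):
    n = len(values)
    return CorticalTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": ages if ages is not None else np.linspace(8, 30, n),
        "sex": sexes if sexes is not None else [i % 2 for i in range(n)],
        "site": sites if sites is not None else ["a"] * n,
        "group": "control",
        "region01": values,
    }), raw_scale=False)


class TestOutlierRemoval:
    def test_identical_values_no_removals(self):
        table, report = remove_outliers(hemi_table([2.5] * 10, [2.5] * 10))
        assert report["n_removed"].sum() == 0

    def test_value_beyond_two_iqr_removed(self):
        # left hemisphere: 1..20 plus 100; mean 14.76, IQR 10 -> only the
        # 100 exceeds 2 IQR from the mean
        left = list(np.arange(1.0, 21.0)) + [100.0]
        right = [2.5] * 21
        table, report = remove_outliers(hemi_table(left, right))
        col = table.column("region01", "left")
        assert np.isnan(table.data[col].iloc[-1])
        assert table.data[col].iloc[:-1].notna().all()
        row = report.set_index(["region", "hemisphere"]).loc[
            ("region01", "left")]
        assert row["n_removed"] == 1
        assert row["fraction_removed"] == pytest.approx(1 / 21)

    def test_degenerate_iqr_removes_everything_off_mean(self):
        # {1.0 x20, 10.0}: IQR is 0, so the rule flags every value that
        # differs from the mean — including the 10.0
        left = [1.0] * 20 + [10.0]
        table, report = remove_outliers(hemi_table(left, [2.5] * 21))
        col = table.column("region01", "left")
        assert np.isnan(table.data[col].iloc[-1])
        assert report.set_index(["region", "hemisphere"]).loc[
            ("region01", "left"), "n_removed"] == 21

    def test_infinite_k_removes_nothing(self):
        left = list(np.arange(1.0, 21.0)) + [1000.0]
        table, report = remove_outliers(hemi_table(left, [2.5] * 21),
                                        k=np.inf)
        assert report["n_removed"].sum() == 0

    def test_small_stratum_passes_through_with_flag(self):
        left = [2.5, 2.6, np.nan] + [np.nan] * 3
        table, report = remove_outliers(hemi_table(left, [2.5] * 6))
        row = report.set_index(["region", "hemisphere"]).loc[
            ("region01", "left")]
        assert bool(row["too_few"])
        assert row["n_removed"] == 0

    def test_not_idempotent_by_contract(self):
        # removing the extreme point shrinks mean and IQR enough that a
        # second pass flags a point the first pass kept
        left = list(np.linspace(1, 2, 20)) + [2.65, 7.0]
        first, rep1 = remove_outliers(hemi_table(left, [2.5] * 22))
        second, rep2 = remove_outliers(first)
        n1 = rep1.set_index(["region", "hemisphere"]).loc[
            ("region01", "left"), "n_removed"]
        n2 = rep2.set_index(["region", "hemisphere"]).loc[
            ("region01", "left"), "n_removed"]
        assert n1 == 1 and n2 >= 1


class TestHemisphereAveraging:
    def test_both_one_and_none_present(self):
        table = average_hemispheres(
            hemi_table([2.4, 2.4, np.nan, np.nan],
                       [2.6, np.nan, 2.6, np.nan]))
        values = table.data["region01"]
        assert values.iloc[0] == pytest.approx(2.5)
        assert values.iloc[1] == pytest.approx(2.4)
        assert values.iloc[2] == pytest.approx(2.6)
        assert np.isnan(values.iloc[3])


class TestStratifiedSplit:
    def test_exact_split_single_stratum(self):
        # one site, one sex, constant age -> a single stratum of 10
        table = cortical(np.linspace(2, 3, 10), sites=["a"] * 10,
                         ages=[20.0] * 10, sexes=[1] * 10)
        split = stratified_split(table, train_fraction=0.7, seed=0)
        assert len(split.train) == 7 and len(split.test) == 3

    def test_two_sites_contribute_proportionally(self):
        table = cortical(np.linspace(2, 3, 20),
                         sites=["a"] * 10 + ["b"] * 10,
                         ages=[20.0] * 20, sexes=[1] * 20)
        split = stratified_split(table, train_fraction=0.7, seed=1)
        counts = split.train.data["site"].value_counts()
        assert counts["a"] == 7 and counts["b"] == 7

    def test_deterministic_given_seed(self, small_cohort):
        table, _ = small_cohort
        a = stratified_split(table, seed=5)
        b = stratified_split(table, seed=5)
        pd.testing.assert_frame_equal(a.train.data, b.train.data)
        pd.testing.assert_frame_equal(a.test.data, b.test.data)

    def test_partition_is_exact_and_disjoint(self, small_split):
        train_ids = set(small_split.train.data["subject_id"])
        test_ids = set(small_split.test.data["subject_id"])
        assert not train_ids & test_ids
        assert len(train_ids) + len(test_ids) == 600 // 2

    def test_per_site_share_within_one_subject_over_seeds(self, small_cohort):
        table, _ = small_cohort
        site_n = table.data["site"].value_counts()
        for seed in range(200):
            split = stratified_split(table, seed=seed)
            share = split.train.data["site"].value_counts() / site_n
            assert (np.abs(share - 0.7) <= 1 / site_n + 1e-12).all()

    def test_singleton_stratum_goes_to_train(self):
        table = cortical([2.5, 2.6, 2.7, 2.4, 2.3],
                         sites=["a", "a", "a", "a", "b"],
                         ages=[20.0] * 5, sexes=[1, 1, 1, 1, 0])
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(table, seed=0)
        table = cortical([2.5, 2.6, 2.7, 2.4, 2.3, 2.2],
                         sites=["a", "a", "a", "a", "b", "b"],
                         ages=[20.0] * 6, sexes=[1, 1, 1, 1, 0, 1])
        split = stratified_split(table, seed=0)
        # both site-b subjects are singleton (site, sex) strata
        assert set(split.singletons) == {"s4", "s5"}
        assert {"s4", "s5"} <= set(split.train.data["subject_id"])


class TestStandardization:
    def test_train_becomes_mean_zero_unit_sd(self, small_cohort):
        table, _ = small_cohort
        std = fit_standardization(table)
        out = std.transform(table)
        for region in table.regions:
            assert out.data[region].mean() == pytest.approx(0, abs=1e-12)
            assert out.data[region].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_two_point_example(self):
        table = cortical([2.0, 4.0], sites=["a", "a"])
        std = Standardizer().fit(table)
        out = std.transform(table)
        assert std.location_["region01"] == pytest.approx(3.0)
        assert std.scale_["region01"] == pytest.approx(np.sqrt(2.0))
        np.testing.assert_allclose(out.data["region01"],
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_shifted_copy_mean_is_shift_over_scale(self, small_cohort):
        table, _ = small_cohort
        std = Standardizer().fit(table)
        shifted = table.data.copy()
        shifted[table.regions] += 0.25
        out = std.transform(CorticalTable(shifted, regions=table.regions))
        for region in table.regions:
            assert out.data[region].mean() == pytest.approx(
                0.25 / std.scale_[region], rel=1e-10)

    def test_apply_uses_train_params_not_refit(self, small_split):
        std = Standardizer().fit(small_split.train)
        out = std.transform(small_split.test)
        # test mean is near but not exactly 0: train parameters were reused
        region = small_split.train.regions[0]
        assert out.data[region].mean() != pytest.approx(0, abs=1e-6)

    def test_constant_region_raises_with_region_name(self):
        table = cortical([2.5] * 6)
        with pytest.raises(ValueError, match="region01"):
            Standardizer().fit(table)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.5, max_value=5.0), min_size=4,
                    max_size=30).filter(lambda v: np.std(v) > 1e-3))
    def test_round_trip_property(self, values):
        table = cortical(np.asarray(values))
        std = Standardizer().fit(table)
        back = std.inverse_transform(std.transform(table))
        np.testing.assert_allclose(back.data["region01"],
                                   table.data["region01"], rtol=1e-10)
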