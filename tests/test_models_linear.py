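import numpy as np
import pandas as pd
import pytest

from sitenorm.models import (BayesianLinearModel,
                             HierarchicalBayesianLinearModel,
                             PredictiveDistribution, build_design,
                             convergence_report, zscores)
from sitenorm.simulate import CohortConfig, simulate_cohort

from conftest import FAST


def covariate_frame(age, sex, site=None):
    frame = pd.DataFrame({"age": age, "sex": sex})
    if site is not None:
        frame["site"] = site
    return frame


class TestDesign:
    def test_two_sites_unit_row_sums(self):
        X, Z, sites = build_design(covariate_frame(
            [10, 20, 30], [0, 1, 0], ["a", "b", "a"]))
        assert X.shape == (3, 3) and Z.shape == (3, 2)
        np.testing.assert_array_equal(Z.sum(axis=1), [1, 1, 1])
        np.testing.assert_array_equal(X[:, 0], [1, 1, 1])
        assert sites == ["a", "b"]

    def test_duplicate_rows_stay_duplicated(self):
        X, Z, _ = build_design(covariate_frame(
            [10, 10], [1, 1], ["a", "a"]))
        np.testing.assert_array_equal(X[0], X[1])
        np.testing.assert_array_equal(Z[0], Z[1])

    def test_single_site_is_all_ones_column(self):
        _, Z, _ = build_design(covariate_frame([10, 20], [0, 1], ["a", "a"]))
        np.testing.assert_array_equal(Z, [[1.0], [1.0]])

    def test_unknown_site_at_predict_time_raises(self):
        with pytest.raises(ValueError, match="unknown site"):
            build_design(covariate_frame([10], [0], ["c"]),
                         site_registry=["a", "b"])

    def test_missing_covariate_raises(self):
        with pytest.raises(ValueError, match="age"):
            build_design(pd.DataFrame({"sex": [0, 1]}))


class TestBayesianLinearModel:
    def test_noiseless_data_recovers_beta(self):
        rng = np.random.default_rng(0)
        X = covariate_frame(rng.uniform(6, 40, 200), rng.integers(0, 2, 200))
        y = 3.0 - 0.02 * X["age"] + 0.1 * X["sex"]
        model = BayesianLinearModel(random_state=0, **FAST).fit(X, y)
        beta = model.posterior_["beta"].reshape(-1, 3).mean(axis=0)
        np.testing.assert_allclose(beta, [3.0, -0.02, 0.1], atol=1e-2)
        assert model.posterior_["sigma"].mean() < 1e-3

    def test_permuting_subjects_gives_identical_posterior(self):
        rng = np.random.default_rng(1)
        X = covariate_frame(rng.uniform(6, 40, 100), rng.integers(0, 2, 100))
        y = 3.0 - 0.02 * X["age"] + 0.15 * rng.standard_normal(100)
        a = BayesianLinearModel(random_state=3, **FAST).fit(X, y)
        perm = rng.permutation(100)
        b = BayesianLinearModel(random_state=3, **FAST).fit(
            X.iloc[perm].reset_index(drop=True), y.iloc[perm])
        # the log-posterior is exchangeable, so the posteriors agree up to
        # Monte Carlo error (summation order perturbs the trajectories)
        mean_a = a.posterior_["beta"].reshape(-1, 3).mean(axis=0)
        mean_b = b.posterior_["beta"].reshape(-1, 3).mean(axis=0)
        sd = a.posterior_["beta"].reshape(-1, 3).std(axis=0, ddof=1)
        assert np.all(np.abs(mean_a - mean_b) < 0.25 * sd)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = covariate_frame(rng.uniform(6, 40, 80), rng.integers(0, 2, 80))
        y = 2.8 - 0.02 * X["age"] + 0.1 * rng.standard_normal(80)
        a = BayesianLinearModel(random_state=11, **FAST).fit(X, y)
        b = BayesianLinearModel(random_state=11, **FAST).fit(X, y)
        np.testing.assert_array_equal(a.posterior_["beta"],
                                      b.posterior_["beta"])

    def test_credible_interval_coverage_near_nominal(self):
        """95% CIs on (beta, sigma) cover the truth at ~nominal frequency."""
        hits, total = 0, 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            X = covariate_frame(rng.uniform(6, 40, n),
                                rng.integers(0, 2, n))
            y = (0.0 - 0.02 * X["age"] + 0.1 * X["sex"]
                 + 0.1 * rng.standard_normal(n))
            m = BayesianLinearModel(random_state=seed, **FAST).fit(X, y)
            flat = m.posterior_["beta"].reshape(-1, 3)
            for j, truth in enumerate([0.0, -0.02, 0.1]):
                lo, hi = np.percentile(flat[:, j], [2.5, 97.5])
                hits += lo <= truth <= hi
                total += 1
            lo, hi = np.percentile(m.posterior_["sigma"].ravel(),
                                   [2.5, 97.5])
            hits += lo <= 0.1 <= hi
            total += 1
        # 100 binary checks at nominal 95%: binomial 99.9% band >= 0.86
        assert hits / total >= 0.86


class TestHierarchicalModel:
    def test_single_site_raises_towards_blm(self, small_cohort):
        table, _ = small_cohort
        one = table.subset(table.data["site"] == "site01")
        model = HierarchicalBayesianLinearModel(**FAST)
        with pytest.raises(ValueError, match="BayesianLinearModel"):
            model.fit(one.covariates, one.data["region01"])

    def test_planted_offsets_recovered_within_two_sd(self, fitted_hblm):
        model, table, truth = fitted_hblm
        u = model.posterior_["u"].reshape(-1, len(model.sites_))
        beta = model.posterior_["beta"].reshape(-1, 3)
        for s in range(len(model.sites_)):
            err = abs(u[:, s].mean() - truth.site_offsets[s, 0])
            assert err <= 2 * u[:, s].std(ddof=1)
        assert abs(beta[:, 1].mean() - truth.beta[1]) <= \
            2 * beta[:, 1].std(ddof=1)

    def test_null_offsets_stay_small(self):
        # common age windows: with staggered windows site is collinear with
        # age and the offsets are legitimately more uncertain
        cfg = CohortConfig(site_offsets=(0.0,) * 6, n_regions=1,
                           site_age_windows=((6, 40),) * 6,
                           region_intercept_sd=0.0, seed=21)
        table, _ = simulate_cohort(cfg)
        m = HierarchicalBayesianLinearModel(random_state=21, **FAST).fit(
            table.covariates, table.data["region01"])
        u = m.posterior_["u"].reshape(-1, 6).mean(axis=0)
        u = u - u.mean()
        # centered offsets bounded by a few likelihood standard errors
        # (sigma/sqrt(n_site) = 0.15/10)
        assert np.max(np.abs(u)) < 4 * 0.15 / np.sqrt(100)

    def test_partial_pooling_shrinkage_monotone_in_site_size(self):
        cfg = CohortConfig(n_sites=6, site_sizes=(6, 6, 30, 30, 200, 200),
                           site_age_windows=((6, 40),) * 6,
                           site_offsets=(0.3, -0.3, 0.3, -0.3, 0.3, -0.3),
                           noise_sd=0.15, n_regions=1,
                           region_intercept_sd=0.0, seed=5)
        table, _ = simulate_cohort(cfg)
        y = table.data["region01"].to_numpy()
        y_std = (y - y.mean()) / y.std(ddof=1)
        m = HierarchicalBayesianLinearModel(random_state=2, **FAST).fit(
            table.covariates, y_std)
        X = np.column_stack([np.ones(len(y)), table.data["age"],
                             table.data["sex"]])
        Z = pd.get_dummies(table.data["site"]).to_numpy(float)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([X, Z[:, 1:]]), y_std, rcond=None)
        u_ols = np.concatenate([[0.0], coef[3:]])
        u_ols -= u_ols.mean()
        u_post = m.posterior_["u"].reshape(-1, 6).mean(axis=0)
        u_post -= u_post.mean()
        shrink = np.abs(u_ols - u_post).reshape(3, 2).mean(axis=1)
        assert shrink[0] > shrink[1] > shrink[2]

    def test_strong_signal_training_correlation(self):
        # noise sd 0.05 against ~0.18 of structured signal: rho ~ 0.96
        cfg = CohortConfig(noise_sd=0.05, n_regions=1, seed=8)
        table, _ = simulate_cohort(cfg)
        model = HierarchicalBayesianLinearModel(random_state=8, **FAST).fit(
            table.covariates, table.data["region01"])
        pred = model.predict(table.covariates)
        rho = np.corrcoef(pred, table.data["region01"])[0, 1]
        assert rho > 0.9

    def test_duplicated_test_row_identical_predictions(self, fitted_hblm):
        model, table, _ = fitted_hblm
        row = table.covariates.iloc[[0]]
        two = pd.concat([row, row], ignore_index=True)
        pred = model.predict_dist(two)
        assert pred.mean[0] == pred.mean[1]
        assert pred.epistemic_var[0] == pred.epistemic_var[1]


class TestZScores:
    def test_exact_match_gives_zero(self):
        pred = PredictiveDistribution(mean=np.array([2.5]),
                                      epistemic_var=np.array([0.01]),
                                      noise_var=0.02)
        assert zscores(np.array([2.5]), pred).z[0] == 0.0

    def test_arithmetic_example(self):
        pred = PredictiveDistribution(mean=np.array([2.5]),
                                      epistemic_var=np.array([0.01]),
                                      noise_var=0.03)
        dev = zscores(np.array([2.7]), pred)
        assert dev.z[0] == pytest.approx(1.0)
        assert not dev.atypical[0]

    def test_zero_variance_mismatch_raises(self):
        pred = PredictiveDistribution(mean=np.array([2.5, 2.0]),
                                      epistemic_var=np.array([0.0, 0.0]),
                                      noise_var=0.0)
        with pytest.raises(ValueError, match="zero predictive variance"):
            zscores(np.array([2.7, 2.0]), pred)
        dev = zscores(np.array([2.5, 2.0]), pred)
        np.testing.assert_array_equal(dev.z, [0.0, 0.0])

    def test_held_out_scores_calibrated(self):
        """On data from the model's own process, held-out z have mean ~0
        and sd ~1 (checked with >= 300 held-out scores)."""
        from sitenorm.pipeline import run_pipeline
        from sitenorm.preprocess import stratified_split
        from sitenorm.simulate import default_config
        table, _ = simulate_cohort(default_config(seed=42))
        split = stratified_split(table, seed=42)
        res = run_pipeline(split.train, split.test, model="hblm", seed=1,
                           sampler=FAST,
                           regions=["region01", "region02", "region03"])
        z = res.predictions.query("split == 'test'")["z"]
        assert len(z) >= 300
        assert abs(z.mean()) < 0.1
        assert 0.9 < z.std() < 1.1


class TestConvergenceReport:
    def test_identical_stationary_chains_rhat_near_one(self):
        # identical chains have zero between-chain variance; split-R-hat is
        # ~1 provided each chain is stationary
        draw = np.random.default_rng(3).standard_normal(500)
        post = {"theta": np.tile(draw, (4, 1))}
        report = convergence_report(post)
        assert report.loc[0, "rhat"] == pytest.approx(1.0, abs=0.05)

    def test_white_noise_ess_near_total(self):
        rng = np.random.default_rng(0)
        post = {"theta": rng.standard_normal((4, 1000))}
        report = convergence_report(post)
        assert report.loc[0, "rhat"] == pytest.approx(1.0, abs=0.01)
        assert report.loc[0, "ess"] > 3000
        assert report.loc[0, "verdict"] == "pass"

    def test_offset_chain_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((4, 500))
        draws[0] += 10.0
        report = convergence_report({"theta": draws})
        assert report.loc[0, "rhat"] > 1.1
        assert report.loc[0, "verdict"] == "warn"

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(2)
        report = convergence_report({"theta": rng.standard_normal((1, 800))})
        assert np.isnan(report.loc[0, "rhat"])
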