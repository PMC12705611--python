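"""Daily-series construction, temporal screens and trajectory clustering."""

import numpy as np
import pandas as pd
import pytest

from phenoloop.trajectory import (
    ClusterReport,
    SmoothingSpec,
    TrajectoryClusterer,
    build_daily_panel,
    build_trajectory_matrix,
    cluster_statistics,
    daily_correlation,
    daily_dose_tests,
    embed_cluster,
    first_significant_day,
    smooth_interpolate,
)

UNIFORM_DAYS = np.arange(4, 25, 2)  # 11 evenly spaced observation days


def make_panel(values_by_plant: dict, days=np.arange(4, 26),
               features=("root_px", "shoot_px", "health")) -> pd.DataFrame:
    """Tidy panel where each plant has a constant level per feature."""
    rows = []
    for pid, level in values_by_plant.items():
        for f in features:
            rows.append(pd.DataFrame(dict(plant_id=pid, feature=f, day=days,
                                          value=float(level))))
    return pd.concat(rows, ignore_index=True)


class TestSmoothInterpolate:
    def test_constant_series(self):
        out = smooth_interpolate(UNIFORM_DAYS, np.full(UNIFORM_DAYS.size, 2.5))
        assert np.allclose(out.to_numpy(), 2.5)
        assert list(out.index) == list(range(4, 26))

    def test_cubic_polynomial_reproduced_exactly(self):
        poly = np.polynomial.Polynomial([1.0, -0.2, 0.03, -0.001])
        out = smooth_interpolate(UNIFORM_DAYS, poly(UNIFORM_DAYS),
                                 SmoothingSpec(polyorder=3))
        grid = np.arange(4, 26)
        inside = (grid >= UNIFORM_DAYS[0]) & (grid <= UNIFORM_DAYS[-1])
        assert np.allclose(out.to_numpy()[inside], poly(grid[inside]), atol=1e-8)

    def test_no_extrapolation_beyond_observed_days(self):
        days = np.arange(6, 26, 2)  # first observation at day 6
        vals = days.astype(float)
        out = smooth_interpolate(days, vals)
        assert out.loc[4] == pytest.approx(out.loc[6])
        assert out.loc[5] == pytest.approx(out.loc[6])

    def test_smoothing_reduces_noise_on_logistic(self):
        rng = np.random.default_rng(0)
        days = np.arange(4, 26, 2)
        truth = 1.0 / (1.0 + np.exp(-(days - 14) / 3.0))
        errs_raw, errs_smooth = [], []
        for _ in range(20):
            noisy = truth * (1 + rng.normal(0, 0.05, days.size))
            out = smooth_interpolate(days, noisy)
            truth_daily = 1.0 / (1.0 + np.exp(-(out.index.to_numpy() - 14) / 3.0))
            errs_smooth.append(np.sqrt(np.mean((out.to_numpy() - truth_daily) ** 2)))
            errs_raw.append(np.sqrt(np.mean((noisy - truth) ** 2)))
        assert np.mean(errs_smooth) < np.mean(errs_raw)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="window"):
            smooth_interpolate([4, 6, 8], [1.0, 2.0, 3.0])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SmoothingSpec(window_length=6)
        with pytest.raises(ValueError):
            SmoothingSpec(window_length=7, polyorder=7)


class TestDailyPanel:
    def test_panel_from_simulated_study(self, round1_study):
        panel = build_daily_panel(round1_study.observations)
        assert set(panel.feature) == {"root_px", "shoot_px", "health", "ndvi"}
        per = panel.groupby(["plant_id", "feature"]).day.count()
        assert (per == 22).all()  # days 4..25 inclusive


class TestDailyCorrelation:
    def test_perfect_negative(self):
        doses = pd.Series([0.0, 100.0, 200.0, 300.0], index=list("abcd"))
        mat = pd.DataFrame(-np.tile(doses.to_numpy(), (3, 1)).T,
                           index=list("abcd"), columns=[11, 12, 13])
        out = daily_correlation(doses, mat, n_boot=200, seed=0)
        assert np.allclose(out.r, -1.0)
        assert np.allclose(out.ci_high - out.ci_low, 0.0, atol=1e-12)

    def test_null_feature_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        idx = [f"p{i}" for i in range(40)]
        coverages = []
        for seed in range(8):
            doses = pd.Series(rng.uniform(0, 500, 40), index=idx)
            mat = pd.DataFrame(rng.normal(0, 1, (40, 15)), index=idx,
                               columns=range(11, 26))
            out = daily_correlation(doses, mat, n_boot=500, seed=seed)
            coverages.append(((out.ci_low <= 0) & (out.ci_high >= 0)).mean())
        assert np.mean(coverages) >= 0.9

    def test_zero_variance_rejected(self):
        doses = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        mat = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=[11, 12])
        with pytest.raises(ValueError):
            daily_correlation(doses, mat, n_boot=10)


class TestDailyDoseTests:
    def test_huge_separation_flagged(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(12)]
        doses = pd.Series([0.0] * 6 + [500.0] * 6, index=idx)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(10, 1, 6)])
        mat = pd.DataFrame(vals[:, None], index=idx, columns=[20])
        out = daily_dose_tests(mat, doses)
        assert out.significant.all()
        assert set(out.dose) == {500.0}

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        idx = [f"p{i}" for i in range(30)]
        doses = pd.Series(np.repeat([0.0, 100.0, 500.0], 10), index=idx)
        mat = pd.DataFrame(rng.normal(0, 1, (30, 10)), index=idx,
                           columns=range(11, 21))
        out = daily_dose_tests(mat, doses)
        assert out.significant.mean() <= 0.15

    def test_missing_control_rejected(self):
        doses = pd.Series([100.0, 100.0, 500.0, 500.0], index=list("abcd"))
        mat = pd.DataFrame(np.ones((4, 1)), index=list("abcd"), columns=[11])
        with pytest.raises(ValueError, match="control"):
            daily_dose_tests(mat, doses)

    def test_first_significant_day_extraction(self):
        tests = pd.DataFrame(dict(day=[11, 12, 13, 11, 12, 13],
                                  dose=[100.0] * 3 + [500.0] * 3,
                                  p_adj=[0.9, 0.01, 0.01, 0.01, 0.01, 0.01],
                                  significant=[False, True, True, True, True, True]))
        fsd = first_significant_day(tests)
        assert fsd[100.0] == 12 and fsd[500.0] == 11


class TestTrajectoryMatrix:
    def test_two_constant_plants_scale_to_zero_and_one(self):
        panel = make_panel({"a": 1.0, "b": 3.0})
        mat = build_trajectory_matrix(panel)
        assert mat.shape == (2, 45)
        assert np.allclose(mat.loc["a"], 0.0)
        assert np.allclose(mat.loc["b"], 1.0)

    def test_71_plants_45_columns(self):
        rng = np.random.default_rng(0)
        panel = make_panel({f"p{i:02d}": rng.uniform(0, 1) for i in range(71)})
        mat = build_trajectory_matrix(panel)
        assert mat.shape == (71, 45)
        assert mat.to_numpy().min() >= 0.0 and mat.to_numpy().max() <= 1.0

    def test_scaling_idempotent(self):
        rng = np.random.default_rng(1)
        panel = make_panel({f"p{i}": rng.uniform(2, 9) for i in range(8)})
        once = build_trajectory_matrix(panel)
        # rebuild a panel from the scaled values and scale again
        rows = []
        for col in once.columns:
            feature, day = col.rsplit("_d", 1)
            for pid in once.index:
                rows.append(dict(plant_id=pid, feature=feature, day=int(day),
                                 value=once.loc[pid, col]))
        twice = build_trajectory_matrix(pd.DataFrame(rows))
        assert np.allclose(twice.to_numpy(), once.to_numpy())

    def test_missing_feature_rejected(self):
        panel = make_panel({"a": 1.0, "b": 2.0}, features=("root_px", "shoot_px"))
        with pytest.raises(ValueError):
            build_trajectory_matrix(panel)


def separable_matrix(n_per_group=12, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"g1_{i}" for i in range(n_per_group)] + \
          [f"g2_{i}" for i in range(n_per_group)]
    a = 0.15 + rng.normal(0, 0.02, (n_per_group, 45))
    b = 0.85 + rng.normal(0, 0.02, (n_per_group, 45))
    return pd.DataFrame(np.vstack([a, b]).clip(0, 1), index=idx)


class TestClustering:
    def test_separable_groups_recovered(self):
        mat = separable_matrix()
        report = embed_cluster(mat, seed=1)
        assert report.n_clusters == 2
        assert report.n_noise == 0
        labels = report.labels
        g1 = set(labels[labels.index.str.startswith("g1")])
        g2 = set(labels[labels.index.str.startswith("g2")])
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2

    def test_deterministic_under_seed(self):
        mat = separable_matrix(seed=3)
        l1 = TrajectoryClusterer(random_state=9).fit_predict(mat.to_numpy())
        l2 = TrajectoryClusterer(random_state=9).fit_predict(mat.to_numpy())
        assert np.array_equal(l1, l2)

    def test_homogeneous_group_at_most_one_cluster(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(0.5 + rng.normal(0, 0.02, (20, 45)),
                           index=[f"p{i}" for i in range(20)])
        report = embed_cluster(mat, seed=2)
        assert report.n_clusters <= 1

    def test_too_few_rows_all_noise(self):
        mat = separable_matrix(n_per_group=3)
        with pytest.warns(UserWarning, match="noise"):
            report = embed_cluster(mat, seed=0)
        assert report.n_clusters == 0
        assert report.n_noise == len(mat)


class TestClusterStatistics:
    def _report(self, labels: pd.Series) -> ClusterReport:
        emb = pd.DataFrame(dict(plant_id=labels.index, x=0.0, y=0.0, label=labels))
        return ClusterReport(embedding=emb, labels=labels,
                             cluster_summary=pd.DataFrame(),
                             n_clusters=len(set(labels) - {-1}),
                             n_noise=int((labels == -1).sum()))

    def test_dose_strata_significant_and_ordered(self):
        rng = np.random.default_rng(5)
        idx = [f"p{i}" for i in range(30)]
        labels = pd.Series(np.repeat([0, 1, 2], 10), index=idx)
        doses = pd.Series(np.repeat([5.0, 150.0, 450.0], 10)
                          + rng.normal(0, 5, 30), index=idx)
        res = cluster_statistics(self._report(labels), doses)
        assert res["dose"].pvalue < 0.01
        assert (res["dose"].pairwise.p_adj < 0.05).all()

    def test_identical_clusters_not_significant(self):
        vals = np.array([1.0, 1.2, 0.8, 1.1, 0.9])
        idx = [f"p{i}" for i in range(10)]
        labels = pd.Series([0] * 5 + [1] * 5, index=idx)
        doses = pd.Series(np.concatenate([vals, vals]), index=idx)
        res = cluster_statistics(self._report(labels), doses)
        assert res["dose"].pvalue > 0.9

    def test_single_cluster_rejected(self):
        idx = list("abcd")
        labels = pd.Series([0, 0, 0, -1], index=idx)
        with pytest.raises(ValueError):
            cluster_statistics(self._report(labels),
                               pd.Series([1.0, 2.0, 3.0, 4.0], index=idx))
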