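"""State-space model: exact-inference oracles, diagnostics, reproducibility."""

import numpy as np
import pytest

from trophlink import (
    AnnualSeries,
    DegenerateSeriesError,
    SSMConfig,
    fit_ssm,
    gelman_rubin,
    kalman_smoother,
    map_series,
)
from trophlink.ssm import fast_config, write_posterior


def _single_obs_series(values, start=1, name="s"):
    return AnnualSeries(
        name, [(start + i, float(v), None) for i, v in enumerate(values)]
    )


class TestAnnualSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            AnnualSeries("bad", [(5, 1.0, None)], year_range=(1, 3))
        with pytest.raises(ValueError):
            AnnualSeries("bad", [(1, float("inf"), None)])

    def test_grid_includes_missing_years(self, tmp_path):
        s = AnnualSeries("s", [(2000, 1.0, None), (2000, 1.5, None), (2004, 2.0, None)])
        assert list(s.years) == [2000, 2001, 2002, 2003, 2004]
        n, total = s.grid_arrays()
        assert list(n) == [2, 0, 0, 0, 1]
        assert total[0] == pytest.approx(2.5)
        p = tmp_path / "s.csv"
        s.to_dataframe().to_csv(p, index=False)
        back = AnnualSeries.from_csv(p)
        assert back.observations[0][:2] == (2000, 1.0)


class TestKalmanSmoother:
    def test_hand_computed_three_year_recursion(self):
        # Local-level model, prior N(0, 1), Q = 0.5, R = 1, observations
        # y_1 = 1.0 (one), year 2 missing, y_3 = {2.0, 3.0}.  The filter and
        # smoother recursions worked by hand give exactly:
        #   filtered: m = (0.5, 0.5, 2.0),  C = (0.5, 1.0, 0.375)
        #   smoothed: m = (1.0, 1.5, 2.0),  V = (0.375, 0.5, 0.375)
        n = np.array([1, 0, 2])
        s = np.array([1.0, 0.0, 5.0])
        sm, sv = kalman_smoother(n, s, q=0.5, r=1.0, prior_mean=0.0, prior_var=1.0)
        assert np.allclose(sm, [1.0, 1.5, 2.0])
        assert np.allclose(sv, [0.375, 0.5, 0.375])

    def test_matches_statsmodels_local_level(self):
        sm_api = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        y = np.cumsum(rng.normal(0, 0.3, 25)) + rng.normal(0, 0.5, 25)
        y_obs = y.copy()
        y_obs[[4, 5, 11, 18]] = np.nan
        q, r = 0.09, 0.25
        mod = sm_api.tsa.UnobservedComponents(y_obs, level="llevel")
        mod.ssm.initialize_known(np.array([0.0]), np.array([[25.0]]))
        res = mod.smooth([r, q])  # params: sigma2.irregular, sigma2.level
        n = (~np.isnan(y_obs)).astype(int)
        s = np.nan_to_num(y_obs)
        means, variances = kalman_smoother(n, s, q, r, 0.0, 25.0)
        assert np.allclose(means, res.smoothed_state[0], atol=1e-8)
        assert np.allclose(variances, res.smoothed_state_cov[0, 0], atol=1e-8)

    def test_missing_year_has_larger_variance_than_neighbours(self):
        n = np.array([1, 1, 0, 1, 1])
        s = np.array([1.0, 1.2, 0.0, 1.8, 2.0])
        _, sv = kalman_smoother(n, s, 0.1, 0.2, 1.0, 5.0)
        assert sv[2] > sv[1] and sv[2] > sv[3]


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 5_000))
        chains[1] += 5.0
        assert gelman_rubin(chains) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        good = rng.normal(size=(4, 2_000))
        bad = good + np.arange(4)[:, None] * 2.0
        for chains, hi in ((good, False), (bad, True)):
            mine = gelman_rubin(chains)
            theirs = float(az.rhat(chains))
            assert (mine > 1.2) == hi and (theirs > 1.2) == hi
            if not hi:
                assert mine == pytest.approx(theirs, abs=0.01)


class TestMapSeries:
    def test_point_mass(self):
        draws = np.full((300, 2), 2.0)
        out = map_series(draws, [1990, 1991])
        assert out[1990] == (2.0, 2.0, 2.0)

    def test_symmetric_unimodal_map_near_median(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(1.5, 0.4, size=(5000, 1))
        out = map_series(draws, [2000])
        m, lo, hi = out[2000]
        assert abs(m - np.median(draws)) < 0.1
        assert lo < m < hi

    def test_bimodal_fixture_picks_heavier_mode(self):
        rng = np.random.default_rng(4)
        draws = np.concatenate(
            [rng.normal(0.0, 0.1, 300), rng.normal(2.0, 0.1, 700)]
        ).reshape(-1, 1)
        out = map_series(draws, [2000])
        assert abs(out[2000][0] - 2.0) < 0.15

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            map_series(np.zeros((50, 3)), [1, 2, 3])


class TestFitSSM:
    def test_noiseless_observation_limit(self):
        rng = np.random.default_rng(5)
        vals = np.cumsum(rng.normal(0, 0.3, 12)) + 3.0
        series = _single_obs_series(vals)
        post = fit_ssm(series, fast_config(seed=1, fixed_r=1e-12))
        got = np.array([post.map_series[y] for y in series.years])
        assert np.allclose(got, vals, atol=1e-5)
        assert all(
            lo <= m <= hi
            for (m, (lo, hi)) in zip(got, (post.ci95[y] for y in series.years))
        )

    def test_gibbs_matches_smoother_at_fixed_variances(self):
        # T=10 with a missing stretch; Q and R pinned at truth so the Gibbs
        # draws target exactly the smoother's Gaussian posterior.
        rng = np.random.default_rng(6)
        truth = np.cumsum(rng.normal(0, 0.2, 10))
        obs = [
            (t + 1, float(truth[t] + rng.normal(0, 0.5)), None)
            for t in range(10)
            if t not in (3, 6)
            for _ in range(3)
        ]
        series = AnnualSeries("k", obs, year_range=(1, 10))
        cfg = SSMConfig(
            n_chains=2, n_iterations=6000, burn_in=1000, thinning=1,
            seed=2, fixed_q=0.04, fixed_r=0.25, prior_x1=(0.0, 10.0),
        )
        post = fit_ssm(series, cfg)
        n, s = series.grid_arrays()
        sm, sv = kalman_smoother(n, s, 0.04, 0.25, 0.0, 10.0)
        pooled = post.pooled_x()
        assert np.allclose(pooled.mean(axis=0), sm, atol=0.03)
        assert np.allclose(pooled.var(axis=0), sv, rtol=0.15)

    def test_missing_year_variance_exceeds_neighbours(self, reference_series):
        series, _ = reference_series
        post = fit_ssm(series, fast_config(seed=3))
        var = post.pooled_x().var(axis=0)
        n_obs, _ = series.grid_arrays()
        lo = series.year_range[0]
        for t in range(1, series.n_years - 1):
            if n_obs[t] == 0 and n_obs[t - 1] > 0 and n_obs[t + 1] > 0:
                assert var[t] > var[t - 1] and var[t] > var[t + 1]

    def test_shift_invariance_same_seed(self):
        rng = np.random.default_rng(7)
        vals = np.cumsum(rng.normal(0, 0.4, 15))
        s1 = _single_obs_series(vals)
        s2 = _single_obs_series(vals + 100.0)
        # with variances pinned, shift equivariance of the state draws is
        # exact; with free variances it holds up to Monte-Carlo noise
        cfg = fast_config(seed=4, fixed_q=0.16, fixed_r=0.09)
        p1, p2 = fit_ssm(s1, cfg), fit_ssm(s2, cfg)
        assert np.allclose(p2.draws_x, p1.draws_x + 100.0, atol=1e-8)
        cfg_free = fast_config(seed=4)
        f1, f2 = fit_ssm(s1, cfg_free), fit_ssm(s2, cfg_free)
        for y in f1.map_series:
            assert f2.map_series[y] - f1.map_series[y] == pytest.approx(100.0, abs=0.2)
        assert np.median(f2.draws_q) == pytest.approx(np.median(f1.draws_q), rel=0.2)
        assert np.median(f2.draws_r) == pytest.approx(np.median(f1.draws_r), rel=0.2)

    def test_bit_identical_given_seed(self):
        rng = np.random.default_rng(8)
        vals = np.cumsum(rng.normal(0, 0.4, 15))
        series = _single_obs_series(vals)
        p1 = fit_ssm(series, fast_config(seed=5))
        p2 = fit_ssm(series, fast_config(seed=5))
        assert np.array_equal(p1.draws_x, p2.draws_x)
        assert np.array_equal(p1.draws_q, p2.draws_q)
        assert p1.map_series == p2.map_series

    def test_degenerate_series_error_advises_fixed_r(self):
        series = _single_obs_series([2.0] * 8)
        with pytest.raises(DegenerateSeriesError, match="fixed_r"):
            fit_ssm(series, fast_config(seed=6))
        post = fit_ssm(series, fast_config(seed=6, fixed_r=0.01))
        assert all(abs(v - 2.0) < 0.2 for v in post.map_series.values())

    def test_too_few_observed_years(self):
        with pytest.raises(ValueError):
            fit_ssm(AnnualSeries("s", [(1, 1.0, None), (1, 2.0, None)]), fast_config())

    def test_log_scale_reports_on_natural_scale(self):
        rng = np.random.default_rng(9)
        vals = np.exp(np.cumsum(rng.normal(0, 0.2, 15)) + 1.0)
        series = _single_obs_series(vals)
        post = fit_ssm(series, fast_config(seed=7, log_scale=True))
        got = np.array([post.map_series[y] for y in series.years])
        assert np.all(got > 0)
        assert np.corrcoef(got, vals)[0, 1] > 0.9

    def test_summary_outputs(self, tmp_path):
        rng = np.random.default_rng(11)
        vals = np.cumsum(rng.normal(0, 0.4, 12))
        post = fit_ssm(_single_obs_series(vals), fast_config(seed=8))
        df = post.summary_frame()
        assert list(df.columns) == ["year", "map", "median", "lower95", "upper95", "n_obs"]
        assert (df["lower95"] <= df["map"]).all() and (df["map"] <= df["upper95"]).all()
        write_posterior(post, tmp_path / "out.csv", tmp_path / "out.json")
        assert (tmp_path / "out.csv").exists() and (tmp_path / "out.json").exists()
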