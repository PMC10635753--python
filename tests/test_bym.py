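"""BYM model: densities, Gibbs updates, posterior summaries, classification."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from bymap import (
    BYMState,
    CountData,
    MCMCConfig,
    RiskBand,
    Significance,
    SpatialWeights,
    classify_significance,
    exact_posterior_quantiles,
    fit_bym,
    gibbs_sweep,
    log_posterior,
    raw_ratio,
    risk_band,
)
from bymap.bym import draw_tau_v


def pair_weights():
    return SpatialWeights(area_ids=["a", "b"], neighbors=[[1], [0]],
                          weights=[[1.0], [1.0]])


def flat_counts(weights, e=50.0):
    n = weights.n
    return CountData(area_ids=list(weights.area_ids),
                     observed=np.full(n, int(e)), expected=np.full(n, e))


class TestLogPosterior:
    def test_poisson_term_matches_direct_arithmetic(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        state = BYMState(alpha=0.0, u=np.zeros(16), v=np.zeros(16),
                         tau_u=1.0, tau_v=1.0)
        lp = log_posterior(state, counts, grid4_weights,
                           tau_u_prior=(1.0, 0.5), tau_v_prior=(1.0, 0.5))
        O = counts.observed
        E = counts.expected
        # independent evaluation: Poisson mass at mu = E, zero random effects,
        # log tau terms vanish at tau = 1, Gamma(1, 0.5) hyperpriors
        expected = float(np.sum(O * np.log(E) - E - gammaln(O + 1))) - 0.5 - 0.5
        assert lp == pytest.approx(expected, abs=1e-9)

    def test_icar_kernel_single_pair(self):
        w = pair_weights()
        counts = CountData(area_ids=["a", "b"], observed=[2, 2],
                           expected=[2.0, 2.0])
        tau_u, c = 3.0, 0.4

        def lp(uvec):
            state = BYMState(alpha=0.0, u=np.asarray(uvec), v=np.zeros(2),
                             tau_u=tau_u, tau_v=1.0)
            return log_posterior(state, counts, w)

        delta = lp([c, -c]) - lp([0.0, 0.0])
        O, E = counts.observed, counts.expected
        lik = float(np.sum(O * np.array([c, -c])
                           - E * (np.exp([c, -c]) - 1.0)))
        assert delta == pytest.approx(lik - tau_u / 2 * (2 * c) ** 2, abs=1e-9)

    def test_alpha_absorbs_constant_shift_of_u(self):
        # recentering a drifted u while shifting alpha leaves theta unchanged
        drifted = BYMState(alpha=0.2, u=np.array([1.0, 0.4]),
                           v=np.array([0.1, 0.0]), tau_u=1.0, tau_v=1.0)
        shift = drifted.u.mean()
        recentered = BYMState(alpha=drifted.alpha + shift, u=drifted.u - shift,
                              v=drifted.v, tau_u=1.0, tau_v=1.0)
        assert abs(recentered.u.sum()) < 1e-12
        np.testing.assert_allclose(recentered.theta, drifted.theta)

    def test_island_without_flag_is_an_error(self):
        w = SpatialWeights(area_ids=["a", "b", "isle"],
                           neighbors=[[1], [0], []],
                           weights=[[1.0], [1.0], []])
        counts = CountData(area_ids=["a", "b", "isle"], observed=[1, 1, 1],
                           expected=[1.0, 1.0, 1.0])
        state = BYMState(alpha=0.0, u=np.zeros(3), v=np.zeros(3),
                         tau_u=1.0, tau_v=1.0)
        with pytest.raises(ValueError, match="apply_manual_links"):
            log_posterior(state, counts, w)
        lp = log_posterior(state, counts, w, allow_islands=True)
        assert np.isfinite(lp)


class TestGibbsSweep:
    def test_deterministic_under_seed(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        state = BYMState(alpha=0.0, u=np.zeros(16), v=np.zeros(16),
                         tau_u=1.0, tau_v=1.0)
        out1 = gibbs_sweep(state, counts, grid4_weights,
                           np.random.default_rng(42))
        out2 = gibbs_sweep(state, counts, grid4_weights,
                           np.random.default_rng(42))
        np.testing.assert_array_equal(out1.u, out2.u)
        np.testing.assert_array_equal(out1.v, out2.v)
        assert out1.alpha == out2.alpha
        assert out1.tau_u == out2.tau_u

    def test_u_recentered_to_sum_zero(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        rng = np.random.default_rng(0)
        state = BYMState(alpha=0.0, u=np.zeros(16), v=np.zeros(16),
                         tau_u=1.0, tau_v=1.0)
        for _ in range(10):
            state = gibbs_sweep(state, counts, grid4_weights, rng)
            assert abs(state.u.sum()) < 1e-9

    def test_huge_tau_u_collapses_field_toward_neighbor_means(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        tau = 1e4
        cfg = MCMCConfig(fixed_tau_u=tau, fixed_tau_v=1.0)
        rng = np.random.default_rng(1)
        state = BYMState(alpha=0.0, u=rng.standard_normal(16),
                         v=np.zeros(16), tau_u=tau, tau_v=1.0)
        W = grid4_weights.to_sparse()
        m = grid4_weights.cardinalities

        def max_dev(u):
            return np.max(np.abs(u - (W @ u) / m))

        deviations = [max_dev(state.u)]
        for sweep in range(200):
            state = gibbs_sweep(state, counts, grid4_weights, rng, cfg)
            if (sweep + 1) % 50 == 0:
                deviations.append(max_dev(state.u))
        # shrinks monotonically (checkpointed) and collapses by the end
        assert all(b < a for a, b in zip(deviations, deviations[1:]))
        assert deviations[-1] < 0.1 * deviations[0]

    def test_tau_v_conjugate_moments(self):
        # with the field held fixed the precision draw is Gamma(a + n/2,
        # b + sum v^2 / 2); check the empirical mean of 10,000 draws
        rng = np.random.default_rng(7)
        v = rng.standard_normal(25) * 0.5
        a, b = 0.5, 0.0005
        draws = [draw_tau_v(v, (a, b), rng) for _ in range(10_000)]
        analytic = (a + 25 / 2) / (b + 0.5 * float(v @ v))
        assert np.mean(draws) == pytest.approx(analytic, rel=0.02)


class TestFitBym:
    def test_flat_truth_gives_unit_risks_and_no_significance(self, grid4_weights):
        counts = flat_counts(grid4_weights, e=50.0)
        cfg = MCMCConfig(n_iter=8000, thin=4, burn_in_fraction=0.5, seed=5)
        _, summary, _ = fit_bym(counts, grid4_weights, cfg)
        f = summary.frame
        assert np.all(np.abs(f["median_rr"] - 1.0) < 0.1)
        assert (f["significance"] == "none").all()

    def test_two_area_medians_match_quadrature_oracle(self):
        w = pair_weights()
        counts = CountData(area_ids=["a", "b"], observed=[1, 4],
                           expected=[2.0, 2.0])
        tau_u, tau_v = 4.0, 4.0
        cfg = MCMCConfig(n_iter=40_000, thin=4, burn_in_fraction=0.5, seed=3,
                         fixed_tau_u=tau_u, fixed_tau_v=tau_v)
        _, summary, _ = fit_bym(counts, w, cfg)
        oracle = exact_posterior_quantiles(
            counts.observed, counts.expected, [(0, 1)], tau_u, tau_v
        )
        med = summary.frame["median_rr"].to_numpy()
        assert np.max(np.abs(med - oracle[:, 1])) < 0.05
        lo = summary.frame["ci_low"].to_numpy()
        hi = summary.frame["ci_high"].to_numpy()
        assert np.max(np.abs(lo - oracle[:, 0])) < 0.1
        assert np.max(np.abs(hi - oracle[:, 2])) < 0.2

    def test_shrinkage_pulls_extreme_sparse_area_toward_field(self, grid3):
        areas, w = grid3
        observed = np.full(9, 50)
        expected = np.full(9, 50.0)
        observed[4] = 3
        expected[4] = 0.5  # raw ratio 6.0 on almost no expected load
        counts = CountData(area_ids=[a.area_id for a in areas],
                           observed=observed, expected=expected)
        cfg = MCMCConfig(n_iter=10_000, thin=4, burn_in_fraction=0.5, seed=9)
        _, summary, _ = fit_bym(counts, w, cfg)
        assert summary.frame["median_rr"].iloc[4] < 6.0

    def test_posterior_variance_never_exceeds_raw_variance(self, grid4_weights):
        rng = np.random.default_rng(12)
        observed = rng.poisson(20, size=16)
        counts = CountData(
            area_ids=list(grid4_weights.area_ids), observed=observed,
            expected=np.full(16, float(observed.sum()) / 16),
        )
        cfg = MCMCConfig(n_iter=8000, thin=4, burn_in_fraction=0.5, seed=13)
        _, summary, _ = fit_bym(counts, grid4_weights, cfg)
        assert (np.var(summary.frame["median_rr"])
                <= np.var(raw_ratio(counts)) + 1e-12)

    def test_kept_draws_are_bit_identical_across_runs(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        cfg = MCMCConfig(n_iter=2000, thin=2, burn_in_fraction=0.5, seed=21)
        post1, _, _ = fit_bym(counts, grid4_weights, cfg)
        post2, _, _ = fit_bym(counts, grid4_weights, cfg)
        np.testing.assert_array_equal(post1.theta, post2.theta)
        np.testing.assert_array_equal(post1.tau_u, post2.tau_u)

    def test_underpowered_schedule_rejected_before_sampling(self, grid4_weights):
        counts = flat_counts(grid4_weights)
        cfg = MCMCConfig(n_iter=1000, thin=20, burn_in_fraction=0.6)
        with pytest.raises(ValueError, match="100"):
            fit_bym(counts, grid4_weights, cfg)


class TestSchedule:
    def test_default_schedule_keeps_10000(self):
        cfg = MCMCConfig()
        assert cfg.n_iter == 500_000
        assert cfg.thin == 20
        assert cfg.burn_in_fraction == 0.6
        assert cfg.n_chains == 1
        assert cfg.n_kept == 10_000

    @pytest.mark.parametrize("bad", [
        dict(n_iter=0), dict(thin=0), dict(burn_in_fraction=0.0),
        dict(burn_in_fraction=1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            MCMCConfig(**bad)


class TestClassification:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (2.14, 3.15, Significance.high),   # interval wholly above 1
            (1.04, 1.59, Significance.high),   # lower limit barely above 1
            (0.80, 1.20, Significance.none),
            (0.40, 0.90, Significance.low),
            (1.0, 1.5, Significance.none),     # touching 1 is not above it
        ],
    )
    def test_interval_rule(self, lo, hi, expected):
        assert classify_significance(lo, hi) == expected

    @pytest.mark.parametrize(
        "rr,expected",
        [
            (2.61, RiskBand.above_100pct),
            (1.29, RiskBand.above_average_within_100pct),
            (1.00, RiskBand.at_or_below_average),
            (2.00, RiskBand.above_average_within_100pct),
            (0.30, RiskBand.at_or_below_average),
        ],
    )
    def test_risk_bands(self, rr, expected):
        assert risk_band(rr) == expected

    def test_nonpositive_risk_rejected(self):
        with pytest.raises(ValueError):
            risk_band(0.0)
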