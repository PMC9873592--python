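"""Growth-model tests: the negative-growth filter, the closed-form
time-to-length, posterior contrasts, and a fast fit on simulated data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redback.growth import (
    ContrastResult,
    GrowthMCMC,
    GrowthObservation,
    GrowthParams,
    GrowthPosterior,
    contrast_K,
    filter_negative_growth,
    fit_growth,
    maturity_curve,
    maturity_from_normal_summaries,
    time_to_length,
)
from redback.scr import SCRParams
from redback.synthetic import TruthParams, simulate_growth_series


def _obs(svl, sex="female", plot="mature", iid="x"):
    return GrowthObservation(
        individual_id=iid,
        sex=sex,
        plot=plot,
        svl=np.asarray(svl, dtype=float),
        intervals_days=np.full(len(svl) - 1, 180.0),
    )


class TestNegativeGrowthFilter:
    def test_shrinking_series_removed(self):
        kept, n = filter_negative_growth([_obs([35, 34])])
        assert kept == [] and n == 1

    def test_equal_series_retained(self):
        kept, n = filter_negative_growth([_obs([35, 35])])
        assert len(kept) == 1 and n == 0

    def test_mixed_input(self):
        obs = [_obs([30, 33], iid="a"), _obs([40, 38], iid="b"), _obs([36, 36, 41], iid="c")]
        kept, n = filter_negative_growth(obs)
        assert [o.individual_id for o in kept] == ["a", "c"] and n == 1

    def test_idempotent(self):
        obs = [_obs([30, 33]), _obs([40, 38]), _obs([36, 36, 41])]
        once, _ = filter_negative_growth(obs)
        twice, n2 = filter_negative_growth(once)
        assert twice == once and n2 == 0


class TestTimeToLength:
    def test_target_equals_start(self):
        assert time_to_length(50.0, 0.5, 30.0, 30.0) == 0.0

    def test_target_at_asymptote_unreachable(self):
        assert np.isinf(time_to_length(50.0, 0.5, 30.0, 50.0))
        assert np.isinf(time_to_length(50.0, 0.5, 30.0, 55.0))

    def test_nonpositive_rate_unreachable(self):
        assert np.isinf(time_to_length(50.0, 0.0, 30.0, 40.0))

    def test_successional_female_field_values(self):
        # L 52.164, K 0.339, 13.5 -> 34 mm: 2.229 years
        t = time_to_length(52.164, 0.339, 13.5, 34.0)
        assert t == pytest.approx(2.229, abs=1e-3)

    @given(
        K=st.floats(0.1, 1.5),
        L=st.floats(45.0, 60.0),
        mid=st.floats(20.0, 33.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additivity_and_monotonicity(self, K, L, mid):
        start, target = 13.5, 34.0
        t_full = time_to_length(L, K, start, target)
        t_split = time_to_length(L, K, start, mid) + time_to_length(L, K, mid, target)
        assert t_split == pytest.approx(t_full, rel=1e-9)
        assert time_to_length(L, K + 0.1, start, target) < t_full
        assert time_to_length(L + 1.0, K, start, target) < t_full

    def test_fabens_fixed_point_and_monotone_convergence(self):
        from redback.growth import fabens_update

        L, K = 50.0, 0.4
        assert fabens_update(L, L, K, 365.0) == pytest.approx(L)
        prev = 20.0
        for _ in range(200):
            nxt = fabens_update(prev, L, K, 365.0)
            assert prev <= nxt <= L
            if L - prev > 1e-9:
                assert nxt > prev
            prev = nxt
        assert prev == pytest.approx(L, abs=1e-6)


def _point_posterior(n: int = 50, **kw) -> GrowthPosterior:
    """Posterior stub with constant draws for contrast/maturity toys."""
    vals = dict(
        L_male=43.569, L_female=52.164, beta0_K=0.237, beta1_K=0.102, beta2_K=0.434
    )
    vals.update(kw)
    draws = {k: np.full((1, n), v) for k, v in vals.items()}
    draws["sigma_obs"] = np.full((1, n), 0.5)
    return GrowthPosterior(draws=draws)


class TestContrast:
    def test_all_draws_one_sided_is_significant(self):
        post = _point_posterior(beta1_K=0.3)
        c = contrast_K(post, "mature_female", "successional_female")
        assert c.prob_positive == 1.0 and c.significant
        assert np.allclose(c.diff, 0.3)

    def test_point_difference_matches_group_means(self):
        post = _point_posterior()
        c = contrast_K(post, "mature_male", "successional_male")
        assert float(c.diff.mean()) == pytest.approx(0.102)

    def test_symmetric_posterior_not_significant(self):
        rng = np.random.default_rng(0)
        post = _point_posterior(n=4000)
        post.draws["beta1_K"] = rng.normal(0, 1, (1, 4000))
        c = contrast_K(post, "mature_female", "successional_female")
        assert abs(c.prob_positive - 0.5) < 0.05 and not c.significant

    def test_identical_groups_rejected(self):
        with pytest.raises(ValueError):
            contrast_K(_point_posterior(), "mature_male", "mature_male")


class TestMaturityCurve:
    def test_point_posterior_median_is_closed_form_plus_lag(self):
        post = _point_posterior()
        c = maturity_curve(post, "successional", "female", pre_growth_lag=1.0, n_draws=100)
        assert c.median_age == pytest.approx(2.229 + 1.0, abs=1e-3)
        c0 = maturity_curve(post, "successional", "female", pre_growth_lag=0.0, n_draws=100)
        assert c0.median_age == pytest.approx(2.229, abs=1e-3)

    def test_unreachable_threshold_flagged(self):
        post = _point_posterior(L_female=30.0)  # below the 34 mm threshold
        c = maturity_curve(post, "mature", "female", n_draws=100)
        assert not c.reaches_half and c.never_mature_fraction == 1.0

    def test_summary_draws_match_posterior_route(self):
        """The published-summary reconstruction and the posterior-draw route
        agree when the posterior is exactly the summary normal."""
        rng = np.random.default_rng(3)
        post = _point_posterior()
        post.draws["beta1_K"] = np.zeros((1, 40_000))
        post.draws["beta0_K"] = rng.normal(0.339, 0.073, (1, 40_000))
        post.draws["L_female"] = rng.normal(52.164, 2.856, (1, 40_000))
        a = maturity_curve(post, "mature", "female", n_draws=40_000, seed=1)
        b = maturity_from_normal_summaries(52.164, 2.856, 0.339, 0.073, n_draws=40_000, seed=2)
        assert a.median_age == pytest.approx(b.median_age, abs=0.05)


class TestFitGrowth:
    def test_recovers_truth_on_small_simulation(self, field_growth_truth):
        truth = TruthParams(
            scr=SCRParams(phi=1, sigma=1, lam=0.1, density=0.1, tau=0.1),
            growth=field_growth_truth,
        )
        obs = simulate_growth_series(truth, 80, [180.0, 185.0], seed=21, sigma_obs=0.5)
        kept, _ = filter_negative_growth(obs)
        post = fit_growth(kept, mcmc=GrowthMCMC(n_steps=2500, n_burn=1200), seed=8)
        for plot in ("mature", "successional"):
            for sex in ("female", "male"):
                k = post.group_K(plot, sex)
                lo, hi = np.quantile(k, [0.025, 0.975])
                assert lo <= field_growth_truth.K(plot, sex) <= hi

    def test_posterior_sd_shrinks_with_sample_size(self, field_growth_truth):
        truth = TruthParams(
            scr=SCRParams(phi=1, sigma=1, lam=0.1, density=0.1, tau=0.1),
            growth=field_growth_truth,
        )
        sds = []
        for n, seed in [(40, 31), (160, 32)]:
            obs = simulate_growth_series(truth, n, [180.0, 185.0], seed=seed, sigma_obs=0.2)
            kept, _ = filter_negative_growth(obs)
            post = fit_growth(kept, seed=9)
            sds.append(post.group_K("mature", "female").std())
        assert sds[1] < sds[0]

    def test_zero_intervals_leave_K_prior_dominated(self):
        """With all capture intervals zero the Fabens expectation reduces to
        the previous size, so the likelihood carries no information on K and
        the posterior spread stays at the prior scale (SD 10)."""
        rng = np.random.default_rng(51)
        obs = [
            GrowthObservation(
                f"i{k}", "male" if k % 2 else "female",
                "successional" if k % 3 else "mature",
                svl=np.array([30.0 + k, 30.0 + k + rng.normal(0, 0.3)]),
                intervals_days=np.array([0.0]),
            )
            for k in range(20)
        ]
        obs, _ = filter_negative_growth(obs)
        post = fit_growth(obs, mcmc=GrowthMCMC(n_steps=3000, n_burn=1500), seed=52)
        assert post.flat("beta0_K").std() > 3.0  # prior SD is 10

    def test_single_plot_data_warns(self, field_growth_truth):
        truth = TruthParams(
            scr=SCRParams(phi=1, sigma=1, lam=0.1, density=0.1, tau=0.1),
            growth=field_growth_truth,
        )
        obs = simulate_growth_series(
            truth, 20, [180.0], seed=41, p_successional=0.0, sigma_obs=0.3
        )
        with pytest.warns(UserWarning, match="single-plot"):
            fit_growth(obs, mcmc=GrowthMCMC(n_steps=600, n_burn=300), seed=10)

    def test_zero_intervals_rejected_by_observation_type(self):
        with pytest.raises(ValueError):
            GrowthObservation("a", "female", "mature", np.array([30.0, 31.0]), np.array([-1.0]))
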