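import numpy as np
import pandas as pd
import pytest
from scipy import stats

from harvestcarbon.deheap import (
    DeheapConfig,
    conjugate_log_posterior,
    fit_deheap,
    lognormal_sd,
    species_type_moments,
)


def _reports(counts, codes, missing=None):
    n = len(counts)
    missing = missing or [False] * n
    return pd.DataFrame(
        {
            "report_id": np.arange(1, n + 1),
            "community": ["Inuvik"] * n,
            "month": [1] * n,
            "species_code": codes,
            "reported_count": [np.nan if m else c for c, m in zip(counts, missing)],
            "missing_flag": missing,
        }
    )


def _species(codes_types):
    return pd.DataFrame(
        [(c, t, "fish", 1.0, "fish_mix") for c, t in codes_types],
        columns=[
            "species_code",
            "species_type",
            "taxon_class",
            "edible_weight_kg_per_animal",
            "replacement_category",
        ],
    )


class TestSpeciesTypeMoments:
    def test_two_point_group_matches_direct_arithmetic(self):
        sp = _species([("a", "g1")])
        mom = species_type_moments(_reports([10, 100], ["a", "a"]), sp)
        mu, sd = mom["g1"]
        assert mu == pytest.approx((np.log(10) + np.log(100)) / 2)  # ~3.454
        assert sd == pytest.approx(np.std([np.log(10), np.log(100)], ddof=1))

    def test_zero_variance_group_gets_floor(self):
        sp = _species([("a", "g1")])
        mom = species_type_moments(_reports([10, 10, 10], ["a"] * 3), sp, sd_floor=0.5)
        mu, sd = mom["g1"]
        assert mu == pytest.approx(np.log(10))
        assert sd == 0.5

    def test_groups_are_independent(self):
        sp = _species([("a", "g1"), ("b", "g2")])
        mom = species_type_moments(_reports([10, 10, 40, 40], ["a", "a", "b", "b"]), sp)
        assert mom["g1"][0] == pytest.approx(np.log(10))
        assert mom["g2"][0] == pytest.approx(np.log(40))

    def test_all_missing_group_is_an_error(self):
        sp = _species([("a", "g1"), ("b", "g2")])
        reports = _reports([10, 5], ["a", "b"], missing=[False, True])
        with pytest.raises(ValueError, match="g2"):
            species_type_moments(reports, sp)


class TestConjugateOracle:
    def test_flat_prior_limit_returns_observation(self):
        m, s = conjugate_log_posterior(2.0, 0.15, 0.0, 1e6)
        assert m == pytest.approx(2.0, abs=1e-6)
        assert s == pytest.approx(0.15, rel=1e-6)

    def test_equal_precisions_average(self):
        m, _ = conjugate_log_posterior(4.0, 0.3, 2.0, 0.3)
        assert m == pytest.approx(3.0)

    def test_stated_numeric_case(self):
        m, _ = conjugate_log_posterior(np.log(50), 0.15, 3.0, 1.0)
        assert m == pytest.approx(3.892, abs=5e-4)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            conjugate_log_posterior(1.0, 0.0, 0.0, 1.0)


class TestLognormalSd:
    def test_reference_values(self):
        assert lognormal_sd(10, 0.15) == pytest.approx(1.5255, abs=1e-3)
        assert lognormal_sd(1, 0.15) == pytest.approx(0.1526, abs=1e-3)

    def test_vanishes_in_degenerate_limit(self):
        assert lognormal_sd(10, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_monte_carlo_cross_check(self):
        rng = np.random.default_rng(5)
        draws = np.exp(np.log(10) + 0.15 * rng.standard_normal(400_000))
        assert lognormal_sd(10, 0.15) == pytest.approx(draws.std(), rel=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            lognormal_sd(0, 0.15)


class TestFitDeheap:
    def test_single_report_matches_conjugate_oracle(self):
        # two reports in one group so the prior is informative but not
        # identical to the observation
        sp = _species([("a", "g1")])
        reports = _reports([20, 60], ["a", "a"])
        post = fit_deheap(reports, sp, DeheapConfig(seed=3))
        mom = post.moments
        mu, s = mom["g1"]
        for i, y in enumerate([20, 60]):
            em, esd = conjugate_log_posterior(np.log(y), 0.15, mu, s)
            se = post.log_sd[i] / np.sqrt(post.ess[i])
            assert abs(post.log_mean[i] - em) < 4 * se
            assert post.log_sd[i] == pytest.approx(esd, rel=0.1)

    def test_shrinkage_pulls_reports_toward_group_mean(self):
        sp = _species([("a", "g1")])
        counts = [20, 25, 30, 30, 35, 45]
        reports = _reports(counts, ["a"] * 6)
        post = fit_deheap(reports, sp, DeheapConfig(seed=4))
        mu = post.moments["g1"][0]
        for i, y in enumerate(counts):
            lo, hi = sorted([np.log(y), mu])
            se = post.log_sd[i] / np.sqrt(post.ess[i])
            assert lo - 3 * se <= post.log_mean[i] <= hi + 3 * se
        # the report of 45 lands strictly between the group centre and 45
        mean_45 = np.exp(post.log_mean[5])
        assert np.exp(mu) < mean_45 < 45

    def test_missing_reports_imputed_from_group_distribution(self):
        sp = _species([("a", "g1")])
        counts = [10, 20, 40, 15, 25, None]
        reports = _reports([c or 1 for c in counts], ["a"] * 6, missing=[False] * 5 + [True])
        post = fit_deheap(reports, sp, DeheapConfig(seed=5))
        mu, s = post.moments["g1"]
        assert post.log_mean[5] == pytest.approx(mu, abs=4 * s / np.sqrt(post.ess[5]))
        assert post.log_sd[5] == pytest.approx(s, rel=0.1)
        assert (post.draws > 0).all()

    def test_no_pooling_mode_leaves_observed_reports_unshrunk(self):
        sp = _species([("a", "g1")])
        reports = _reports([10, 10, 10, 80], ["a"] * 4, missing=[False, False, False, False])
        cfg = DeheapConfig(seed=6, pooling_mode="no_pooling")
        post = fit_deheap(reports, sp, cfg)
        # observed latents center on their own observation, sd = sigma_obs
        se = post.log_sd[3] / np.sqrt(post.ess[3])
        assert abs(post.log_mean[3] - np.log(80)) < 4 * se
        assert post.log_sd[3] == pytest.approx(0.15, rel=0.1)

    def test_seeded_determinism(self, species, small_survey):
        reports, _ = small_survey
        cfg = DeheapConfig(seed=7, iterations=1000)
        a = fit_deheap(reports, species, cfg)
        b = fit_deheap(reports, species, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draw_shape_and_positivity(self, species, small_survey):
        reports, _ = small_survey
        post = fit_deheap(reports, species, DeheapConfig(seed=8, iterations=2000, n_keep=150))
        assert post.draws.shape == (150, len(reports))
        assert (post.draws > 0).all()
        assert post.rhat.shape == (len(reports),)

    def test_nonconvergence_is_flagged_not_silent(self, species, small_survey):
        reports, _ = small_survey
        cfg = DeheapConfig(seed=9, iterations=60, rhat_threshold=1.001)
        with pytest.warns(RuntimeWarning, match="not converged"):
            post = fit_deheap(reports, species, cfg)
        assert not post.converged
        assert post.warnings_


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        DeheapConfig(sigma_obs=0.0)
    with pytest.raises(ValueError):
        DeheapConfig(chains=1)
    with pytest.raises(ValueError):
        DeheapConfig(pooling_mode="partial")
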