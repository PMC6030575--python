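"""The synthetic cohort generator: marginal moments, calibrations, determinism."""

import numpy as np
import pandas as pd
import pytest

from phqdaily import simulate
from phqdaily.params import default_parameters, rating_count_probabilities
from phqdaily.prediction import summarize_daily
from phqdaily.simulate import (
    GeneratorConfig,
    calibrate_outcome_model,
    calibrate_truncation_mean,
    generate_baseline,
    generate_cohort,
    generate_daily_items,
    generate_latents,
    generate_outcomes,
    generate_questionnaire,
    sample_cluster_sizes,
)


class TestClusterSizes:
    def test_fixture_mode_totals(self):
        sizes = sample_cluster_sizes(545, "fixture")
        assert sizes.sum() == 2992
        assert len(sizes) == 545
        assert sizes.min() >= 1 and sizes.max() <= 14

    def test_fixture_mode_rejects_other_n(self):
        with pytest.raises(ValueError, match="545"):
            sample_cluster_sizes(100, "fixture")

    def test_degenerate_distribution(self):
        probs = np.zeros(14)
        probs[0] = 1.0
        assert (sample_cluster_sizes(50, probs, rng=0) == 1).all()

    def test_sampled_mean_matches_expectation(self):
        sizes = sample_cluster_sizes(100_000, rating_count_probabilities(), rng=1)
        assert abs(sizes.mean() - 2992 / 545) < 0.05


class TestLatents:
    def test_perfect_correlation(self):
        lat = generate_latents(200, 1.0, rng=0)
        np.testing.assert_allclose(lat[:, 0], lat[:, 1])

    @pytest.mark.parametrize("r", [0.0, 0.8])
    def test_sample_correlation(self, r):
        lat = generate_latents(50_000, r, rng=3)
        assert abs(np.corrcoef(lat.T)[0, 1] - r) < 0.02


class TestDailyItems:
    def test_degenerate_equals_intercept(self):
        p = default_parameters().copy(
            phq9_loadings=np.zeros(9),
            daily_between_loading=0.0,
            daily_within_loading=0.0,
            daily_between_residuals=np.zeros(2),
            daily_within_residuals=np.full(2, 1e-20),
            latent_corr=0.0,
        )
        lat = generate_latents(20, 0.0, rng=0)
        daily = generate_daily_items(lat, np.full(20, 3), p, rng=0)
        np.testing.assert_allclose(daily["item1"], 2.20, atol=1e-8)
        np.testing.assert_allclose(daily["item2"], 2.20, atol=1e-8)

    def test_within_covariance_matches_model(self):
        p = default_parameters()
        n = 20_000
        lat = generate_latents(n, 0.8, rng=5)
        daily = generate_daily_items(lat, np.full(n, 4), p, rng=5)
        wide = daily[["person_id", "item1", "item2"]]
        centered = wide.groupby("person_id").transform(lambda s: s - s.mean())
        pooled = centered.to_numpy()
        # pooled within covariance with Sum (n_j - 1) denominator
        cov = pooled.T @ pooled / (n * (4 - 1))
        lam, th = 0.66, 0.20
        np.testing.assert_allclose(cov[0, 1], lam * lam, rtol=0.02)
        np.testing.assert_allclose(np.diag(cov), lam * lam + th, rtol=0.02)

    def test_full_window_occupied(self):
        lat = generate_latents(1, 0.0, rng=0)
        daily = generate_daily_items(lat, np.array([14]), default_parameters(), rng=0)
        assert sorted(daily["day"]) == list(range(14, 28))


class TestQuestionnaire:
    def test_degenerate_sum_is_intercept_total(self):
        p = default_parameters().copy(
            phq9_loadings=np.zeros(9), phq9_residuals=np.full(9, 1e-20)
        )
        lat = generate_latents(10, 0.0, rng=0)
        panel = generate_questionnaire(lat, p, rng=0)
        np.testing.assert_allclose(panel["phq9_sum"], 8.51, atol=1e-6)

    def test_item_covariance_matches_loadings(self):
        lat = generate_latents(20_000, 0.8, rng=2)
        panel = generate_questionnaire(lat, default_parameters(), rng=2)
        cov = np.cov(panel["phq1"], panel["phq2"])[0, 1]
        np.testing.assert_allclose(cov, 0.60 * 0.63, rtol=0.02)

    def test_latent_shift_moves_means_by_loadings(self):
        p = default_parameters()
        lat = generate_latents(30_000, 0.0, rng=9)
        base = generate_questionnaire(lat, p, rng=11)
        shifted = generate_questionnaire(
            np.column_stack([lat[:, 0], lat[:, 1] + 1.0]), p, rng=11
        )
        for i in range(9):
            delta = shifted[f"phq{i+1}"].mean() - base[f"phq{i+1}"].mean()
            assert abs(delta - p.phq9_loadings[i]) < 1e-9  # same noise stream


class TestBaseline:
    def test_no_floor_plain_normal(self):
        x = generate_baseline(20_000, 13.9, 5.0, eligibility_floor=None, rng=0)
        assert abs(x.mean() - 13.9) < 0.1

    def test_truncated_mean_hits_target(self):
        x = generate_baseline(20_000, 13.9, 5.0, eligibility_floor=5.0, rng=1)
        assert abs(x.mean() - 13.9) < 0.1
        assert x.min() >= 5.0

    def test_calibrated_pretruncation_mean_below_target(self):
        m = calibrate_truncation_mean(13.9, 5.0, 5.0)
        assert m < 13.9

    def test_infeasible_floor_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_truncation_mean(3.0, 1.0, 10.0)


class TestOutcomes:
    def test_zero_residual_gives_exact_linearity(self):
        panel4 = pd.DataFrame(
            {"person_id": list("abcd"), "phq9_sum": [5.0, 10.0, 15.0, 20.0]}
        )
        out = generate_outcomes(
            panel4, None, {"intercept": 1.0, "phq9_week4": 0.5},
            {"intercept": 0.0, "phq9_week4": 2.0}, np.zeros((2, 2)), rng=0,
        )
        np.testing.assert_allclose(out["phq9_sum"], 1.0 + 0.5 * panel4["phq9_sum"])
        np.testing.assert_allclose(out["sds_sum"], 2.0 * panel4["phq9_sum"])

    def test_mcar_deletion_rate(self):
        panel4 = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(10_000)], "phq9_sum": 10.0}
        )
        out = generate_outcomes(
            panel4, None, {"intercept": 0.0}, {"intercept": 0.0},
            np.eye(2), rng=0, missing_rate=0.35,
        )
        # binomial(10000, 0.65): +-4 sd ~ 190
        assert abs(len(out) - 6500) < 200

    def test_calibration_residuals_match_targets(self):
        c1, c2, cov = calibrate_outcome_model(default_parameters())
        var_x = default_parameters().phq9_sum_moments()[1]
        r2 = c1["phq9_week4"] ** 2 * var_x / (
            c1["phq9_week4"] ** 2 * var_x + cov[0, 0]
        )
        assert abs(r2 - 0.49) < 1e-12


class TestCohort:
    def test_same_seed_identical(self):
        a = generate_cohort(GeneratorConfig(seed=3))
        b = generate_cohort(GeneratorConfig(seed=3))
        pd.testing.assert_frame_equal(a.daily, b.daily)
        pd.testing.assert_frame_equal(a.panel, b.panel)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(seed=3))
        b = generate_cohort(GeneratorConfig(seed=4))
        assert not a.daily["item1"].equals(b.daily["item1"])

    def test_every_person_has_anchor_week_row(self, fixture_cohort):
        panel = fixture_cohort.panel
        wk4 = panel[panel["week"] == 4]
        assert set(wk4["person_id"]) == set(fixture_cohort.truth["person_id"])

    def test_truth_alignment_recovers_loadings(self):
        """Regressing generated items on the retained latents gives back the
        generating loadings (oracle use of the truth table)."""
        cfg = GeneratorConfig(
            n_persons=20_000,
            cluster_size_distribution=rating_count_probabilities(),
            seed=11,
        )
        coh = generate_cohort(cfg)
        wk4 = coh.panel[coh.panel["week"] == 4].sort_values("person_id")
        truth = coh.truth.sort_values("person_id")
        xi = truth["xi"].to_numpy()
        for i, lam in enumerate(cfg.params.phq9_loadings):
            slope = np.polyfit(xi, wk4[f"phq{i+1}"].to_numpy(), 1)[0]
            assert abs(slope - lam) < 0.03

    def test_discretize_attenuates_covariance(self):
        kw = dict(
            n_persons=20_000,
            cluster_size_distribution=rating_count_probabilities(),
            seed=13,
        )
        cont = generate_cohort(GeneratorConfig(**kw))
        disc = generate_cohort(GeneratorConfig(discretize=True, **kw))
        def item_cov(coh):
            wk4 = coh.panel[coh.panel["week"] == 4]
            return np.cov(wk4["phq1"], wk4["phq2"])[0, 1]
        assert 0 < abs(item_cov(disc)) < abs(item_cov(cont))
        disc_daily = disc.daily[["item1", "item2"]]
        assert set(np.unique(disc_daily)) <= set(range(1, 6))

    def test_group_offsets_shift_parameters(self):
        cfg = GeneratorConfig(
            n_persons=4000,
            cluster_size_distribution=rating_count_probabilities(),
            seed=5,
            group_offsets={
                "column": "gender", "level": "man",
                "phq9_intercepts": np.full(9, 1.0),
            },
        )
        coh = generate_cohort(cfg)
        wk4 = coh.panel[coh.panel["week"] == 4]
        men = wk4[wk4["gender"] == "man"]["phq9_sum"].mean()
        women = wk4[wk4["gender"] == "woman"]["phq9_sum"].mean()
        assert 8.0 < men - women < 10.0  # 9 intercepts shifted by +1
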