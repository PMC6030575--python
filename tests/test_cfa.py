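"""The FIML engine: likelihood oracle checks, nesting, fit indices, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phqdaily import cfa, simulate
from phqdaily.cfa import ModelSpec, compute_fit_indices
from phqdaily.params import default_parameters


def _zero_params():
    return default_parameters().copy(
        phq9_loadings=np.zeros(9),
        phq9_intercepts=np.zeros(9),
        phq9_residuals=np.ones(9),
        daily_between_loading=0.0,
        daily_intercepts=np.zeros(2),
        daily_between_residuals=np.zeros(2),
        daily_within_loading=0.0,
        daily_within_residuals=np.ones(2),
        latent_corr=0.0,
    )


def _random_params(rng):
    return default_parameters().copy(
        phq9_loadings=rng.uniform(0.3, 0.8, 9),
        phq9_intercepts=rng.uniform(0.2, 1.5, 9),
        phq9_residuals=rng.uniform(0.2, 0.6, 9),
        daily_between_loading=rng.uniform(0.5, 0.9),
        daily_intercepts=rng.uniform(1.5, 2.5, 2),
        daily_between_residuals=rng.uniform(0.05, 0.3, 2),
        daily_within_loading=rng.uniform(0.4, 0.8),
        daily_within_residuals=rng.uniform(0.1, 0.4, 2),
        latent_corr=rng.uniform(-0.9, 0.9),
    )


def _dense_person_loglik(params, z, y):
    """Independent oracle: assemble the person's full covariance entry by
    entry from the factor structure and use the dense MVN density."""
    lam9 = params.phq9_loadings
    lam_b = np.full(2, params.daily_between_loading)
    lam_w = np.full(2, params.daily_within_loading)
    r = params.latent_corr
    n = 0 if y is None else y.shape[0]
    d = (9 if z is not None else 0) + 2 * n
    cov = np.zeros((d, d))
    mean = np.zeros(d)
    q = 9 if z is not None else 0
    if z is not None:
        for a in range(9):
            mean[a] = params.phq9_intercepts[a]
            for b in range(9):
                cov[a, b] = lam9[a] * lam9[b]
            cov[a, a] += params.phq9_residuals[a]
    for i in range(n):
        for a in range(2):
            row = q + 2 * i + a
            mean[row] = params.daily_intercepts[a]
            if z is not None:
                for b in range(9):
                    cov[row, b] = cov[b, row] = lam9[b] * r * lam_b[a]
            for i2 in range(n):
                for b in range(2):
                    col = q + 2 * i2 + b
                    cov[row, col] += lam_b[a] * lam_b[b] + (
                        params.daily_between_residuals[a] if a == b else 0.0
                    )
                    if i2 == i:
                        cov[row, col] += lam_w[a] * lam_w[b] + (
                            params.daily_within_residuals[a] if a == b else 0.0
                        )
    obs = np.concatenate(([] if z is None else [z]) + ([] if y is None else [y.ravel()]))
    return stats.multivariate_normal.logpdf(obs, mean=mean, cov=cov)


class TestMarginalLoglik:
    def test_standard_normal_mode(self):
        """One person, one day, null model: two independent N(0,1) at 0."""
        daily = pd.DataFrame(
            {"person_id": ["a"], "day": [20], "item1": [0.0], "item2": [0.0]}
        )
        ll = cfa.marginal_loglik(
            _zero_params(), daily, None, ModelSpec(questionnaire=False)
        )
        np.testing.assert_allclose(ll, -np.log(2 * np.pi), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_oracle(self, seed):
        """Structured likelihood equals the dense MVN density on small data."""
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        n_persons = int(rng.integers(1, 6))
        drows, prows = [], []
        expected = 0.0
        for j in range(n_persons):
            pid = f"p{j}"
            has_z = rng.random() < 0.8 or seed == 0
            n_days = int(rng.integers(0 if has_z else 1, 5))
            z = rng.normal(1.0, 1.0, 9) if has_z else None
            y = rng.normal(2.0, 1.0, (n_days, 2)) if n_days else None
            if z is not None:
                prows.append([pid, 4, *z, z.sum(), np.nan, "woman", "<55", "no"])
            if y is not None:
                for i, (a, b) in enumerate(y):
                    drows.append([pid, 14 + i, a, b])
            expected += _dense_person_loglik(params, z, y)
        daily = pd.DataFrame(
            drows, columns=["person_id", "day", "item1", "item2"]
        ) if drows else None
        panel = pd.DataFrame(
            prows,
            columns=["person_id", "week"] + [f"phq{i}" for i in range(1, 10)]
            + ["phq9_sum", "sds_sum", "gender", "age_band", "minority"],
        ) if prows else None
        ll = cfa.marginal_loglik(params, daily, panel)
        np.testing.assert_allclose(ll, expected, rtol=0, atol=1e-8)

    def test_translation_invariance(self):
        """Shifting intercepts and observations together leaves ll unchanged."""
        rng = np.random.default_rng(3)
        params = _random_params(rng)
        daily = pd.DataFrame(
            {"person_id": ["a"] * 3, "day": [20, 21, 22],
             "item1": [1.0, 2.0, 3.0], "item2": [2.0, 2.5, 1.5]}
        )
        spec = ModelSpec(questionnaire=False)
        ll1 = cfa.marginal_loglik(params, daily, None, spec)
        shifted = params.copy(daily_intercepts=params.daily_intercepts + 5.0)
        daily2 = daily.assign(item1=daily["item1"] + 5.0, item2=daily["item2"] + 5.0)
        ll2 = cfa.marginal_loglik(shifted, daily2, None, spec)
        np.testing.assert_allclose(ll1, ll2, rtol=1e-12)


class TestNestingAndCounts:
    def test_nesting_chain_and_free_counts(self, small_tables):
        daily, panel = small_tables
        spec = ModelSpec()
        data = cfa.stack_data(daily, panel, spec)
        fit = cfa.fit_mlcfa(daily, panel, spec, compute_se=False)
        sat = cfa.fit_saturated(None, None, spec, data=data)
        base = cfa.fit_baseline(None, None, spec, data=data)
        assert base.loglik <= fit.loglik <= sat.loglik
        # 11 means + 66 between + 3 within; 11 means + 11 + 2 variances
        assert sat.n_free == 80
        assert base.n_free == 24
        assert fit.n_free == 36

    def test_saturated_matches_balanced_closed_form(self):
        """Balanced clusters: ML has a closed form via the between/within
        decomposition; the optimizer must reach its likelihood."""
        rng = np.random.default_rng(0)
        n_per, n_days = 120, 3
        params = default_parameters()
        lat = simulate.generate_latents(n_per, 0.8, rng)
        daily = simulate.generate_daily_items(
            lat, np.full(n_per, n_days), params, rng=rng
        )
        panel = simulate.generate_questionnaire(lat, params, rng=rng)
        for c, v in (("sds_sum", np.nan), ("gender", "woman"),
                     ("age_band", "<55"), ("minority", "no")):
            panel[c] = v
        spec = ModelSpec()
        data = cfa.stack_data(daily, panel, spec)

        # closed form: v_j = (z_j, ybar_j); Sigma_w from within deviations
        wk4 = panel.sort_values("person_id")
        z = wk4[[f"phq{i}" for i in range(1, 10)]].to_numpy()
        y = (
            daily.sort_values(["person_id", "day"])[["item1", "item2"]]
            .to_numpy()
            .reshape(n_per, n_days, 2)
        )
        ybar = y.mean(axis=1)
        dev = (y - ybar[:, None, :]).reshape(-1, 2)
        sw = dev.T @ dev / (n_per * (n_days - 1))
        v = np.hstack([z, ybar])
        mu = v.mean(axis=0)
        cov_v = (v - mu).T @ (v - mu) / n_per
        sb = cov_v.copy()
        sb[9:, 9:] -= sw / n_days
        ll_closed = cfa.loglik_from_moments(mu, sb, sw, data)

        sat = cfa.fit_saturated(None, None, spec, data=data)
        np.testing.assert_allclose(sat.loglik, ll_closed, rtol=0, atol=1e-4)
        assert sat.loglik >= ll_closed - 1e-4

    def test_baseline_matches_null_data(self):
        """With all loadings zero the independence model is true: the full
        model cannot beat it by more than chi-square noise."""
        rng = np.random.default_rng(4)
        params = _zero_params().copy(
            daily_between_residuals=np.array([0.3, 0.3]),
            phq9_intercepts=np.full(9, 1.0),
            daily_intercepts=np.array([2.0, 2.0]),
        )
        n = 300
        lat = simulate.generate_latents(n, 0.0, rng)
        daily = simulate.generate_daily_items(lat, np.full(n, 4), params, rng=rng)
        panel = simulate.generate_questionnaire(lat, params, rng=rng)
        for c, v in (("sds_sum", np.nan), ("gender", "woman"),
                     ("age_band", "<55"), ("minority", "no")):
            panel[c] = v
        spec = ModelSpec()
        data = cfa.stack_data(daily, panel, spec)
        fit = cfa.fit_mlcfa(daily, panel, spec, compute_se=False)
        base = cfa.fit_baseline(None, None, spec, data=data)
        gain = 2 * (fit.loglik - base.loglik)
        df_gain = fit.n_free - base.n_free
        assert gain < stats.chi2.ppf(0.999, df_gain) + 10
        # identified null signal: implied item covariances lam_i*lam_j near 0
        # (individual loadings trade off against residuals when truly null)
        lam = fit.params.phq9_loadings
        prod = np.abs(np.outer(lam, lam))
        np.fill_diagonal(prod, 0.0)
        assert prod.max() < 0.2


class TestFitIndices:
    def test_saturated_model_is_perfect(self):
        idx = compute_fit_indices(0.0, 0, 1000.0, 50, 500)
        assert not idx.defined  # df=0 flagged
        idx = compute_fit_indices(44.0, 44.0, 1000.0, 56, 545)
        assert idx.rmsea == 0.0 and idx.cfi == 1.0

    def test_formula_values(self):
        idx = compute_fit_indices(200.0, 100, 1100.0, 120, 500)
        np.testing.assert_allclose(idx.cfi, 0.8980, atol=5e-5)
        np.testing.assert_allclose(idx.tli, 0.8776, atol=5e-5)
        np.testing.assert_allclose(idx.rmsea, 0.0447, atol=5e-5)

    def test_limit_near_perfect_fit(self):
        idx = compute_fit_indices(101.0, 100, 1100.0, 120, 500)
        assert idx.cfi > 0.998 and idx.tli > 0.998


class TestFitMlcfa:
    def test_recovery_smoke(self, small_tables):
        daily, panel = small_tables
        fit = cfa.fit_mlcfa(daily, panel, compute_se=False)
        assert fit.converged
        p = default_parameters()
        assert abs(fit.params.latent_corr - 0.8) < 0.15
        assert abs(fit.params.daily_within_loading - p.daily_within_loading) < 0.1
        np.testing.assert_allclose(
            fit.params.phq9_loadings, p.phq9_loadings, atol=0.25
        )

    def test_duplicated_data_same_estimates_smaller_ses(self):
        rng = np.random.default_rng(8)
        params = default_parameters()
        n = 250
        lat = simulate.generate_latents(n, 0.8, rng)
        sizes = rng.integers(3, 8, size=n)
        daily = simulate.generate_daily_items(lat, sizes, params, rng=rng)
        spec = ModelSpec(questionnaire=False)
        fit1 = cfa.fit_mlcfa(daily, None, spec)
        doubled = pd.concat(
            [daily, daily.assign(person_id="dup_" + daily["person_id"])],
            ignore_index=True,
        )
        fit2 = cfa.fit_mlcfa(doubled, None, spec)
        np.testing.assert_allclose(
            fit2.params.daily_between_loading,
            fit1.params.daily_between_loading,
            atol=1e-3,
        )
        ratio = fit2.se.daily_between_loading / fit1.se.daily_between_loading
        np.testing.assert_allclose(ratio, 1 / np.sqrt(2), atol=0.03)

    def test_rescaling_equivariance(self):
        """Multiplying the daily items by c rescales loadings and residual
        SDs by c and leaves r and the chi-square unchanged."""
        rng = np.random.default_rng(12)
        params = default_parameters()
        n = 250
        lat = simulate.generate_latents(n, 0.8, rng)
        sizes = rng.integers(2, 8, size=n)
        daily = simulate.generate_daily_items(lat, sizes, params, rng=rng)
        panel = simulate.generate_questionnaire(lat, params, rng=rng)
        for cname, v in (("sds_sum", np.nan), ("gender", "woman"),
                         ("age_band", "<55"), ("minority", "no")):
            panel[cname] = v
        c = 2.0
        scaled = daily.assign(item1=daily["item1"] * c, item2=daily["item2"] * c)

        spec = ModelSpec()
        f1 = cfa.fit_mlcfa(daily, panel, spec, compute_se=False)
        f2 = cfa.fit_mlcfa(scaled, panel, spec, compute_se=False)
        assert abs(f2.params.latent_corr - f1.params.latent_corr) < 1e-3
        np.testing.assert_allclose(
            f2.params.daily_between_loading,
            c * f1.params.daily_between_loading, rtol=1e-3,
        )
        np.testing.assert_allclose(
            np.sqrt(f2.params.daily_within_residuals),
            c * np.sqrt(f1.params.daily_within_residuals), rtol=5e-3,
        )
        d1 = cfa.stack_data(daily, panel, spec)
        d2 = cfa.stack_data(scaled, panel, spec)
        chi1 = 2 * (cfa.fit_saturated(None, None, spec, data=d1).loglik - f1.loglik)
        chi2_ = 2 * (cfa.fit_saturated(None, None, spec, data=d2).loglik - f2.loglik)
        assert abs(chi1 - chi2_) < 0.5

    def test_constraint_release_never_hurts(self, small_tables):
        """Freeing the equal-daily-item constraint cannot lower the loglik."""
        daily, panel = small_tables
        tight = cfa.fit_mlcfa(
            daily, panel, ModelSpec(equal_daily_item_params=True), compute_se=False
        )
        loose = cfa.fit_mlcfa(daily, panel, ModelSpec(), compute_se=False)
        assert loose.loglik >= tight.loglik - 1e-4
        assert loose.n_free == tight.n_free + 3
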