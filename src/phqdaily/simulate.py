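"""Synthetic cohort generator with the statistical structure of an
intensive-longitudinal depression-monitoring study.

The generator emulates a cohort of moderately depressed adults who rate
their mood daily on a 2-item scale for the two weeks before a 9-item
questionnaire at the anchor week, and complete outcome questionnaires four
weeks later:

* ratings-per-person follows an empirical 1..14 distribution (fixture mode
  reproduces the emulated study's counts exactly: 545 persons, 2992 rows);
* per-person latent severities (eta_b, xi) are bivariate standard normal
  with correlation r;
* daily items follow the two-level measurement model, questionnaire items
  the single-level model, both from a :class:`~phqdaily.params.ParameterSet`;
* baseline severity is a floor-truncated normal calibrated so the
  post-truncation mean hits a target (screening eligibility);
* week-8 outcomes are a bivariate linear model in week-4 predictors with
  correlated errors and optional MCAR missingness.

Continuous mode (default) keeps responses on the latent-linear scale so
sample moments converge to the model-implied moments; ``discretize``
rounds and clips to the Likert ranges, which attenuates covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import (
    DEFAULT_LATENT_CORR,
    DEFAULT_RATING_COUNTS,
    N_DAILY,
    N_PHQ9,
    ParameterSet,
    default_parameters,
    rating_count_probabilities,
)
from .io import PHQ_ITEM_COLUMNS

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "sample_cluster_sizes",
    "generate_latents",
    "generate_daily_items",
    "generate_questionnaire",
    "generate_baseline",
    "calibrate_truncation_mean",
    "generate_outcomes",
    "calibrate_outcome_model",
    "generate_cohort",
]

FIXTURE_N_PERSONS = sum(DEFAULT_RATING_COUNTS.values())
WINDOW_DAYS = 14


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the emulated study: 545 persons, the empirical
    ratings-per-person distribution, published measurement parameters,
    latent correlation 0.80, eligibility floor 5 on a baseline score with
    post-screening mean 13.9 (SD 5.0), and week-8 outcomes calibrated so a
    regression on the anchor-week questionnaire sum has population R^2
    0.49 (depression) and 0.37 (disability), with 35% of week-8 rows
    missing completely at random.
    """

    n_persons: int = FIXTURE_N_PERSONS
    cluster_size_distribution: str | np.ndarray = "fixture"
    params: ParameterSet = field(default_factory=default_parameters)
    latent_corr: float | None = None  # overrides params.latent_corr if set
    baseline_mean: float = 13.9
    baseline_sd: float = 5.0
    eligibility_floor: float | None = 5.0
    discretize: bool = False
    anchor_week: int = 4
    outcome_week: int = 8
    group_proportions: dict = field(
        default_factory=lambda: {"woman": 0.783, "minority": 0.381, "age_55plus": 0.061}
    )
    group_offsets: dict = field(default_factory=dict)
    outcome_slope_phq9: float = 0.7
    outcome_slope_sds: float = 2.7
    outcome_r2_phq9: float = 0.49
    outcome_r2_sds: float = 0.37
    outcome_resid_corr: float = 0.4
    outcome_daily_mean_slopes: tuple[float, float] = (0.0, 0.0)
    week8_missing_rate: float = 0.35
    seed: int = 0

    @property
    def anchor_day(self) -> int:
        return 7 * self.anchor_week

    def effective_corr(self) -> float:
        return self.params.latent_corr if self.latent_corr is None else self.latent_corr


@dataclass
class SyntheticCohort:
    daily: pd.DataFrame
    panel: pd.DataFrame
    truth: pd.DataFrame  # person_id, eta_b, xi, baseline, cluster_size
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# cluster sizes


def sample_cluster_sizes(
    n_persons: int,
    distribution="fixture",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Number of daily ratings per person, each in 1..14.

    ``distribution='fixture'`` reproduces the emulated study's exact counts
    (requires ``n_persons`` = 545); otherwise a probability table over
    1..14 is sampled i.i.d.
    """
    if isinstance(distribution, str) and distribution == "fixture":
        if n_persons != FIXTURE_N_PERSONS:
            raise ValueError(
                f"fixture mode is exact and requires n_persons={FIXTURE_N_PERSONS}"
            )
        sizes = np.repeat(
            list(DEFAULT_RATING_COUNTS.keys()), list(DEFAULT_RATING_COUNTS.values())
        )
        return np.sort(sizes)
    probs = np.asarray(distribution, dtype=float)
    if probs.shape != (WINDOW_DAYS,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("distribution must be a length-14 probability table")
    rng = np.random.default_rng(rng)
    return rng.choice(np.arange(1, WINDOW_DAYS + 1), size=n_persons, p=probs)


# ---------------------------------------------------------------------------
# latents and measurement blocks


def generate_latents(
    n_persons: int, r: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """(eta_b, xi) pairs from a standard bivariate normal with correlation r."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    rng = np.random.default_rng(rng)
    z = rng.standard_normal((n_persons, 2))
    eta_b = z[:, 0]
    xi = r * z[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * z[:, 1]
    return np.column_stack([eta_b, xi])


def generate_daily_items(
    latents: np.ndarray,
    sizes: np.ndarray,
    params: ParameterSet,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Long daily table from the two-level measurement model.

    y_ji = nu + lam_b*eta_bj + lam_w*eta_wij + eps_bj + eps_wij with a fresh
    day factor eta_wij ~ N(0,1) shared by the two items within a day, a
    person-level residual shared across days, and a day-level residual.
    Day offsets are sampled uniformly without replacement from the 14-day
    window preceding the anchor day.
    """
    cfg = cfg or GeneratorConfig()
    if np.any(np.asarray(params.daily_between_residuals) < 0) or np.any(
        np.asarray(params.daily_within_residuals) < 0
    ):
        raise ValueError("residual variances must be non-negative")
    if len(latents) != len(sizes):
        raise ValueError("latents and sizes must be aligned")
    rng = np.random.default_rng(rng)
    anchor = cfg.anchor_day
    rows = []
    nu = params.daily_intercepts
    lam_b = params.daily_between_loading
    lam_w = params.daily_within_loading
    sd_b = np.sqrt(params.daily_between_residuals)
    sd_w = np.sqrt(params.daily_within_residuals)
    for j, (eta_b, n_j) in enumerate(zip(latents[:, 0], sizes)):
        n_j = int(n_j)
        days = np.sort(rng.choice(WINDOW_DAYS, size=n_j, replace=False)) + (
            anchor - WINDOW_DAYS
        )
        eps_b = rng.standard_normal(N_DAILY) * sd_b
        eta_w = rng.standard_normal(n_j)
        eps_w = rng.standard_normal((n_j, N_DAILY)) * sd_w
        y = nu + lam_b * eta_b + eps_b + lam_w * eta_w[:, None] + eps_w
        if cfg.discretize:
            y = np.clip(np.rint(y), 1, 5)
        for d, (y1, y2) in zip(days, y):
            rows.append((f"p{j:06d}", int(d), y1, y2))
    return pd.DataFrame(rows, columns=["person_id", "day", "item1", "item2"])


def generate_questionnaire(
    latents: np.ndarray,
    params: ParameterSet,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Anchor-week questionnaire items z_j = tau + Lambda xi_j + delta_j."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(rng)
    n = len(latents)
    xi = latents[:, 1]
    delta = rng.standard_normal((n, N_PHQ9)) * np.sqrt(params.phq9_residuals)
    z = params.phq9_intercepts + np.outer(xi, params.phq9_loadings) + delta
    if cfg.discretize:
        z = np.clip(np.rint(z), 0, 3)
    df = pd.DataFrame(z, columns=PHQ_ITEM_COLUMNS)
    df.insert(0, "person_id", [f"p{j:06d}" for j in range(n)])
    df.insert(1, "week", cfg.anchor_week)
    df["phq9_sum"] = z.sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# baseline screening scores


def calibrate_truncation_mean(
    target_mean: float, sd: float, floor: float
) -> float:
    """Pre-truncation mean m such that E[X | X >= floor] = target for
    X ~ N(m, sd^2).  Truncation from below raises the mean, so m < target."""
    if floor > target_mean + 3.0 * sd:
        raise ValueError("infeasible calibration: floor above target mean + 3 sd")

    def trunc_mean(m):
        a = (floor - m) / sd
        return m + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    lo, hi = target_mean - 20.0 * sd, target_mean
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi))


def generate_baseline(
    n_persons: int,
    baseline_mean: float = 13.9,
    baseline_sd: float = 5.0,
    eligibility_floor: float | None = 5.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Baseline questionnaire sums after eligibility screening.

    Draws from a normal whose pre-truncation mean is calibrated so the mean
    of draws at or above the floor equals ``baseline_mean``; scores are
    clipped to the 0-27 scale.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be > 0")
    rng = np.random.default_rng(rng)
    if eligibility_floor is None or np.isneginf(eligibility_floor):
        x = rng.normal(baseline_mean, baseline_sd, size=n_persons)
    else:
        m = calibrate_truncation_mean(baseline_mean, baseline_sd, eligibility_floor)
        a = (eligibility_floor - m) / baseline_sd
        x = stats.truncnorm.rvs(
            a, np.inf, loc=m, scale=baseline_sd, size=n_persons, random_state=rng
        )
    return np.clip(x, 0.0, 27.0)


# ---------------------------------------------------------------------------
# week-8 outcomes


def calibrate_outcome_model(
    params: ParameterSet,
    r2_phq9: float = 0.49,
    r2_sds: float = 0.37,
    slope_phq9: float = 0.7,
    slope_sds: float = 2.7,
    resid_corr: float = 0.4,
    outcome_means: tuple[float, float] = (8.5, 15.0),
) -> tuple[dict, dict, np.ndarray]:
    """Coefficients and residual covariance hitting target population R^2.

    With outcome = b0 + b1*x + e and x the anchor-week questionnaire sum,
    R^2 = b1^2 var(x) / (b1^2 var(x) + sigma^2); the residual variance is
    solved from the model-implied var(x).
    """
    mean_x, var_x = params.phq9_sum_moments()
    sig2 = []
    coefs = []
    for r2, b1, mean_out in zip(
        (r2_phq9, r2_sds), (slope_phq9, slope_sds), outcome_means
    ):
        if not 0 < r2 < 1:
            raise ValueError("target R^2 must be in (0, 1)")
        explained = b1 ** 2 * var_x
        sig2.append(explained * (1.0 - r2) / r2)
        coefs.append({"intercept": mean_out - b1 * mean_x, "phq9_week4": b1})
    s1, s2 = np.sqrt(sig2)
    resid_cov = np.array(
        [[sig2[0], resid_corr * s1 * s2], [resid_corr * s1 * s2, sig2[1]]]
    )
    return coefs[0], coefs[1], resid_cov


def generate_outcomes(
    panel_week4: pd.DataFrame,
    summaries: pd.DataFrame | None,
    coef_phq9: dict,
    coef_sds: dict,
    resid_cov: np.ndarray,
    rng: np.random.Generator | int | None = None,
    missing_rate: float = 0.0,
    outcome_week: int = 8,
) -> pd.DataFrame:
    """Week-8 outcome rows: (phq9_sum, sds_sum) = B x + e, e ~ N(0, Sigma_e).

    Predictor names in the coefficient dicts are resolved against the
    anchor-week panel (``phq9_week4``) and the daily summary table
    (``daily_mean``, ``daily_sd``, ...).  ``missing_rate`` deletes rows
    completely at random.
    """
    resid_cov = np.asarray(resid_cov, dtype=float)
    if np.any(np.linalg.eigvalsh(resid_cov) < -1e-12):
        raise ValueError("residual covariance must be positive semidefinite")
    rng = np.random.default_rng(rng)

    pred = pd.DataFrame({"person_id": panel_week4["person_id"].to_numpy()})
    pred["intercept"] = 1.0
    pred["phq9_week4"] = panel_week4["phq9_sum"].to_numpy()
    if summaries is not None:
        s = summaries.rename(
            columns={
                c: f"daily_{c}" for c in ("mean", "sd", "min", "max", "slope")
            }
        )
        pred = pred.merge(s, on="person_id", how="left")

    n = len(pred)
    mean = np.zeros((n, 2))
    for k, coef in enumerate((coef_phq9, coef_sds)):
        for name, b in coef.items():
            if name not in pred.columns:
                raise ValueError(f"unknown predictor {name!r} in outcome model")
            mean[:, k] += b * pred[name].to_numpy(dtype=float)
    try:
        chol = np.linalg.cholesky(resid_cov)
    except np.linalg.LinAlgError:  # positive semidefinite boundary
        vals, vecs = np.linalg.eigh(resid_cov)
        chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    e = rng.standard_normal((n, 2)) @ chol.T
    out = mean + e
    keep = rng.random(n) >= missing_rate
    return pd.DataFrame(
        {
            "person_id": pred["person_id"].to_numpy()[keep],
            "week": outcome_week,
            "phq9_sum": out[keep, 0],
            "sds_sum": out[keep, 1],
        }
    )


# ---------------------------------------------------------------------------
# full cohort


def _assign_groups(n: int, proportions: dict, rng: np.random.Generator):
    gender = np.where(rng.random(n) < proportions.get("woman", 0.5), "woman", "man")
    minority = np.where(rng.random(n) < proportions.get("minority", 0.5), "yes", "no")
    age = np.where(rng.random(n) < proportions.get("age_55plus", 0.5), "55+", "<55")
    return gender, age, minority


def generate_cohort(cfg: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a complete cohort: daily table, 3-week panel, truth table."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    params = cfg.params
    r = cfg.effective_corr()

    sizes = sample_cluster_sizes(n, cfg.cluster_size_distribution, rng)
    latents = generate_latents(n, r, rng)
    daily = generate_daily_items(latents, sizes, params, cfg, rng)
    panel4 = generate_questionnaire(latents, params, cfg, rng)

    gender, age, minority = _assign_groups(n, cfg.group_proportions, rng)
    labels = pd.DataFrame(
        {
            "person_id": panel4["person_id"],
            "gender": gender,
            "age_band": age,
            "minority": minority,
        }
    )
    if cfg.group_offsets:
        daily, panel4 = _apply_group_offsets(daily, panel4, labels, cfg, latents, rng)

    baseline = generate_baseline(
        n, cfg.baseline_mean, cfg.baseline_sd, cfg.eligibility_floor, rng
    )
    panel0 = pd.DataFrame(
        {"person_id": panel4["person_id"], "week": 0, "phq9_sum": baseline}
    )

    from .prediction import summarize_daily

    summaries = summarize_daily(daily, cfg.anchor_day, WINDOW_DAYS)
    coef1, coef2, resid_cov = calibrate_outcome_model(
        params,
        cfg.outcome_r2_phq9,
        cfg.outcome_r2_sds,
        cfg.outcome_slope_phq9,
        cfg.outcome_slope_sds,
        cfg.outcome_resid_corr,
    )
    b_daily1, b_daily2 = cfg.outcome_daily_mean_slopes
    if b_daily1:
        coef1["daily_mean"] = b_daily1
    if b_daily2:
        coef2["daily_mean"] = b_daily2
    panel8 = generate_outcomes(
        panel4,
        summaries,
        coef1,
        coef2,
        resid_cov,
        rng,
        missing_rate=cfg.week8_missing_rate,
        outcome_week=cfg.outcome_week,
    )

    panel = pd.concat([panel0, panel4, panel8], ignore_index=True)
    panel = panel.merge(labels, on="person_id", how="left")
    for col in PHQ_ITEM_COLUMNS + ["sds_sum"]:
        if col not in panel.columns:
            panel[col] = np.nan
    from .io import PANEL_COLUMNS

    panel = panel.loc[:, PANEL_COLUMNS].sort_values(
        ["person_id", "week"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "person_id": panel4["person_id"],
            "eta_b": latents[:, 0],
            "xi": latents[:, 1],
            "baseline": baseline,
            "cluster_size": sizes,
        }
    )
    return SyntheticCohort(daily=daily, panel=panel, truth=truth, config=cfg)


def _apply_group_offsets(daily, panel4, labels, cfg, latents, rng):
    """Shift measurement parameters for one labelled group.

    ``cfg.group_offsets`` maps a (column, level) pair to additive offsets,
    e.g. ``{"column": "gender", "level": "man", "phq9_loadings": -0.3}``.
    Implemented by regenerating the affected persons' blocks under the
    offset parameter set (latents held fixed).
    """
    off = cfg.group_offsets
    col, level = off["column"], off["level"]
    mask = (labels[col] == level).to_numpy()
    params2 = cfg.params.copy(
        **{
            k: getattr(cfg.params, k) + np.asarray(v)
            for k, v in off.items()
            if k not in ("column", "level")
        }
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return daily, panel4
    sub_lat = latents[idx]
    # regenerate questionnaire rows for the offset group
    sub_panel = generate_questionnaire(sub_lat, params2, cfg, rng)
    ids = panel4["person_id"].to_numpy()[idx]
    sub_panel["person_id"] = ids
    panel4 = panel4.copy()
    keep = ~panel4["person_id"].isin(ids)
    panel4 = (
        pd.concat([panel4[keep], sub_panel], ignore_index=True)
        .sort_values("person_id", kind="stable")
        .reset_index(drop=True)
    )
    # regenerate daily rows for the offset group
    id_set = set(ids)
    sizes = daily.groupby("person_id").size()
    sub_sizes = sizes.loc[list(ids)].to_numpy()
    sub_daily = generate_daily_items(sub_lat, sub_sizes, params2, cfg, rng)
    sub_daily["person_id"] = np.repeat(ids, sub_sizes)
    daily = (
        pd.concat([daily[~daily["person_id"].isin(id_set)], sub_daily],
                  ignore_index=True)
        .sort_values(["person_id", "day"], kind="stable")
        .reset_index(drop=True)
    )
    return daily, panel4
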