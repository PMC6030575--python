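"""Daily-summary predictors and seemingly-unrelated regression of later
outcomes.

Each person's daily 2-item ratings in the 14-day window are reduced to a
composite (the mean of the two items) and summarized by mean, SD, min, max
and least-squares slope per day.  Four regression models predict the
week-8 questionnaire and disability sums from week-4 information:

1. anchor-week questionnaire sum only;
2. daily mean only;
3. both;
4. daily mean, slope, max, min and SD.

The two outcome equations are estimated jointly by seemingly unrelated
regression (two-step feasible GLS; optionally iterated).  All four models
use identical regressors in both equations, so by Kruskal's theorem the
SUR point estimates coincide with per-equation OLS — the joint fit still
supplies the cross-equation residual covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MODEL_PREDICTORS",
    "summarize_daily",
    "build_model_matrices",
    "SURResult",
    "fit_sur",
    "predict_report",
]

EQUATIONS = ("phq9_week8", "sds_week8")

MODEL_PREDICTORS: dict[int, list[str]] = {
    1: ["phq9_week4"],
    2: ["daily_mean"],
    3: ["phq9_week4", "daily_mean"],
    4: ["daily_mean", "daily_slope", "daily_max", "daily_min", "daily_sd"],
}


def summarize_daily(
    daily: pd.DataFrame, anchor_day: int = 28, window_days: int = 14
) -> pd.DataFrame:
    """Per-person summaries of the daily composite over the window.

    The composite day score is the mean of the two items.  SD is the
    sample (n-1) standard deviation and the slope is the least-squares
    trend of the composite on the calendar-day offset; both are missing
    when a person has fewer than two in-window days.
    """
    lo = anchor_day - window_days
    d = daily[(daily["day"] >= lo) & (daily["day"] < anchor_day)].copy()
    if d.empty:
        raise ValueError("no in-window daily ratings; filters must run upstream")
    d["score"] = d[["item1", "item2"]].mean(axis=1)

    rows = []
    for pid, grp in d.groupby("person_id", sort=True):
        s = grp["score"].to_numpy(dtype=float)
        days = grp["day"].to_numpy(dtype=float)
        n = len(s)
        if n >= 2 and len(np.unique(days)) >= 2:
            slope = float(np.polyfit(days, s, 1)[0])
            sd = float(np.std(s, ddof=1))
        else:
            slope = np.nan
            sd = np.nan
        rows.append(
            {
                "person_id": pid,
                "mean": float(s.mean()),
                "sd": sd,
                "min": float(s.min()),
                "max": float(s.max()),
                "slope": slope,
                "n_days": n,
            }
        )
    return pd.DataFrame(rows)


def build_model_matrices(
    panel: pd.DataFrame,
    summaries: pd.DataFrame,
    model_id: int,
    anchor_week: int = 4,
    outcome_week: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design and outcome matrices for one of the four models.

    Both equations share the design.  Persons missing any required
    predictor or either outcome are dropped listwise; the design includes
    an intercept column.
    """
    if model_id not in MODEL_PREDICTORS:
        raise ValueError("model_id must be 1, 2, 3 or 4")
    wk4 = panel[panel["week"] == anchor_week][["person_id", "phq9_sum"]].rename(
        columns={"phq9_sum": "phq9_week4"}
    )
    wk8 = panel[panel["week"] == outcome_week][
        ["person_id", "phq9_sum", "sds_sum"]
    ].rename(columns={"phq9_sum": "phq9_week8", "sds_sum": "sds_week8"})
    s = summaries.rename(
        columns={c: f"daily_{c}" for c in ("mean", "sd", "min", "max", "slope")}
    )
    merged = wk4.merge(s, on="person_id", how="left").merge(
        wk8, on="person_id", how="inner"
    )
    cols = MODEL_PREDICTORS[model_id]
    merged = merged.dropna(subset=cols + list(EQUATIONS)).reset_index(drop=True)
    if merged.empty:
        raise ValueError("empty design after listwise deletion")
    design = merged[["person_id"] + cols].copy()
    design.insert(1, "intercept", 1.0)
    outcomes = merged[["person_id"] + list(EQUATIONS)].copy()
    return design, outcomes


@dataclass
class SURResult:
    """Joint two-equation fit: coefficients, SEs, p-values, residual
    covariance, per-equation R-squared and the analysis N."""

    coef: dict[str, dict[str, float]]
    se: dict[str, dict[str, float]]
    pvalues: dict[str, dict[str, float]]
    resid_cov: np.ndarray
    r2: dict[str, float]
    n: int
    n_iterations: int
    loglik: float

    def as_dict(self) -> dict:
        return {
            "coef": self.coef,
            "se": self.se,
            "pvalues": self.pvalues,
            "resid_cov": self.resid_cov.tolist(),
            "r2": self.r2,
            "n": self.n,
            "n_iterations": self.n_iterations,
            "loglik": self.loglik,
        }


def _concentrated_loglik(resid: np.ndarray) -> float:
    """Gaussian log-likelihood concentrated over the residual covariance."""
    n = resid.shape[0]
    sigma = resid.T @ resid / n
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    return -0.5 * n * (2 * (1 + np.log(2 * np.pi)) + logdet)


def fit_sur(
    designs: pd.DataFrame | list[pd.DataFrame],
    outcomes: pd.DataFrame,
    iterate: bool = False,
    max_iterations: int = 50,
    tol: float = 1e-10,
) -> SURResult:
    """Two-step feasible-GLS seemingly unrelated regression.

    ``designs`` is one design shared by both equations or a list of one
    per equation; person_id columns are ignored for the algebra.  First
    stage: per-equation OLS (statsmodels); the OLS residual covariance
    then weights a joint GLS step.  With ``iterate`` the covariance and
    GLS step are repeated to convergence (iterated FGLS), which cannot
    decrease the concentrated Gaussian likelihood.
    """
    if isinstance(designs, pd.DataFrame):
        designs = [designs, designs]
    xs = []
    names = []
    for d in designs:
        cols = [c for c in d.columns if c != "person_id"]
        x = d[cols].to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"singular design; check columns {cols}")
        xs.append(x)
        names.append(cols)
    y = outcomes[list(EQUATIONS)].to_numpy(dtype=float)
    n = y.shape[0]
    if any(x.shape[0] != n for x in xs):
        raise ValueError("design and outcome row sets differ")

    # stage 1: equation-by-equation OLS
    betas = [sm.OLS(y[:, k], xs[k]).fit().params for k in range(2)]
    resid = np.column_stack([y[:, k] - xs[k] @ betas[k] for k in range(2)])
    sigma = resid.T @ resid / n

    n_iter = 0
    while True:
        n_iter += 1
        w = np.linalg.inv(sigma)
        k1, k2 = xs[0].shape[1], xs[1].shape[1]
        bread = np.block(
            [
                [w[0, 0] * xs[0].T @ xs[0], w[0, 1] * xs[0].T @ xs[1]],
                [w[1, 0] * xs[1].T @ xs[0], w[1, 1] * xs[1].T @ xs[1]],
            ]
        )
        rhs = np.concatenate(
            [
                xs[0].T @ (w[0, 0] * y[:, 0] + w[0, 1] * y[:, 1]),
                xs[1].T @ (w[1, 0] * y[:, 0] + w[1, 1] * y[:, 1]),
            ]
        )
        bread_inv = np.linalg.inv(bread)
        beta_all = bread_inv @ rhs
        betas = [beta_all[:k1], beta_all[k1:]]
        new_resid = np.column_stack(
            [y[:, k] - xs[k] @ betas[k] for k in range(2)]
        )
        new_sigma = new_resid.T @ new_resid / n
        done = (not iterate) or (
            np.max(np.abs(new_sigma - sigma)) < tol or n_iter >= max_iterations
        )
        resid, sigma = new_resid, new_sigma
        if done:
            break

    cov_beta = bread_inv
    ses = [
        np.sqrt(np.diag(cov_beta)[:k1]),
        np.sqrt(np.diag(cov_beta)[k1:]),
    ]
    coef, se, pval, r2 = {}, {}, {}, {}
    for k, eq in enumerate(EQUATIONS):
        z = betas[k] / ses[k]
        p = 2.0 * stats.norm.sf(np.abs(z))
        coef[eq] = dict(zip(names[k], betas[k].tolist()))
        se[eq] = dict(zip(names[k], ses[k].tolist()))
        pval[eq] = dict(zip(names[k], p.tolist()))
        sst = float(np.sum((y[:, k] - y[:, k].mean()) ** 2))
        ssr = float(np.sum(resid[:, k] ** 2))
        r2[eq] = 1.0 - ssr / sst if sst > 0 else np.nan

    return SURResult(
        coef=coef,
        se=se,
        pvalues=pval,
        resid_cov=sigma,
        r2=r2,
        n=n,
        n_iterations=n_iter,
        loglik=_concentrated_loglik(resid),
    )


def predict_report(
    panel: pd.DataFrame,
    summaries: pd.DataFrame,
    models: tuple[int, ...] = (1, 2, 3, 4),
    anchor_week: int = 4,
    outcome_week: int = 8,
    iterate: bool = False,
) -> dict[int, SURResult]:
    """Fit the requested models and return their SUR results keyed by id."""
    out = {}
    for m in models:
        design, outcomes = build_model_matrices(
            panel, summaries, m, anchor_week=anchor_week, outcome_week=outcome_week
        )
        out[m] = fit_sur(design, outcomes, iterate=iterate)
    return out


def report_table(results: dict[int, "SURResult"]) -> pd.DataFrame:
    """Comparison table: coefficient and p-value per predictor and model,
    with R-squared and N rows, mirroring the standard presentation."""
    predictors = ["phq9_week4", "daily_mean", "daily_slope",
                  "daily_max", "daily_min", "daily_sd"]
    rows = []
    for eq in EQUATIONS:
        for pred in predictors:
            row = {"outcome": eq, "predictor": pred}
            for m, res in results.items():
                row[f"model{m}_coef"] = res.coef[eq].get(pred, np.nan)
                row[f"model{m}_p"] = res.pvalues[eq].get(pred, np.nan)
            rows.append(row)
        row = {"outcome": eq, "predictor": "R2"}
        for m, res in results.items():
            row[f"model{m}_coef"] = res.r2[eq]
            row[f"model{m}_p"] = np.nan
        rows.append(row)
    row = {"outcome": "", "predictor": "N"}
    for m, res in results.items():
        row[f"model{m}_coef"] = res.n
        row[f"model{m}_p"] = np.nan
    rows.append(row)
    return pd.DataFrame(rows)
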