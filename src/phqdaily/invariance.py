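"""Multiple-group fitting and likelihood-ratio invariance tests.

The cohort is split on a binary demographic label and the joint factor
model is fitted twice:

* unconstrained — every measurement parameter estimated freely in each
  group (the total log-likelihood is the sum of two independent fits);
* constrained — loadings, intercepts and residual variances shared across
  groups.  Once the measurement parameters are equated, the second group's
  latent variances are re-freed (the usual convention: with loadings fixed
  in a common metric, group differences in latent spread become estimable)
  while latent means stay at 0; the latent correlation is free per group.

The likelihood-ratio statistic is 2(ll_u - ll_c) on df equal to the
difference in free-parameter counts, which is derived from the parameter
vector lengths rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cfa
from .cfa import FitResult, ModelSpec, StackedData
from .params import ParameterSet
from .reliability import ReliabilityReport, reliability_report

__all__ = [
    "MultiGroupFit",
    "GroupComparison",
    "split_by_group",
    "fit_multigroup",
    "lrt",
    "compare_groups",
]


@dataclass
class MultiGroupFit:
    """A two-group fit (constrained or unconstrained)."""

    group_var: str
    levels: tuple[str, str]
    constrained: bool
    loglik: float
    n_free: int
    group_params: dict[str, ParameterSet]
    group_fits: dict[str, FitResult] | None  # per-group fits (unconstrained only)
    latent_variances: dict[str, tuple[float, float, float]]
    converged: bool


@dataclass
class GroupComparison:
    group_var: str
    levels: tuple[str, str]
    unconstrained: MultiGroupFit
    constrained: MultiGroupFit
    chi2: float
    df: int
    p_value: float
    group_reliability: dict[str, ReliabilityReport]
    group_corr: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "group_var": self.group_var,
            "levels": list(self.levels),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": round(self.p_value, 3),
            "loglik_unconstrained": self.unconstrained.loglik,
            "loglik_constrained": self.constrained.loglik,
            "n_free_unconstrained": self.unconstrained.n_free,
            "n_free_constrained": self.constrained.n_free,
            "group_reliability": {
                g: r.as_dict() for g, r in self.group_reliability.items()
            },
            "group_corr": self.group_corr,
        }


def split_by_group(
    daily: pd.DataFrame, panel: pd.DataFrame, group_var: str
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Split both tables into exactly two person-level groups."""
    labels = (
        panel[["person_id", group_var]]
        .dropna()
        .drop_duplicates("person_id")
        .set_index("person_id")[group_var]
    )
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"{group_var} must have exactly 2 levels, got {levels}")
    out = {}
    for lev in levels:
        ids = set(labels.index[labels == lev])
        if len(ids) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 persons")
        out[lev] = (
            daily[daily["person_id"].isin(ids)].reset_index(drop=True),
            panel[panel["person_id"].isin(ids)].reset_index(drop=True),
        )
    return out


def fit_multigroup(
    daily: pd.DataFrame,
    panel: pd.DataFrame,
    group_var: str,
    spec: ModelSpec = ModelSpec(),
    constrained: bool = False,
    *,
    anchor_week: int = 4,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> MultiGroupFit:
    """Fit the model to two groups jointly.

    Unconstrained: independent parameter sets, so the groups are fitted
    separately and their log-likelihoods added.  Constrained: one shared
    measurement parameter set; per-group latent correlation; group-2
    latent variances free.
    """
    groups = split_by_group(daily, panel, group_var)
    levels = tuple(groups)

    if not constrained:
        fits = {
            lev: cfa.fit_mlcfa(
                d, p, spec, anchor_week=anchor_week, gtol=gtol,
                maxiter=maxiter, compute_se=False,
            )
            for lev, (d, p) in groups.items()
        }
        return MultiGroupFit(
            group_var=group_var,
            levels=levels,
            constrained=False,
            loglik=sum(f.loglik for f in fits.values()),
            n_free=sum(f.n_free for f in fits.values()),
            group_params={lev: f.params for lev, f in fits.items()},
            group_fits=fits,
            latent_variances={lev: (1.0, 1.0, 1.0) for lev in levels},
            converged=all(f.converged for f in fits.values()),
        )

    data = {
        lev: cfa.stack_data(d, p, spec, anchor_week=anchor_week)
        for lev, (d, p) in groups.items()
    }
    m_len = cfa.measurement_len(spec)
    n_corr = 2 if spec.has_corr else 0
    psi_names = ([True] if spec.questionnaire else []) + (
        [True, True] if spec.daily else []
    )
    n_psi = len(psi_names)

    def group_psis(x, lev_idx):
        psis = [1.0, 1.0, 1.0]  # psi_q, psi_b, psi_w
        if lev_idx == 1:
            log_psi = x[m_len + n_corr :]
            j = 0
            if spec.questionnaire:
                psis[0] = float(np.exp(log_psi[j])); j += 1
            if spec.daily:
                psis[1] = float(np.exp(log_psi[j])); j += 1
                psis[2] = float(np.exp(log_psi[j])); j += 1
        return psis

    def group_moments(x, lev_idx):
        psis = group_psis(x, lev_idx)
        meas = x[:m_len]
        if spec.has_corr:
            meas = np.append(meas, x[m_len + lev_idx])
        return cfa.moments_from_x(meas, spec, *psis)

    def negll(x):
        try:
            total = 0.0
            for i, lev in enumerate(levels):
                mu, sb, sw = group_moments(x, i)
                total += cfa.loglik_from_moments(mu, sb, sw, data[lev])
        except np.linalg.LinAlgError:
            return 1e12
        return -total if np.isfinite(total) else 1e12

    start = cfa.default_start(daily, panel, spec, anchor_week)
    x0 = np.concatenate(
        [
            cfa.pack_measurement(start, spec),
            np.zeros(n_corr),
            np.zeros(n_psi),
        ]
    )
    res = cfa._minimize(negll, x0, gtol, maxiter)

    group_params = {}
    latent_var = {}
    for i, lev in enumerate(levels):
        meas = cfa.unpack_measurement(res.x[:m_len], spec)
        if spec.has_corr:
            meas.latent_corr = float(np.tanh(res.x[m_len + i]))
        group_params[lev] = meas
        latent_var[lev] = tuple(group_psis(res.x, i))
    return MultiGroupFit(
        group_var=group_var,
        levels=levels,
        constrained=True,
        loglik=-res.fun,
        n_free=x0.size,
        group_params=group_params,
        group_fits=None,
        latent_variances=latent_var,
        converged=bool(res.success),
    )


def lrt(
    constrained: MultiGroupFit, unconstrained: MultiGroupFit
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the constrained (nested) model."""
    chi2 = 2.0 * (unconstrained.loglik - constrained.loglik)
    df = unconstrained.n_free - constrained.n_free
    if chi2 < -1e-4:
        raise RuntimeError(
            f"negative LRT chi-square ({chi2:.4f}): constrained fit beat the "
            "unconstrained fit; refit with tighter tolerances or multistart"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def compare_groups(
    daily: pd.DataFrame,
    panel: pd.DataFrame,
    group_var: str,
    spec: ModelSpec = ModelSpec(),
    *,
    anchor_week: int = 4,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> GroupComparison:
    """Full invariance comparison for one demographic split.

    Per-group reliabilities and latent correlations come from the
    unconstrained fits (each group in its own metric).
    """
    unc = fit_multigroup(
        daily, panel, group_var, spec, constrained=False,
        anchor_week=anchor_week, gtol=gtol, maxiter=maxiter,
    )
    con = fit_multigroup(
        daily, panel, group_var, spec, constrained=True,
        anchor_week=anchor_week, gtol=gtol, maxiter=maxiter,
    )
    chi2, df, p = lrt(con, unc)

    rel = {}
    corr = {}
    groups = split_by_group(daily, panel, group_var)
    for lev, (d, _) in groups.items():
        sizes = d.groupby("person_id").size().to_numpy()
        rel[lev] = reliability_report(unc.group_params[lev], cluster_sizes=sizes)
        corr[lev] = unc.group_params[lev].latent_corr
    return GroupComparison(
        group_var=group_var,
        levels=unc.levels,
        unconstrained=unc,
        constrained=con,
        chi2=chi2,
        df=df,
        p_value=p,
        group_reliability=rel,
        group_corr=corr,
    )
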