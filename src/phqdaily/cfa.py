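"""Full-information ML estimation of the joint two-level factor model.

Each person j contributes one stacked observation vector: the 9
questionnaire items z_j (if completed) followed by their n_j daily 2-item
ratings y_j1..y_jn_j in day order.  Integrating the latents analytically,
the vector is multivariate normal with

    Cov(y_ji, y_ji') = Sigma_b            (i != i')
    Cov(y_ji, y_ji ) = Sigma_b + Sigma_w
    Cov(z_j)         = Lambda9 Lambda9' + Theta9
    Cov(z_j, y_ji)   = Lambda9 r lambda_b'

where Sigma_b = lambda_b lambda_b' + Theta_b and
Sigma_w = lambda_w lambda_w' + Theta_w.  Because this covariance depends on
a person only through the cluster size n_j and which blocks are observed,
persons are grouped into patterns and the likelihood is evaluated from
per-pattern sufficient statistics (one Cholesky per pattern), making the
cost independent of the number of persons.

Estimation maximizes this marginal likelihood over the free parameters
(variances on the log scale, the latent correlation via atanh) with
L-BFGS-B.  Saturated and independence (baseline) counterparts of the same
marginal likelihood supply the chi-square and CFI/TLI/RMSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .params import N_DAILY, N_PHQ9, ParameterSet

__all__ = [
    "ModelSpec",
    "StackedData",
    "FitResult",
    "MomentsResult",
    "FitIndices",
    "stack_data",
    "marginal_loglik",
    "loglik_from_moments",
    "fit_mlcfa",
    "fit_saturated",
    "fit_baseline",
    "fit_indices",
    "compute_fit_indices",
    "numeric_hessian",
    "pack_params",
    "unpack_params",
    "n_free_params",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which blocks the model includes and which equality constraints apply.

    Latent means are fixed at 0 and latent variances at 1 for
    identification; the daily items share one loading per level.  With
    ``equal_daily_item_params`` the two daily items additionally share
    their intercept and their residual variance at each level.
    """

    daily: bool = True
    questionnaire: bool = True
    equal_daily_item_params: bool = False

    def __post_init__(self) -> None:
        if not (self.daily or self.questionnaire):
            raise ValueError("model must include at least one block")

    @property
    def q_dim(self) -> int:
        return N_PHQ9 if self.questionnaire else 0

    @property
    def between_dim(self) -> int:
        return self.q_dim + (N_DAILY if self.daily else 0)

    @property
    def has_corr(self) -> bool:
        return self.daily and self.questionnaire


# ---------------------------------------------------------------------------
# data stacking


@dataclass
class _Pattern:
    has_q: bool
    n_days: int
    m: int              # persons with this pattern
    sum_x: np.ndarray   # sum of stacked observation vectors
    sxx: np.ndarray     # sum of outer products x x'

    @property
    def dim(self) -> int:
        return self.sum_x.shape[0]


@dataclass
class StackedData:
    """Person-level data grouped by (questionnaire observed, cluster size)."""

    patterns: list[_Pattern]
    spec: ModelSpec
    n_persons: int
    n_daily_obs: int

    @property
    def n_obs_vectors(self) -> int:
        return sum(p.m * p.dim for p in self.patterns)


def stack_data(
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    anchor_week: int = 4,
) -> StackedData:
    """Group persons into likelihood patterns and precompute sufficient stats.

    A person's questionnaire block enters only if all 9 items at the anchor
    week are present; daily rows with a missing item are dropped.  Persons
    with neither block are skipped.
    """
    from .io import PHQ_ITEM_COLUMNS

    z_by_person: dict[str, np.ndarray] = {}
    if spec.questionnaire and panel is not None:
        rows = panel[panel["week"] == anchor_week]
        items = rows[PHQ_ITEM_COLUMNS].to_numpy(dtype=float)
        complete = ~np.isnan(items).any(axis=1)
        for pid, z in zip(rows["person_id"].to_numpy()[complete], items[complete]):
            z_by_person[pid] = z

    y_by_person: dict[str, np.ndarray] = {}
    if spec.daily and daily is not None:
        d = daily.dropna(subset=["item1", "item2"])
        d = d.sort_values(["person_id", "day"], kind="stable")
        for pid, grp in d.groupby("person_id", sort=True):
            y_by_person[pid] = grp[["item1", "item2"]].to_numpy(dtype=float)

    persons = sorted(set(z_by_person) | set(y_by_person))
    groups: dict[tuple[bool, int], list[np.ndarray]] = {}
    n_daily_obs = 0
    for pid in persons:
        z = z_by_person.get(pid)
        y = y_by_person.get(pid)
        n_days = 0 if y is None else y.shape[0]
        n_daily_obs += n_days
        parts = []
        if z is not None:
            parts.append(z)
        if n_days:
            parts.append(y.ravel())
        x = np.concatenate(parts)
        groups.setdefault((z is not None, n_days), []).append(x)

    patterns = []
    for (has_q, n_days), vecs in sorted(groups.items()):
        x = np.vstack(vecs)
        patterns.append(
            _Pattern(
                has_q=has_q,
                n_days=n_days,
                m=x.shape[0],
                sum_x=x.sum(axis=0),
                sxx=x.T @ x,
            )
        )
    return StackedData(
        patterns=patterns, spec=spec, n_persons=len(persons), n_daily_obs=n_daily_obs
    )


# ---------------------------------------------------------------------------
# likelihood


def _pattern_moments(mu, sigma_b, sigma_w, q_dim, has_q, n_days):
    """Mean vector and covariance of one pattern's stacked observation.

    Builds the block-exchangeable covariance with ``np.tile`` plus an
    in-place diagonal-block update (faster than ``np.kron`` at these
    pattern sizes; this is the optimizer hot path)."""
    q = q_dim if has_q else 0
    d = q + N_DAILY * n_days
    cov = np.empty((d, d))
    mean = np.empty(d)
    if has_q:
        cov[:q, :q] = sigma_b[:q_dim, :q_dim]
        mean[:q] = mu[:q_dim]
    if n_days:
        yy = np.tile(sigma_b[q_dim:, q_dim:], (n_days, n_days))
        idx = np.arange(n_days)
        view = yy.reshape(n_days, N_DAILY, n_days, N_DAILY)
        view[idx, :, idx, :] += sigma_w
        cov[q:, q:] = yy
        mean[q:] = np.tile(mu[q_dim:], n_days)
        if has_q:
            cross = np.tile(sigma_b[:q_dim, q_dim:], (1, n_days))
            cov[:q, q:] = cross
            cov[q:, :q] = cross.T
    return mean, cov


def loglik_from_moments(
    mu: np.ndarray,
    sigma_b: np.ndarray,
    sigma_w: np.ndarray | None,
    data: StackedData,
) -> float:
    """Marginal Gaussian log-likelihood from person-level moments.

    Raises ``numpy.linalg.LinAlgError`` if any pattern's implied covariance
    is not positive definite; the error message names the pattern.
    """
    q_dim = data.spec.q_dim
    ll = 0.0
    for p in data.patterns:
        mean, cov = _pattern_moments(mu, sigma_b, sigma_w, q_dim, p.has_q, p.n_days)
        try:
            chol, low = linalg.cho_factor(cov, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"implied covariance not positive definite for pattern "
                f"(questionnaire={p.has_q}, n_days={p.n_days}, dim={p.dim})"
            ) from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        dev = p.sum_x - p.m * mean
        scatter = p.sxx - np.outer(p.sum_x, mean) - np.outer(mean, dev)
        quad = float(np.trace(linalg.cho_solve((chol, low), scatter,
                                               check_finite=False)))
        ll += -0.5 * (p.m * p.dim * _LOG2PI + p.m * logdet + quad)
    return ll


def moments_from_x(
    x: np.ndarray,
    spec: ModelSpec,
    psi_q: float = 1.0,
    psi_b: float = 1.0,
    psi_w: float = 1.0,
    corr_override: float | None = None,
):
    """Transformed parameter vector -> (mu, sigma_b, sigma_w).

    Equivalent to ``_implied(unpack_params(x, spec), spec, ...)`` but avoids
    constructing a :class:`ParameterSet`; this is the optimizer hot path.
    """
    i = 0
    if spec.questionnaire:
        lam9 = x[i : i + N_PHQ9]; i += N_PHQ9
        tau9 = x[i : i + N_PHQ9]; i += N_PHQ9
        th9 = np.exp(x[i : i + N_PHQ9]); i += N_PHQ9
    if spec.daily:
        k = 1 if spec.equal_daily_item_params else N_DAILY
        lam_b = x[i]; i += 1
        nu = _expand(x[i : i + k]); i += k
        th_b = _expand(np.exp(x[i : i + k])); i += k
        lam_w = x[i]; i += 1
        th_w = _expand(np.exp(x[i : i + k])); i += k
    if spec.has_corr:
        r = np.tanh(x[i]) if corr_override is None else corr_override

    if not spec.daily:
        sb = psi_q * np.outer(lam9, lam9)
        sb[np.arange(N_PHQ9), np.arange(N_PHQ9)] += th9
        return tau9, sb, None
    lb = np.full(N_DAILY, lam_b)
    s_bb = psi_b * np.outer(lb, lb)
    s_bb[np.arange(N_DAILY), np.arange(N_DAILY)] += th_b
    lw = np.full(N_DAILY, lam_w)
    sw = psi_w * np.outer(lw, lw)
    sw[np.arange(N_DAILY), np.arange(N_DAILY)] += th_w
    if not spec.questionnaire:
        return nu, s_bb, sw
    db = N_PHQ9 + N_DAILY
    sb = np.empty((db, db))
    sb[:N_PHQ9, :N_PHQ9] = psi_q * np.outer(lam9, lam9)
    sb[np.arange(N_PHQ9), np.arange(N_PHQ9)] += th9
    sb[N_PHQ9:, N_PHQ9:] = s_bb
    s_qb = (r * np.sqrt(psi_q * psi_b)) * np.outer(lam9, lb)
    sb[:N_PHQ9, N_PHQ9:] = s_qb
    sb[N_PHQ9:, :N_PHQ9] = s_qb.T
    mu = np.concatenate([tau9, nu])
    return mu, sb, sw


def _implied(params: ParameterSet, spec: ModelSpec, psi_q=1.0, psi_b=1.0, psi_w=1.0):
    mu, sb, sw = params.implied_moments(psi_q=psi_q, psi_b=psi_b, psi_w=psi_w)
    if not spec.questionnaire:
        mu, sb = mu[N_PHQ9:], sb[N_PHQ9:, N_PHQ9:]
    if not spec.daily:
        mu, sb, sw = mu[:N_PHQ9], sb[:N_PHQ9, :N_PHQ9], None
    return mu, sb, sw


def marginal_loglik(
    params: ParameterSet,
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    anchor_week: int = 4,
) -> float:
    """Log-likelihood of the data under ``params`` (latents integrated out)."""
    data = stack_data(daily, panel, spec, anchor_week=anchor_week)
    return loglik_from_moments(*_implied(params, spec), data)


# ---------------------------------------------------------------------------
# parameter packing (transformed scale: log variances, atanh correlation)


def _daily_len(spec: ModelSpec) -> int:
    k = 1 if spec.equal_daily_item_params else N_DAILY
    return 1 + k + k + 1 + k  # lam_b, nu, th_b, lam_w, th_w


def measurement_len(spec: ModelSpec) -> int:
    n = 0
    if spec.questionnaire:
        n += 3 * N_PHQ9
    if spec.daily:
        n += _daily_len(spec)
    return n


def n_free_params(spec: ModelSpec) -> int:
    return measurement_len(spec) + (1 if spec.has_corr else 0)


def _expand(v: np.ndarray) -> np.ndarray:
    return np.full(N_DAILY, v[0]) if v.shape[0] == 1 else np.asarray(v, float)


def pack_measurement(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    parts = []
    if spec.questionnaire:
        parts += [
            params.phq9_loadings,
            params.phq9_intercepts,
            np.log(params.phq9_residuals),
        ]
    if spec.daily:
        k = 1 if spec.equal_daily_item_params else N_DAILY
        parts += [
            [params.daily_between_loading],
            params.daily_intercepts[:k],
            np.log(params.daily_between_residuals[:k]),
            [params.daily_within_loading],
            np.log(params.daily_within_residuals[:k]),
        ]
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def unpack_measurement(x: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Inverse of :func:`pack_measurement`; latent correlation set to 0."""
    i = 0
    lam9 = tau9 = th9 = None
    if spec.questionnaire:
        lam9 = x[i : i + N_PHQ9]; i += N_PHQ9
        tau9 = x[i : i + N_PHQ9]; i += N_PHQ9
        th9 = np.exp(x[i : i + N_PHQ9]); i += N_PHQ9
    if lam9 is None:
        lam9, tau9 = np.zeros(N_PHQ9), np.zeros(N_PHQ9)
        th9 = np.ones(N_PHQ9)
    lam_b = lam_w = 0.0
    nu = np.zeros(N_DAILY)
    th_b = th_w = np.ones(N_DAILY)
    if spec.daily:
        k = 1 if spec.equal_daily_item_params else N_DAILY
        lam_b = float(x[i]); i += 1
        nu = _expand(x[i : i + k]); i += k
        th_b = _expand(np.exp(x[i : i + k])); i += k
        lam_w = float(x[i]); i += 1
        th_w = _expand(np.exp(x[i : i + k])); i += k
    assert i == measurement_len(spec)
    return ParameterSet(
        phq9_loadings=lam9,
        phq9_intercepts=tau9,
        phq9_residuals=th9,
        daily_between_loading=lam_b,
        daily_intercepts=nu,
        daily_between_residuals=th_b,
        daily_within_loading=lam_w,
        daily_within_residuals=th_w,
        latent_corr=0.0,
    )


def pack_params(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    x = pack_measurement(params, spec)
    if spec.has_corr:
        x = np.append(x, np.arctanh(np.clip(params.latent_corr, -0.999999, 0.999999)))
    return x


def unpack_params(x: np.ndarray, spec: ModelSpec) -> ParameterSet:
    params = unpack_measurement(x[: measurement_len(spec)], spec)
    if spec.has_corr:
        params.latent_corr = float(np.tanh(x[measurement_len(spec)]))
    return params


def _transform_jacobian(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """d(raw parameter)/d(transformed parameter), elementwise."""
    jac = np.ones_like(x)
    i = 0
    if spec.questionnaire:
        jac[i + 2 * N_PHQ9 : i + 3 * N_PHQ9] = np.exp(x[i + 2 * N_PHQ9 : i + 3 * N_PHQ9])
        i += 3 * N_PHQ9
    if spec.daily:
        k = 1 if spec.equal_daily_item_params else N_DAILY
        i += 1 + k  # lam_b, nu
        jac[i : i + k] = np.exp(x[i : i + k]); i += k
        i += 1  # lam_w
        jac[i : i + k] = np.exp(x[i : i + k]); i += k
    if spec.has_corr:
        jac[i] = 1.0 - np.tanh(x[i]) ** 2
    return jac


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """A converged factor-model fit."""

    params: ParameterSet
    loglik: float
    n_free: int
    converged: bool
    n_iter: int
    grad_norm: float
    n_persons: int
    spec: ModelSpec
    x: np.ndarray
    se: ParameterSet | None = None
    boundary_warning: bool = False
    cov_x: np.ndarray | None = None   # covariance of the transformed estimate


@dataclass
class MomentsResult:
    """An unstructured (saturated or independence) fit of the same likelihood."""

    mu: np.ndarray
    sigma_b: np.ndarray
    sigma_w: np.ndarray | None
    loglik: float
    n_free: int
    converged: bool


class ConvergenceError(RuntimeError):
    pass


def _guarded_negll(fn):
    def negll(x):
        try:
            val = fn(x)
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    return negll


def _minimize(negll, x0, gtol, maxiter):
    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12, "maxfun": 10 ** 6},
    )
    return res


def default_start(
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec,
    anchor_week: int = 4,
) -> ParameterSet:
    """Starting values: loadings 0.5, intercepts at item means, residual
    variances at half the item variances, correlation 0."""
    from .io import PHQ_ITEM_COLUMNS

    lam9 = np.full(N_PHQ9, 0.5)
    tau9 = np.zeros(N_PHQ9)
    th9 = np.full(N_PHQ9, 0.5)
    if spec.questionnaire and panel is not None:
        rows = panel[panel["week"] == anchor_week]
        items = rows[PHQ_ITEM_COLUMNS].to_numpy(dtype=float)
        if len(items):
            tau9 = np.nanmean(items, axis=0)
            th9 = np.maximum(0.5 * np.nanvar(items, axis=0), 0.05)
    nu = np.full(N_DAILY, 2.0)
    th_b = np.full(N_DAILY, 0.25)
    th_w = np.full(N_DAILY, 0.25)
    if spec.daily and daily is not None and len(daily):
        vals = daily[["item1", "item2"]].to_numpy(dtype=float)
        nu = np.nanmean(vals, axis=0)
        v = np.maximum(np.nanvar(vals, axis=0), 0.1)
        th_b = 0.25 * v
        th_w = 0.25 * v
    return ParameterSet(
        phq9_loadings=lam9,
        phq9_intercepts=tau9,
        phq9_residuals=th9,
        daily_between_loading=0.5,
        daily_intercepts=nu,
        daily_between_residuals=th_b,
        daily_within_loading=0.5,
        daily_within_residuals=th_w,
        latent_corr=0.0,
    )


def fit_mlcfa(
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    *,
    anchor_week: int = 4,
    gtol: float = 1e-6,
    maxiter: int = 500,
    compute_se: bool = True,
    start: ParameterSet | None = None,
    multistart: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit the joint factor model by full-information maximum likelihood.

    ``multistart`` adds that many randomly perturbed restarts (seeded by
    ``seed``) and keeps the best optimum.  Standard errors come from the
    inverse of a numerically differentiated Hessian on the transformed
    scale, delta-method mapped back to the raw scale.
    """
    data = stack_data(daily, panel, spec, anchor_week=anchor_week)
    if data.n_persons == 0:
        raise ValueError("no usable persons in the data")

    negll = _guarded_negll(
        lambda x: loglik_from_moments(*moments_from_x(x, spec), data)
    )
    x0 = pack_params(start or default_start(daily, panel, spec, anchor_week), spec)

    starts = [x0]
    if multistart:
        rng = np.random.default_rng(seed)
        starts += [x0 + rng.normal(scale=0.2, size=x0.shape) for _ in range(multistart)]

    best = None
    for s in starts:
        res = _minimize(negll, s, gtol, maxiter)
        if best is None or res.fun < best.fun:
            best = res
    res = best
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(
            f"optimizer did not converge in {maxiter} iterations: {res.message}"
        )

    params = unpack_params(res.x, spec)
    boundary = spec.has_corr and abs(params.latent_corr) > 0.995
    if boundary:
        warnings.warn("latent correlation estimate at the boundary (|r| -> 1)")

    se_params = None
    cov_x = None
    if compute_se:
        hess = numeric_hessian(negll, res.x)
        cov_x = _safe_inverse(hess)
        se_x = np.sqrt(np.clip(np.diag(cov_x), 0.0, np.inf))
        se_raw = se_x * np.abs(_transform_jacobian(res.x, spec))
        se_params = _se_paramset(se_raw, res.x, spec)

    return FitResult(
        params=params,
        loglik=-res.fun,
        n_free=n_free_params(spec),
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
        n_persons=data.n_persons,
        spec=spec,
        x=res.x.copy(),
        se=se_params,
        boundary_warning=boundary,
        cov_x=cov_x,
    )


def _se_paramset(se_raw: np.ndarray, x: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Arrange raw-scale standard errors in a ParameterSet-shaped container."""
    i = 0
    lam9 = tau9 = th9 = np.zeros(N_PHQ9)
    if spec.questionnaire:
        lam9 = se_raw[i : i + N_PHQ9]; i += N_PHQ9
        tau9 = se_raw[i : i + N_PHQ9]; i += N_PHQ9
        th9 = se_raw[i : i + N_PHQ9]; i += N_PHQ9
    lam_b = lam_w = 0.0
    nu = th_b = th_w = np.zeros(N_DAILY)
    if spec.daily:
        k = 1 if spec.equal_daily_item_params else N_DAILY
        lam_b = float(se_raw[i]); i += 1
        nu = _expand(se_raw[i : i + k]); i += k
        th_b = _expand(se_raw[i : i + k]); i += k
        lam_w = float(se_raw[i]); i += 1
        th_w = _expand(se_raw[i : i + k]); i += k
    r = float(se_raw[i]) if spec.has_corr else 0.0
    out = ParameterSet(
        phq9_loadings=lam9,
        phq9_intercepts=tau9,
        phq9_residuals=np.maximum(th9, 0),
        daily_between_loading=lam_b,
        daily_intercepts=nu,
        daily_between_residuals=np.maximum(th_b, 1e-12),
        daily_within_residuals=np.maximum(th_w, 1e-12),
        daily_within_loading=lam_w,
        latent_corr=0.0,
    )
    out.latent_corr = r  # stores the SE of r; bypasses the [-1,1] check
    return out


def _safe_inverse(h: np.ndarray) -> np.ndarray:
    try:
        return linalg.inv(h)
    except linalg.LinAlgError:
        return np.linalg.pinv(h)


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


# ---------------------------------------------------------------------------
# saturated and independence fits


def _tri_indices(d: int):
    return np.tril_indices(d)


def _chol_pack(s: np.ndarray) -> np.ndarray:
    chol = linalg.cholesky(s, lower=True)
    rows, cols = _tri_indices(s.shape[0])
    vals = chol[rows, cols].copy()
    diag = rows == cols
    vals[diag] = np.log(vals[diag])
    return vals

def _chol_unpack(vals: np.ndarray, d: int) -> np.ndarray:
    chol = np.zeros((d, d))
    rows, cols = _tri_indices(d)
    v = vals.copy()
    diag = rows == cols
    v[diag] = np.exp(np.clip(v[diag], -30, 30))
    chol[rows, cols] = v
    return chol @ chol.T


def _pattern_person_blocks(p: _Pattern, q: int):
    """Per-pattern sums needed for person-level (z, daily-mean) moments."""
    off = q if p.has_q else 0
    n = p.n_days
    sum_v_z = p.sum_x[:off]
    blocks = {}
    if n:
        sum_y = p.sum_x[off:].reshape(n, N_DAILY).sum(axis=0)
        yy = p.sxx[off:, off:]
        # sum over persons of (sum_i y_ji)(sum_i y_ji)'
        grid = yy.reshape(n, N_DAILY, n, N_DAILY).sum(axis=(0, 2))
        diag = sum(
            yy[N_DAILY * i : N_DAILY * (i + 1), N_DAILY * i : N_DAILY * (i + 1)]
            for i in range(n)
        )
        blocks["sum_y"] = sum_y
        blocks["grid"] = grid
        blocks["diag"] = diag
        if p.has_q:
            zy = p.sxx[:off, off:].reshape(q, n, N_DAILY).sum(axis=1)
            blocks["zy"] = zy
    blocks["sum_z"] = sum_v_z
    return blocks


def _clip_pd(s: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    vals, vecs = np.linalg.eigh((s + s.T) / 2.0)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _moment_start(data: StackedData) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """ANOVA-style moment estimates used as optimizer starting values.

    Uses persons observed on both blocks; exact only for balanced clusters
    but always a sensible neighbourhood of the optimum.
    """
    spec = data.spec
    q = spec.q_dim
    db = spec.between_dim

    sw = np.eye(N_DAILY) * 0.3 if spec.daily else None
    if spec.daily:
        num = np.zeros((N_DAILY, N_DAILY))
        den = 0
        for p in data.patterns:
            if p.n_days < 2:
                continue
            b = _pattern_person_blocks(p, q)
            num += b["diag"] - b["grid"] / p.n_days
            den += p.m * (p.n_days - 1)
        if den > 0:
            sw = _clip_pd(num / den, 1e-3)

    # person-level vector v_j = (z_j, mean_i y_ji)
    m_tot = 0
    sum_v = np.zeros(db)
    sum_vv = np.zeros((db, db))
    inv_n = []
    for p in data.patterns:
        if (q and not p.has_q) or (spec.daily and p.n_days == 0):
            continue
        b = _pattern_person_blocks(p, q)
        v = np.zeros(db)
        vv = np.zeros((db, db))
        if q:
            v[:q] = b["sum_z"]
            vv[:q, :q] = p.sxx[:q, :q]
        if p.n_days:
            n = p.n_days
            v[q:] = b["sum_y"] / n
            vv[q:, q:] = b["grid"] / n ** 2
            if q:
                vv[:q, q:] = b["zy"] / n
                vv[q:, :q] = vv[:q, q:].T
            inv_n += [1.0 / n] * p.m
        m_tot += p.m
        sum_v += v
        sum_vv += vv
    if m_tot == 0:
        mu = np.zeros(db)
        sb = np.eye(db) * 0.5
        return mu, sb, sw
    mu = sum_v / m_tot
    cov_v = sum_vv / m_tot - np.outer(mu, mu)
    sb = cov_v.copy()
    if spec.daily and inv_n:
        sb[q:, q:] = sb[q:, q:] - sw * float(np.mean(inv_n))
    sb = _clip_pd(sb, 1e-3)
    return mu, sb, sw


def fit_saturated(
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    *,
    anchor_week: int = 4,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    data: StackedData | None = None,
) -> MomentsResult:
    """Unrestricted ML fit: free means, a free person-level covariance over
    all between-level components, and a free day-level covariance."""
    if data is None:
        data = stack_data(daily, panel, spec, anchor_week=anchor_week)
    db = data.spec.between_dim
    has_w = data.spec.daily
    mu0, sb0, sw0 = _moment_start(data)

    def split(x):
        mu = x[:db]
        n_b = db * (db + 1) // 2
        sb = _chol_unpack(x[db : db + n_b], db)
        sw = _chol_unpack(x[db + n_b :], N_DAILY) if has_w else None
        return mu, sb, sw

    negll = _guarded_negll(lambda x: loglik_from_moments(*split(x), data))
    x0 = np.concatenate(
        [mu0, _chol_pack(sb0)] + ([_chol_pack(sw0)] if has_w else [])
    )
    res = _minimize(negll, x0, gtol, maxiter)
    mu, sb, sw = split(res.x)
    n_free = db + db * (db + 1) // 2 + (N_DAILY * (N_DAILY + 1) // 2 if has_w else 0)
    return MomentsResult(
        mu=mu, sigma_b=sb, sigma_w=sw, loglik=-res.fun, n_free=n_free,
        converged=bool(res.success),
    )


def fit_baseline(
    daily: pd.DataFrame | None,
    panel: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    *,
    anchor_week: int = 4,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    data: StackedData | None = None,
) -> MomentsResult:
    """Independence model: free means and variances, all covariances zero."""
    if data is None:
        data = stack_data(daily, panel, spec, anchor_week=anchor_week)
    db = data.spec.between_dim
    has_w = data.spec.daily
    mu0, sb0, sw0 = _moment_start(data)

    def split(x):
        mu = x[:db]
        sb = np.diag(np.exp(np.clip(x[db : 2 * db], -30, 30)))
        sw = (
            np.diag(np.exp(np.clip(x[2 * db : 2 * db + N_DAILY], -30, 30)))
            if has_w
            else None
        )
        return mu, sb, sw

    negll = _guarded_negll(lambda x: loglik_from_moments(*split(x), data))
    x0 = np.concatenate(
        [mu0, np.log(np.diag(sb0))] + ([np.log(np.diag(sw0))] if has_w else [])
    )
    res = _minimize(negll, x0, gtol, maxiter)
    mu, sb, sw = split(res.x)
    n_free = 2 * db + (N_DAILY if has_w else 0)
    return MomentsResult(
        mu=mu, sigma_b=sb, sigma_w=sw, loglik=-res.fun, n_free=n_free,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float | None
    tli: float | None
    rmsea: float | None
    chi2_baseline: float
    df_baseline: int
    defined: bool = True


def compute_fit_indices(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, n_persons: int
) -> FitIndices:
    """Chi-square based incremental fit indices.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0);
    TLI = ((chi2_B/df_B) - (chi2_M/df_M)) / ((chi2_B/df_B) - 1);
    RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M * N)) with N = persons.
    """
    if df_m <= 0 or df_b <= 0:
        return FitIndices(
            chi2=chi2_m, df=df_m, cfi=None, tli=None, rmsea=None,
            chi2_baseline=chi2_b, df_baseline=df_b, defined=False,
        )
    excess_m = max(chi2_m - df_m, 0.0)
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess_m / denom
    ratio_b = chi2_b / df_b
    tli = (ratio_b - chi2_m / df_m) / (ratio_b - 1.0) if ratio_b != 1.0 else None
    rmsea = float(np.sqrt(excess_m / (df_m * n_persons)))
    return FitIndices(
        chi2=chi2_m, df=df_m, cfi=cfi, tli=tli, rmsea=rmsea,
        chi2_baseline=chi2_b, df_baseline=df_b,
    )


def fit_indices(
    model: FitResult,
    saturated: MomentsResult,
    baseline: MomentsResult,
    n_persons: int | None = None,
) -> FitIndices:
    chi2_m = 2.0 * (saturated.loglik - model.loglik)
    df_m = saturated.n_free - model.n_free
    chi2_b = 2.0 * (saturated.loglik - baseline.loglik)
    df_b = saturated.n_free - baseline.n_free
    return compute_fit_indices(
        chi2_m, df_m, chi2_b, df_b, n_persons or model.n_persons
    )
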