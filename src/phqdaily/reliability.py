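"""Level-specific composite (omega) reliabilities of the two measures.

Three quantities are reported:

* ``omega_questionnaire`` — composite reliability of the 9-item sum,
  (sum lambda)^2 psi / [(sum lambda)^2 psi + sum theta];
* ``omega_within`` — day-to-day reliability of the daily 2-item composite,
  the same formula applied to the within-level parameters;
* ``rho_between`` — reliability of a person's *mean* daily composite over
  n_bar days: the within-level composite variance shrinks by 1/n_bar, so

      rho = (sum lambda_b)^2 / [(sum lambda_b)^2 + sum theta_b
            + ((sum lambda_w)^2 + sum theta_w) / n_bar].

The person-mean formula uses the arithmetic mean cluster size by default;
a harmonic-mean option is provided because cluster sizes are unbalanced
and the harmonic mean is the exact choice for equal-weight person means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "omega_composite",
    "omega_within_daily",
    "omega_questionnaire",
    "rho_person_mean",
    "mean_cluster_size",
    "ReliabilityReport",
    "reliability_report",
]


def omega_composite(
    loadings: np.ndarray, residual_variances: np.ndarray, factor_variance: float = 1.0
) -> float:
    """Composite reliability of an unweighted sum of congeneric items."""
    loadings = np.asarray(loadings, dtype=float)
    residual_variances = np.asarray(residual_variances, dtype=float)
    if loadings.shape != residual_variances.shape:
        raise ValueError("loadings and residual variances must have equal length")
    if np.any(residual_variances < 0) or factor_variance <= 0:
        raise ValueError("variances must be positive")
    common = loadings.sum() ** 2 * factor_variance
    return float(common / (common + residual_variances.sum()))


def omega_questionnaire(params: ParameterSet) -> float:
    """Composite reliability of the 9-item questionnaire sum."""
    return omega_composite(params.phq9_loadings, params.phq9_residuals, 1.0)


def omega_within_daily(params: ParameterSet) -> float:
    """Reliability of the daily composite's day-to-day variation."""
    lam = np.full(2, params.daily_within_loading)
    return omega_composite(lam, params.daily_within_residuals, 1.0)


def rho_person_mean(params: ParameterSet, n_bar: float) -> float:
    """Reliability of the person-mean daily composite over ``n_bar`` days."""
    if n_bar <= 0:
        raise ValueError("n_bar must be > 0")
    lam_b = np.full(2, params.daily_between_loading)
    lam_w = np.full(2, params.daily_within_loading)
    common_b = lam_b.sum() ** 2
    noise_b = params.daily_between_residuals.sum()
    within_total = lam_w.sum() ** 2 + params.daily_within_residuals.sum()
    return float(common_b / (common_b + noise_b + within_total / n_bar))


def mean_cluster_size(cluster_sizes, kind: str = "arithmetic") -> float:
    """Arithmetic (default) or harmonic mean number of ratings per person."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if sizes.size == 0 or np.any(sizes <= 0):
        raise ValueError("cluster sizes must be positive and non-empty")
    if kind == "arithmetic":
        return float(sizes.mean())
    if kind == "harmonic":
        return float(sizes.size / np.sum(1.0 / sizes))
    raise ValueError("kind must be 'arithmetic' or 'harmonic'")


@dataclass
class ReliabilityReport:
    omega_questionnaire: float
    omega_within: float
    rho_between: float
    n_bar: float
    notes: str = (
        "omega = (sum lambda)^2 psi / [(sum lambda)^2 psi + sum theta]; "
        "person-mean reliability divides the within-level composite variance "
        "by the mean cluster size (arithmetic mean by default)."
    )

    def as_dict(self) -> dict:
        return {
            "omega_questionnaire": self.omega_questionnaire,
            "omega_within": self.omega_within,
            "rho_between": self.rho_between,
            "n_bar": self.n_bar,
            "notes": self.notes,
        }


def reliability_report(
    params: ParameterSet,
    cluster_sizes=None,
    n_bar: float | None = None,
    n_bar_kind: str = "arithmetic",
) -> ReliabilityReport:
    """All three reliabilities from a fitted or tabulated parameter set.

    Supply either raw ``cluster_sizes`` (ratings per person) or ``n_bar``
    directly.
    """
    if n_bar is None:
        if cluster_sizes is None:
            raise ValueError("supply cluster_sizes or n_bar")
        n_bar = mean_cluster_size(cluster_sizes, kind=n_bar_kind)
    return ReliabilityReport(
        omega_questionnaire=omega_questionnaire(params),
        omega_within=omega_within_daily(params),
        rho_between=rho_person_mean(params, n_bar),
        n_bar=float(n_bar),
    )
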