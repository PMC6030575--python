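"""Measurement parameters of the joint daily/questionnaire depression factor model.

The model couples two blocks observed on the same people:

* a two-level factor model for the 2-item daily depressed-mood rating
  (PHQ-2 recast to "yesterday", 1-5 scale), decomposing each item into a
  between-person component (stable severity, factor ``eta_b``) and a
  within-person component (day-to-day fluctuation, factor ``eta_w``), and
* a single-level factor model for the 9-item PHQ-9 completed at the
  anchor week (factor ``xi``).

All latent variables have mean 0 and variance 1; the two daily items share
one loading at each level.  The between-level daily factor and the
questionnaire factor correlate freely (``latent_corr``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

N_PHQ9 = 9
N_DAILY = 2

__all__ = [
    "N_PHQ9",
    "N_DAILY",
    "ParameterSet",
    "default_parameters",
    "DEFAULT_RATING_COUNTS",
    "rating_count_probabilities",
    "DEFAULT_LATENT_CORR",
]


@dataclass
class ParameterSet:
    """All free parameters of the joint two-level factor model.

    Attributes
    ----------
    phq9_loadings, phq9_intercepts, phq9_residuals
        Length-9 arrays: loading, intercept and residual variance of each
        questionnaire item on the single questionnaire factor.
    daily_between_loading
        Between-level loading shared by both daily items.
    daily_intercepts
        Length-2 intercepts of the daily items.
    daily_between_residuals
        Length-2 between-level residual variances.
    daily_within_loading
        Within-level loading shared by both daily items.
    daily_within_residuals
        Length-2 within-level residual variances.
    latent_corr
        Correlation between the between-level daily factor and the
        questionnaire factor.
    """

    phq9_loadings: np.ndarray
    phq9_intercepts: np.ndarray
    phq9_residuals: np.ndarray
    daily_between_loading: float
    daily_intercepts: np.ndarray
    daily_between_residuals: np.ndarray
    daily_within_loading: float
    daily_within_residuals: np.ndarray
    latent_corr: float

    def __post_init__(self) -> None:
        self.phq9_loadings = np.asarray(self.phq9_loadings, dtype=float)
        self.phq9_intercepts = np.asarray(self.phq9_intercepts, dtype=float)
        self.phq9_residuals = np.asarray(self.phq9_residuals, dtype=float)
        self.daily_intercepts = np.asarray(self.daily_intercepts, dtype=float)
        self.daily_between_residuals = np.asarray(
            self.daily_between_residuals, dtype=float
        )
        self.daily_within_residuals = np.asarray(
            self.daily_within_residuals, dtype=float
        )
        for name in ("phq9_loadings", "phq9_intercepts", "phq9_residuals"):
            if getattr(self, name).shape != (N_PHQ9,):
                raise ValueError(f"{name} must have length {N_PHQ9}")
        for name in (
            "daily_intercepts",
            "daily_between_residuals",
            "daily_within_residuals",
        ):
            if getattr(self, name).shape != (N_DAILY,):
                raise ValueError(f"{name} must have length {N_DAILY}")
        if abs(self.latent_corr) > 1:
            raise ValueError("latent_corr must lie in [-1, 1]")

    # ---- model-implied moments -------------------------------------------

    def implied_moments(
        self,
        psi_q: float = 1.0,
        psi_b: float = 1.0,
        psi_w: float = 1.0,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(mu, sigma_between, sigma_within)`` implied by the model.

        ``mu`` stacks the 9 questionnaire intercepts followed by the 2 daily
        intercepts.  ``sigma_between`` is the 11x11 person-level covariance of
        (questionnaire items, between-person daily components);
        ``sigma_within`` is the 2x2 day-level covariance of the daily items.
        The ``psi_*`` arguments rescale the latent variances (used by
        multiple-group fits where the second group re-frees them).
        """
        lam_q = self.phq9_loadings
        lam_b = np.full(N_DAILY, self.daily_between_loading)
        lam_w = np.full(N_DAILY, self.daily_within_loading)

        s_qq = psi_q * np.outer(lam_q, lam_q) + np.diag(self.phq9_residuals)
        s_bb = psi_b * np.outer(lam_b, lam_b) + np.diag(self.daily_between_residuals)
        s_qb = self.latent_corr * np.sqrt(psi_q * psi_b) * np.outer(lam_q, lam_b)

        sigma_b = np.block([[s_qq, s_qb], [s_qb.T, s_bb]])
        sigma_w = psi_w * np.outer(lam_w, lam_w) + np.diag(self.daily_within_residuals)
        mu = np.concatenate([self.phq9_intercepts, self.daily_intercepts])
        return mu, sigma_b, sigma_w

    def phq9_sum_moments(self) -> tuple[float, float]:
        """Mean and variance of the questionnaire sum score (continuous mode)."""
        mean = float(self.phq9_intercepts.sum())
        var = float(self.phq9_loadings.sum() ** 2 + self.phq9_residuals.sum())
        return mean, var

    def copy(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


#: Latent correlation between average daily mood and the questionnaire factor
#: used as the generator default.
DEFAULT_LATENT_CORR = 0.80


def default_parameters(latent_corr: float = DEFAULT_LATENT_CORR) -> ParameterSet:
    """Default measurement parameters.

    These are the published estimates from a large community study of daily
    mobile depression monitoring (N=545) and define the conditions the
    synthetic-data generator emulates.
    """
    return ParameterSet(
        phq9_loadings=np.array(
            [0.60, 0.63, 0.59, 0.65, 0.65, 0.70, 0.56, 0.34, 0.37]
        ),
        phq9_intercepts=np.array(
            [1.07, 1.12, 1.25, 1.39, 1.07, 1.03, 0.90, 0.34, 0.34]
        ),
        phq9_residuals=np.array(
            [0.20, 0.22, 0.53, 0.40, 0.58, 0.44, 0.45, 0.32, 0.36]
        ),
        daily_between_loading=0.85,
        daily_intercepts=np.array([2.20, 2.20]),
        daily_between_residuals=np.array([0.05, 0.05]),
        daily_within_loading=0.66,
        daily_within_residuals=np.array([0.20, 0.20]),
        latent_corr=latent_corr,
    )


#: Empirical distribution of number-of-daily-ratings per person (1..14)
#: in the emulated study: 545 people, 2992 ratings, mean 5.49.
DEFAULT_RATING_COUNTS: dict[int, int] = {
    1: 40,
    2: 22,
    3: 27,
    4: 45,
    5: 79,
    6: 109,
    7: 199,
    8: 18,
    9: 2,
    10: 2,
    11: 1,
    12: 1,
    13: 0,
    14: 0,
}


def rating_count_probabilities() -> np.ndarray:
    """Probability table over 1..14 ratings per person (empirical proportions)."""
    counts = np.array([DEFAULT_RATING_COUNTS[k] for k in range(1, 15)], dtype=float)
    return counts / counts.sum()
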