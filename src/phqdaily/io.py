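"""Readers, writers and sample filters for the two tabular inputs.

Two tables drive every analysis stage:

* the long-format daily table — one row per person-day with the two daily
  mood items (``person_id, day, item1, item2``), and
* the wide-format questionnaire panel — one row per person-week with the
  nine questionnaire items, their sum, the disability-scale sum and the
  demographic group labels.

Both are plain UTF-8 CSV with a header row; missing cells are empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import N_PHQ9

__all__ = [
    "FormatError",
    "IntegrityError",
    "RunConfig",
    "DAILY_COLUMNS",
    "PANEL_COLUMNS",
    "read_long_daily",
    "write_long_daily",
    "read_panel",
    "write_panel",
    "validate_daily",
    "validate_panel",
    "apply_sample_filters",
]


class FormatError(ValueError):
    """A file does not have the expected columns or cell types."""


class IntegrityError(ValueError):
    """A file parses but violates a table invariant (range, duplicates, sums)."""


DAILY_COLUMNS = ["person_id", "day", "item1", "item2"]
PHQ_ITEM_COLUMNS = [f"phq{i}" for i in range(1, N_PHQ9 + 1)]
PANEL_COLUMNS = (
    ["person_id", "week"]
    + PHQ_ITEM_COLUMNS
    + ["phq9_sum", "sds_sum", "gender", "age_band", "minority"]
)

GENDER_LEVELS = {"man", "woman"}
AGE_LEVELS = {"<55", "55+"}
MINORITY_LEVELS = {"yes", "no"}


@dataclass
class RunConfig:
    """Analysis settings shared across pipeline stages.

    ``anchor_week`` is the week of the questionnaire the daily ratings are
    compared against; the daily window is the half-open interval
    ``[anchor_day - window_length_days, anchor_day)`` so a rating on the
    anchor day itself is excluded (the daily item asks about "yesterday").
    """

    window_length_days: int = 14
    anchor_week: int = 4
    outcome_week: int = 8
    seed: int = 0
    gtol: float = 1e-6
    maxiter: int = 500
    equal_daily_item_params: bool = False

    def __post_init__(self) -> None:
        if self.window_length_days < 1:
            raise ValueError("window_length_days must be >= 1")
        if self.gtol <= 0:
            raise ValueError("tolerances must be > 0")

    @property
    def anchor_day(self) -> int:
        return 7 * self.anchor_week

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# daily table


def validate_daily(
    df: pd.DataFrame, response_range: tuple[float, float] | None = (1, 5)
) -> pd.DataFrame:
    """Validate and canonicalize a long daily table.

    Returns the table sorted stably by ``(person_id, day)``.  ``response_range``
    of ``None`` disables the range check (continuous simulation output).
    """
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"daily table missing required column(s): {missing}")
    df = df.loc[:, DAILY_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    day = pd.to_numeric(df["day"], errors="coerce")
    if day.isna().any():
        rows = _csv_rows(df.index[day.isna()])
        raise FormatError(f"non-numeric or missing day on row(s) {rows}")
    df["day"] = day.astype(int)
    for col in ("item1", "item2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    if response_range is not None:
        lo, hi = response_range
        vals = df[["item1", "item2"]]
        bad = ((vals < lo) | (vals > hi)).any(axis=1)
        if bad.any():
            rows = _csv_rows(df.index[bad])
            raise IntegrityError(
                f"daily item response outside [{lo}, {hi}] on row(s) {rows}"
            )

    dup = df.duplicated(subset=["person_id", "day"], keep=False)
    if dup.any():
        rows = _csv_rows(df.index[dup])
        raise IntegrityError(f"duplicate (person_id, day) on row(s) {rows}")

    return df.sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)


def read_long_daily(
    path: str | Path, response_range: tuple[float, float] | None = (1, 5)
) -> pd.DataFrame:
    """Read and validate a long-format daily ratings CSV."""
    df = pd.read_csv(path, dtype={"person_id": str})
    return validate_daily(df, response_range=response_range)


def write_long_daily(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, DAILY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# questionnaire panel


def validate_panel(
    df: pd.DataFrame,
    item_range: tuple[float, float] | None = (0, 3),
    check_sum: bool = True,
) -> pd.DataFrame:
    """Validate and canonicalize the questionnaire panel."""
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel missing required column(s): {missing}")
    df = df.loc[:, PANEL_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    week = pd.to_numeric(df["week"], errors="coerce")
    if week.isna().any():
        raise FormatError("non-numeric or missing week")
    df["week"] = week.astype(int)
    for col in PHQ_ITEM_COLUMNS + ["phq9_sum", "sds_sum"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    if item_range is not None:
        lo, hi = item_range
        vals = df[PHQ_ITEM_COLUMNS]
        bad = ((vals < lo) | (vals > hi)).any(axis=1)
        if bad.any():
            rows = _csv_rows(df.index[bad])
            raise IntegrityError(
                f"questionnaire item outside [{lo}, {hi}] on row(s) {rows}"
            )

    dup = df.duplicated(subset=["person_id", "week"], keep=False)
    if dup.any():
        rows = _csv_rows(df.index[dup])
        raise IntegrityError(f"duplicate (person_id, week) on row(s) {rows}")

    if check_sum:
        items = df[PHQ_ITEM_COLUMNS]
        complete = items.notna().all(axis=1) & df["phq9_sum"].notna()
        mismatch = complete & ~np.isclose(
            items.sum(axis=1), df["phq9_sum"], atol=1e-6
        )
        if mismatch.any():
            rows = _csv_rows(df.index[mismatch])
            raise IntegrityError(
                f"phq9_sum does not equal the item sum on row(s) {rows}"
            )

    for col, levels in (
        ("gender", GENDER_LEVELS),
        ("age_band", AGE_LEVELS),
        ("minority", MINORITY_LEVELS),
    ):
        vals = df[col].dropna().astype(str)
        bad_levels = set(vals) - levels
        if bad_levels:
            raise IntegrityError(f"unknown {col} level(s): {sorted(bad_levels)}")

    return df.sort_values(["person_id", "week"], kind="stable").reset_index(drop=True)


def read_panel(
    path: str | Path,
    item_range: tuple[float, float] | None = (0, 3),
    check_sum: bool = True,
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    return validate_panel(df, item_range=item_range, check_sum=check_sum)


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, PANEL_COLUMNS].to_csv(path, index=False)


def _csv_rows(index) -> list[int]:
    # 1-based data row numbers (header row excluded)
    return [int(i) + 1 for i in index]


# ---------------------------------------------------------------------------
# sample filters


def apply_sample_filters(
    daily: pd.DataFrame, panel: pd.DataFrame, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the study eligibility filters.

    A person is retained when they have a questionnaire sum at the anchor
    week AND at least one daily rating whose day offset falls in the window
    ``[anchor_day - window, anchor_day)``.  The returned daily table is
    restricted to in-window rows of retained persons; the panel keeps all
    weeks of retained persons.  The exclusion log has one row per excluded
    person with a reason.
    """
    cfg = cfg or RunConfig()
    anchor = cfg.anchor_day
    lo, hi = anchor - cfg.window_length_days, anchor

    persons = pd.Index(
        sorted(set(daily["person_id"]) | set(panel["person_id"])), name="person_id"
    )

    wk = panel[(panel["week"] == cfg.anchor_week) & panel["phq9_sum"].notna()]
    has_anchor = persons.isin(wk["person_id"])

    in_window = daily[(daily["day"] >= lo) & (daily["day"] < hi)]
    has_daily = persons.isin(in_window["person_id"])

    retained_mask = has_anchor & has_daily
    reasons = np.where(
        ~has_anchor, "missing anchor-week questionnaire", "no in-window daily rating"
    )
    exclusions = pd.DataFrame(
        {"person_id": persons[~retained_mask], "reason": reasons[~retained_mask]}
    ).reset_index(drop=True)

    retained = set(persons[retained_mask])
    if not retained:
        raise IntegrityError("no eligible persons after sample filters")

    daily_f = (
        in_window[in_window["person_id"].isin(retained)]
        .sort_values(["person_id", "day"], kind="stable")
        .reset_index(drop=True)
    )
    panel_f = (
        panel[panel["person_id"].isin(retained)]
        .sort_values(["person_id", "week"], kind="stable")
        .reset_index(drop=True)
    )
    return daily_f, panel_f, exclusions
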