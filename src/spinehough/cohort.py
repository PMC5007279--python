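"""Desk-scale cohort statistics: dichotomization, contingency arithmetic,
group comparison, and thin survival-report hooks.

The prognostic analysis of the study dichotomizes subjects at the fifth
decile (median) of the whole-cord NSUV and tabulates mortality per group.
Kaplan-Meier / log-rank / Cox models are exposed only as thin wrappers over
standard survival routines — they are validation statistics around the
imaging method, not part of it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
    "dichotomize_fifth_decile",
    "mortality_rate",
    "compare_groups",
    "GroupComparison",
    "kaplan_meier",
    "logrank",
    "cox_univariate",
    "simulate_survival",
]

# documented header of the delimited cohort table
COHORT_COLUMNS = [
    "subject", "group", "sc_nsuv", "survival_months", "death",
    "age", "sex", "alsfrs_r", "months_to_pet", "riluzole",
]


def read_cohort_table(path) -> pd.DataFrame:
    """Read a tab-delimited cohort table; validates the required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject", "sc_nsuv") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if (df["sc_nsuv"] <= 0).any():
        raise ValueError("sc_nsuv values must be positive")
    if "survival_months" in df.columns and (df["survival_months"] < 0).any():
        raise ValueError("survival_months must be >= 0")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def dichotomize_fifth_decile(values):
    """Split values at the fifth decile (median, lower interpolation).

    Returns ``(threshold, low_index, high_index)`` where the boolean index
    arrays select values ``<= threshold`` and ``> threshold``.  With an
    even sample size the lower-interpolation convention keeps the threshold
    at an observed value, matching a printed decile cut.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    threshold = float(np.percentile(values, 50, method="lower"))
    low = values <= threshold
    high = values > threshold
    if not high.any():
        warnings.warn("degenerate dichotomization: the high group is empty",
                      stacklevel=2)
    return threshold, low, high


def mortality_rate(deaths: int, n: int) -> int:
    """Mortality in percent, rounded half-up to the nearest integer."""
    if n <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= deaths <= n:
        raise ValueError(f"deaths must be within [0, {n}], got {deaths}")
    return int(math.floor(100.0 * deaths / n + 0.5))


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float


def compare_groups(a, b) -> GroupComparison:
    """Unpaired two-sample t test with per-group mean ± SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        statistic=float(t), p_value=float(p))


# --- thin survival-report hooks (validation statistics, not the method) ---

def kaplan_meier(durations, events, label: str = "KM"):
    """Fit a Kaplan-Meier curve; returns the fitted lifelines object."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(durations, event_observed=events, label=label)
    return km


def logrank(durations_a, events_a, durations_b, events_b):
    """Log-rank test between two groups; returns (statistic, p-value)."""
    from lifelines.statistics import logrank_test

    res = logrank_test(durations_a, durations_b,
                       event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(df: pd.DataFrame, covariate: str,
                   duration_col: str = "survival_months",
                   event_col: str = "death"):
    """Univariate Cox proportional-hazards fit; returns the fitted model."""
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df[[duration_col, event_col, covariate]],
            duration_col=duration_col, event_col=event_col)
    return cph


def simulate_survival(sc_nsuv, seed: int = 0, follow_up_months: float = 36.0,
                      base_median_months: float = 40.0,
                      log_hr_per_nsuv: float = 2.5):
    """Draw (survival_months, death) pairs with NSUV-dependent hazard.

    Exponential survival with hazard increasing with the whole-cord NSUV,
    censored at the follow-up horizon — a convenience generator for the
    survival report hooks.
    """
    sc_nsuv = np.asarray(sc_nsuv, dtype=float)
    rng = np.random.default_rng(seed)
    base_rate = np.log(2.0) / base_median_months
    rate = base_rate * np.exp(log_hr_per_nsuv * (sc_nsuv - sc_nsuv.mean()))
    t = rng.exponential(1.0 / rate)
    death = t <= follow_up_months
    months = np.minimum(t, follow_up_months)
    return months, death.astype(int)
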