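"""Graft-survival analysis: Kaplan-Meier, log-rank, stratification, Cox.

Thin, contract-enforcing layer over lifelines. Records carry a positive
follow-up time, an event flag (1 = graft loss, 0 = censored) and named
covariates. Cox fits use Efron tie handling and report per-unit hazard
ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "validate_records", "km_estimate", "logrank", "stratify_by_ratio",
    "cox_fit",
]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the survival-table contract: time > 0, event in {0, 1}."""
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (graft loss)")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Censored subjects remain at risk through their censoring time. Returns a
    step-function table (time, survival, at_risk, events, censored) including
    the t=0 row with S(0)=1.
    """
    records = validate_records(records)
    if len(records) == 0:
        raise ValueError("km_estimate needs >=1 record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
    })
    return out.reset_index(drop=True)


def logrank(records: pd.DataFrame, group_col: str = "group") -> tuple[float, int, float]:
    """Log-rank test across groups: (chi-square statistic, df, p-value).

    Standard observed-minus-expected statistic over the pooled event times.
    Requires >= 2 groups and >= 1 event in total.
    """
    records = validate_records(records)
    labels = records[group_col]
    if labels.nunique() < 2:
        raise ValueError("logrank requires >=2 groups")
    if int(records["event"].sum()) == 0:
        raise ValueError("logrank undefined with zero events")
    res = multivariate_logrank_test(records["time"], labels, records["event"])
    return (
        float(res.test_statistic),
        int(labels.nunique() - 1),
        float(res.p_value),
    )


def stratify_by_ratio(
    records: pd.DataFrame, covariate: str, ratio: str = "1:1",
) -> pd.Series:
    """Split samples into "high"/"low" by a covariate quantile ratio.

    ``"a:b"`` assigns the top a/(a+b) fraction (by covariate value) to
    "high"; the cut is the ceil(n*a/(a+b))-th largest value and ties at the
    cut go to "high", so the high group may exceed the nominal size under
    ties. Degenerate (constant) covariates raise.
    """
    try:
        a, b = (int(part) for part in ratio.split(":"))
    except ValueError as exc:
        raise ValueError(f"ratio must look like '1:2', got {ratio!r}") from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"both ratio parts must be positive, got {ratio!r}")
    x = records[covariate].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"covariate {covariate!r} has missing values")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant; cannot stratify")
    n_high = math.ceil(len(x) * a / (a + b))
    cut = np.sort(x)[::-1][n_high - 1]
    labels = np.where(x >= cut, "high", "low")
    return pd.Series(labels, index=records.index, name=f"{covariate}_{ratio}")


def cox_fit(
    records: pd.DataFrame, covariates: list[str],
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron ties, Wald 95% CI).

    Returns one row per covariate: coef, hr (= exp(coef) per unit), ci_low,
    ci_high, se, p, plus the number of events used. Non-convergence and
    detected separation surface as lifelines errors/warnings.
    """
    records = validate_records(records)
    n_events = int(records["event"].sum())
    if n_events < 2:
        raise ValueError("cox_fit requires >=2 events")
    df = records[["time", "event", *covariates]].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    out = pd.DataFrame({
        "covariate": covariates,
        "coef": summary["coef"].to_numpy(),
        "hr": summary["exp(coef)"].to_numpy(),
        "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
        "se": summary["se(coef)"].to_numpy(),
        "p": summary["p"].to_numpy(),
    })
    out["n"] = len(records)
    out["n_events"] = n_events
    return out
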