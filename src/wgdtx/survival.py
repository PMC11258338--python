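"""Kaplan-Meier survival comparison across WGD timing groups.

Thin wrappers over lifelines: the product-limit estimator per group and the
k-sample log-rank test (observed-minus-expected with hypergeometric
variance, df = k - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["km_curve", "logrank_test", "LogrankResult", "compare_groups"]


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p: float


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"records need a {col!r} column")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return records


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns a step-function table with columns time, survival, n_at_risk;
    survival starts at 1 and is non-increasing.
    """
    records = _validate(records)
    if records.empty:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    ev = kmf.event_table
    out = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "n_at_risk": ev["at_risk"].to_numpy(dtype=int),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> LogrankResult:
    """K-sample log-rank test across the groups in ``group_col``."""
    records = _validate(records)
    counts = records[group_col].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(
        records["time"], records[group_col], records["event"]
    )
    k = len(counts)
    return LogrankResult(
        statistic=float(res.test_statistic), df=k - 1, p=float(res.p_value)
    )


def compare_groups(records: pd.DataFrame, group_col: str = "group"):
    """Per-group KM curves plus the joint log-rank test.

    Returns (curves, LogrankResult) where ``curves`` maps group label to the
    :func:`km_curve` table.
    """
    curves = {
        str(g): km_curve(sub)
        for g, sub in records.groupby(group_col, sort=True)
    }
    return curves, logrank_test(records, group_col)
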