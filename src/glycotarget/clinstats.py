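"""Clinical association statistics for biomarker cross-tabulations and
survival cohorts: uncorrected Pearson chi-square, Kaplan-Meier estimation
and the log-rank test.

Pearson's statistic is computed without Yates continuity correction; the
classical uncorrected form is what reproduces published cross-tabulation
p-values in this setting. Survival analysis delegates to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ContingencyTable",
    "CohortRecord",
    "TestResult",
    "pearson_chi2",
    "fisher_exact",
    "km_estimate",
    "logrank",
    "read_contingency",
    "read_cohort",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative counts with labelled margins."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class CohortRecord:
    """One subject in a survival cohort (time in months)."""

    subject_id: str
    group: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.subject_id}: negative survival time")


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square test of independence.

    statistic = sum (O - E)^2 / E, expected counts from the product of the
    marginals over n; df = (r-1)(c-1); upper-tail chi-square p-value.
    Rows or columns with zero marginal totals are rejected.
    """
    arr = table.array
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("table has a zero marginal row or column")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        method="pearson-chi2",
    )


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Fisher's exact test (2x2 only); exploratory alternative to chi-square."""
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    res = stats.fisher_exact(arr)
    return TestResult(
        statistic=float(res.statistic), df=1, p_value=float(res.pvalue),
        method="fisher-exact",
    )


def km_estimate(cohort: Sequence[CohortRecord]) -> dict[str, pd.DataFrame]:
    """Per-group Kaplan-Meier product-limit survival curves.

    Returns, per group, a DataFrame with columns ``time``, ``at_risk``,
    ``survival``; right censoring is honored, S(0) = 1 and S is
    non-increasing.
    """
    if not cohort:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        {
            "group": [r.group for r in cohort],
            "time": [r.time for r in cohort],
            "event": [int(r.event) for r in cohort],
        }
    )
    out: dict[str, pd.DataFrame] = {}
    for group, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"]
        out[group] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "at_risk": at_risk.reindex(surv.index).to_numpy(dtype=float),
                "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def logrank(cohort: Sequence[CohortRecord]) -> TestResult:
    """Two-group log-rank comparison of survival, df = 1, chi-square p-value."""
    groups = sorted({r.group for r in cohort})
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly two groups, got {groups}")
    a = [r for r in cohort if r.group == groups[0]]
    b = [r for r in cohort if r.group == groups[1]]
    res = logrank_test(
        [r.time for r in a],
        [r.time for r in b],
        event_observed_A=[int(r.event) for r in a],
        event_observed_B=[int(r.event) for r in b],
    )
    return TestResult(
        statistic=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
        method="logrank",
    )


def read_contingency(path) -> ContingencyTable:
    """Read a contingency TSV: first column row labels, header column labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContingencyTable(
        counts=tuple(tuple(int(v) for v in row) for row in df.to_numpy()),
        row_labels=tuple(str(i) for i in df.index),
        col_labels=tuple(str(c) for c in df.columns),
    )


def read_cohort(path) -> list[CohortRecord]:
    """Read a long-format cohort TSV (id, group, time, event)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CohortRecord(
            subject_id=str(r["id"]),
            group=str(r["group"]),
            time=float(r["time"]),
            event=bool(int(r["event"])),
        )
        for _, r in df.iterrows()
    ]
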