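"""Clinical association and survival statistics.

Covariate-by-subtype association uses the Pearson chi-square test without
continuity correction (this reproduces the published stratification
table's p-values on its 2x2 rows; Kruskal-Wallis is available for ordered
covariates such as CKD stage).  Survival endpoints (cancer-specific and
metastasis-free survival) are compared between subtypes with the
Kaplan-Meier product-limit estimator and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")


@dataclass
class SurvivalRecord:
    """Follow-up of one patient: time in months, event flag, subtype group."""

    sample_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: time must be positive, got {self.time}")


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Accepts a ContingencyTable or a plain r x c count array; returns
    (statistic, degrees of freedom, p-value).  Zero marginals are an error
    (expected counts undefined).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal: expected counts undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class KMEstimate:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray       # event times where the curve steps
    survival: np.ndarray    # S(t) just after each step
    at_risk: np.ndarray     # number at risk just before each step

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:  # no events: S(t) = 1 everywhere
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(records: list[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier estimator over the given records (any grouping ignored)."""
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    event_times = np.unique(times[events])
    surv = sf["KM_estimate"].reindex(event_times, method="ffill").to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMEstimate(event_times, surv, at_risk)


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    by_group = {g: [r for r in records if r.group == g] for g in groups}
    if any(len(v) == 0 for v in by_group.values()):
        raise ValueError("one group is empty")
    if not any(r.event for r in records):
        raise ValueError("no events in either group")
    a, b = groups
    res = _ll_logrank(
        np.array([r.time for r in by_group[a]]),
        np.array([r.time for r in by_group[b]]),
        event_observed_A=np.array([r.event for r in by_group[a]], dtype=int),
        event_observed_B=np.array([r.event for r in by_group[b]], dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def build_table_one(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    subtype_col: str = "subtype",
    test: str = "chi2",
) -> pd.DataFrame:
    """Clinical-characteristics table stratified by subtype.

    One block per covariate: level rows carry "count(percent)" cells with
    within-subtype column percentages to 1 decimal place, and the block
    header row carries the association p-value to 3 decimals ("<0.001"
    below that).  Covariates with a single observed level are rendered
    without a p-value.  ``test`` may be "chi2" (default) or "kruskal"
    (rank test on level codes, for ordered covariates).
    """
    if subtype_col not in cohort.columns:
        raise ValueError(f"cohort lacks subtype column {subtype_col!r}")
    if covariates is None:
        covariates = [c for c in cohort.columns if c != subtype_col]
    subtypes = list(pd.unique(cohort[subtype_col]))
    rows = []
    n_total = len(cohort)
    header = {"Variable": "Total", "No. (%)": str(n_total), "P-value": ""}
    for s in subtypes:
        header[f"{s} (%)"] = str(int((cohort[subtype_col] == s).sum()))
    rows.append(header)
    for cov in covariates:
        levels = list(pd.unique(cohort[cov].dropna()))
        counts = np.array(
            [
                [((cohort[cov] == lev) & (cohort[subtype_col] == s)).sum() for s in subtypes]
                for lev in levels
            ]
        )
        if len(levels) >= 2 and len(subtypes) >= 2 and not (
            np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0)
        ):
            if test == "kruskal":
                codes = cohort[cov].astype("category").cat.codes
                samples = [codes[cohort[subtype_col] == s] for s in subtypes]
                p = float(stats.kruskal(*samples).pvalue)
            else:
                _, _, p = chi_square_test(counts)
            p_cell = _format_p(p)
        else:
            p_cell = ""
        rows.append({"Variable": cov, "No. (%)": "", "P-value": p_cell})
        col_totals = counts.sum(axis=0)
        for i, lev in enumerate(levels):
            row_n = int(counts[i].sum())
            cells = {
                "Variable": str(lev),
                "No. (%)": f"{row_n}({100 * row_n / n_total:.1f})",
                "P-value": "",
            }
            for j, s in enumerate(subtypes):
                pct = 100 * counts[i, j] / col_totals[j] if col_totals[j] else 0.0
                cells[f"{s} (%)"] = f"{counts[i, j]}({pct:.1f})"
            rows.append(cells)
    cols = ["Variable", "No. (%)"] + [f"{s} (%)" for s in subtypes] + ["P-value"]
    return pd.DataFrame(rows, columns=cols).fillna("")
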