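"""Nonparametric statistics for per-sample sequencing QC metric tables.

The workflow for comparing a QC metric (insert size, percent duplicated
reads, nucleotide content, ...) across preservation groups is a fixed
decision tree.  Metrics are first screened for normality (Shapiro–Wilk, per
group) and homogeneity of variance (Levene, across groups); the screen is
advisory — the small paired designs use nonparametric tests regardless.
With exactly two preservation groups, a paired two-tailed Wilcoxon
signed-rank test on the patient-matched differences is used.  With three or
more groups, a Friedman test on the complete patient blocks acts as a gate:
pairwise Holm-adjusted Wilcoxon tests run only when the Friedman p-value is
below 0.05.

Input tables are tidy pandas DataFrames with one row per sample, a patient
column, a group column, and numeric metric columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass(frozen=True)
class QCTestResult:
    metric: str
    test: str  # shapiro_wilk / levene / wilcoxon_signed_rank / friedman
    statistic: float | None
    p_value: float | None
    adjusted_p: float | None = None
    significant: bool | None = None
    group: str | None = None  # group (screen) or "A vs B" (pairwise)
    note: str | None = None

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "group": self.group,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "significant": self.significant,
            "note": self.note,
        }


def _blocks(
    table: pd.DataFrame, metric: str, patient_col: str, group_col: str
) -> pd.DataFrame:
    """Pivot to a complete patient × group block matrix; error on holes."""
    wide = table.pivot_table(
        index=patient_col, columns=group_col, values=metric, aggfunc="first"
    )
    missing = [
        f"{patient}×{group}"
        for patient, row in wide.iterrows()
        for group, value in row.items()
        if pd.isna(value)
    ]
    if missing:
        raise ValueError(f"{metric}: incomplete blocks, missing {missing}")
    return wide


def screen_assumptions(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
) -> list[QCTestResult]:
    """Shapiro–Wilk normality per group plus Levene homogeneity across groups.

    Groups with fewer than 3 observations are flagged and skipped.  Results
    are advisory; the paired tests downstream are nonparametric either way.
    """
    results: list[QCTestResult] = []
    groups = []
    for group, sub in table.groupby(group_col, sort=True):
        values = sub[metric].to_numpy(dtype=float)
        groups.append(values)
        if values.size < 3:
            results.append(
                QCTestResult(
                    metric,
                    "shapiro_wilk",
                    None,
                    None,
                    group=str(group),
                    note=f"skipped: n={values.size} < 3",
                )
            )
            continue
        if np.ptp(values) == 0:
            results.append(
                QCTestResult(
                    metric,
                    "shapiro_wilk",
                    None,
                    None,
                    group=str(group),
                    note="skipped: constant values",
                )
            )
            continue
        stat, p = stats.shapiro(values)
        results.append(
            QCTestResult(
                metric,
                "shapiro_wilk",
                float(stat),
                float(p),
                significant=p < ALPHA,
                group=str(group),
            )
        )
    if len(groups) >= 2 and all(g.size >= 3 for g in groups):
        stat, p = stats.levene(*groups, center="median")
        if np.isnan(stat):  # all deviations identical: trivially homogeneous
            stat, p = 0.0, 1.0
        results.append(
            QCTestResult(
                metric, "levene", float(stat), float(p), significant=p < ALPHA
            )
        )
    return results


def wilcoxon_signed_rank(
    differences: np.ndarray, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-tailed paired Wilcoxon signed-rank test on a difference vector.

    Zero differences are dropped (standard convention); ties get mid-ranks.
    The exact null distribution is enumerated for n ≤ ``exact_max_n``, the
    normal approximation used above.
    """
    diffs = np.asarray(differences, dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size < 2:
        raise ValueError(
            f"need ≥ 2 non-zero paired differences, have {diffs.size}"
        )
    method = "exact" if diffs.size <= exact_max_n else "approx"
    res = stats.wilcoxon(
        diffs, alternative="two-sided", zero_method="wilcox", method=method
    )
    return float(res.statistic), float(res.pvalue)


def two_group_paired_test(
    table: pd.DataFrame,
    metric: str,
    patient_col: str = "patient_id",
    group_col: str = "group",
) -> QCTestResult:
    """Paired two-tailed Wilcoxon signed-rank test between two groups."""
    wide = _blocks(table, metric, patient_col, group_col)
    if wide.shape[1] != 2:
        raise ValueError(
            f"{metric}: two-group test needs exactly 2 groups, have {wide.shape[1]}"
        )
    a, b = wide.columns
    stat, p = wilcoxon_signed_rank(wide[b].to_numpy() - wide[a].to_numpy())
    return QCTestResult(
        metric,
        "wilcoxon_signed_rank",
        stat,
        p,
        significant=p < ALPHA,
        group=f"{a} vs {b}",
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order."""
    if not p_values:
        return []
    return list(multipletests(p_values, method="holm")[1])


def multi_group_paired_test(
    table: pd.DataFrame,
    metric: str,
    patient_col: str = "patient_id",
    group_col: str = "group",
) -> list[QCTestResult]:
    """Friedman gate, then Holm-adjusted pairwise Wilcoxon tests.

    The Friedman test runs on complete patient blocks across all groups;
    pairwise signed-rank tests (all group pairs, Holm-adjusted within the
    metric's family) run only when the Friedman p-value is below 0.05.
    """
    wide = _blocks(table, metric, patient_col, group_col)
    if wide.shape[1] < 3:
        raise ValueError(
            f"{metric}: multi-group test needs ≥ 3 groups, have {wide.shape[1]}"
        )
    columns = [wide[c].to_numpy(dtype=float) for c in wide.columns]
    if all(np.array_equal(columns[0], c) for c in columns[1:]):
        friedman_stat, friedman_p = 0.0, 1.0  # identical groups: no evidence
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(*columns)
    results = [
        QCTestResult(
            metric,
            "friedman",
            float(friedman_stat),
            float(friedman_p),
            significant=friedman_p < ALPHA,
        )
    ]
    if friedman_p >= ALPHA:
        return results
    pairs = list(itertools.combinations(wide.columns, 2))
    raw: list[tuple[str, float, float]] = []
    for a, b in pairs:
        try:
            stat, p = wilcoxon_signed_rank(wide[b].to_numpy() - wide[a].to_numpy())
        except ValueError:
            stat, p = np.nan, 1.0  # all-zero differences: no evidence
        raw.append((f"{a} vs {b}", stat, p))
    adjusted = holm_adjust([p for _, _, p in raw])
    for (label, stat, p), adj in zip(raw, adjusted):
        results.append(
            QCTestResult(
                metric,
                "wilcoxon_signed_rank",
                None if np.isnan(stat) else float(stat),
                float(p),
                adjusted_p=float(adj),
                significant=adj < ALPHA,
                group=label,
            )
        )
    return results


def run_qc_tests(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    patient_col: str = "patient_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Apply the full decision tree to every metric column of a table."""
    if metrics is None:
        reserved = {patient_col, group_col, "sample_id", "tissue"}
        metrics = [
            c
            for c in table.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows: list[QCTestResult] = []
    n_groups = table[group_col].nunique()
    for metric in metrics:
        rows.extend(screen_assumptions(table, metric, group_col=group_col))
        if n_groups == 2:
            rows.append(
                two_group_paired_test(
                    table, metric, patient_col=patient_col, group_col=group_col
                )
            )
        elif n_groups >= 3:
            rows.extend(
                multi_group_paired_test(
                    table, metric, patient_col=patient_col, group_col=group_col
                )
            )
        else:
            raise ValueError("need at least 2 preservation groups")
    return pd.DataFrame([r.as_dict() for r in rows])
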