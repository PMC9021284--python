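"""Pooled genotype-quality distributions, cumulative curves and KS comparison.

GQ values from all samples of a treatment group are pooled and summarised as
a cumulative-percent curve: the percent of the group's SNPs scoring at or
below each GQ value.  Scores above ``max_gq`` (default 300) are excluded
before curve construction; they correspond to the extreme right tail and
would otherwise flatten the comparison range.  Curves, or the underlying raw
score vectors, are compared with two-sided two-sample Kolmogorov–Smirnov
tests.

Two KS modes are exposed because the quantity handed to the test is a real
modelling choice:

* ``curve_values`` (default) — the two "samples" are the cumulative-percent
  values of each curve evaluated on a shared integer grid 0..max_gq;
* ``raw_scores`` — the samples are the pooled GQ values themselves, the
  statistically conventional two-sample test on the score distributions.

Reports always label which mode produced a result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .concordance import (
    CONCORDANT,
    UNIQUE_TO_QUERY,
    PairClassifiedVariant,
)
from .vcf_io import CallSet

DEFAULT_MAX_GQ = 300

KS_CURVE_VALUES = "curve_values"
KS_RAW_SCORES = "raw_scores"


@dataclass
class GQCurve:
    """Cumulative percent of pooled SNPs at or below each GQ grid value."""

    group_label: str
    grid: np.ndarray  # ascending integer GQ values
    cum_percent: np.ndarray
    n_pooled: int
    max_gq_included: int = DEFAULT_MAX_GQ

    def evaluate(self, grid: Sequence[int]) -> np.ndarray:
        """Step-evaluate the curve on an arbitrary ascending grid."""
        idx = np.searchsorted(self.grid, np.asarray(grid), side="right") - 1
        values = np.where(idx >= 0, self.cum_percent[np.clip(idx, 0, None)], 0.0)
        return values


@dataclass(frozen=True)
class KSResult:
    group_a: str
    group_b: str
    d_statistic: float
    p_value: float
    mode: str
    n_a: int
    n_b: int
    sided: str = "two-sided"


@dataclass(frozen=True)
class ClassGQSummary:
    """Mean ± SD of uncapped GQ for one class within one group."""

    group_label: str
    class_label: str  # concordant / unique
    mean_gq: float | None
    sd_gq: float | None
    n: int


def pool_group(
    callsets: Iterable[CallSet],
    grouping: Callable[[CallSet], str] | None = None,
) -> dict[str, np.ndarray]:
    """Concatenate uncapped GQ values of member samples per group.

    ``grouping`` maps a call set to its group label (default: the sample's
    treatment group from its metadata).  Raises if no call sets are given.
    """
    if grouping is None:
        grouping = lambda cs: cs.meta.group
    buckets: dict[str, list[np.ndarray]] = {}
    for cs in callsets:
        buckets.setdefault(grouping(cs), []).append(cs.gq_values())
    if not buckets:
        raise ValueError("no call sets to pool")
    return {group: np.concatenate(parts) for group, parts in buckets.items()}


def cumulative_curve(
    gq_values: Sequence[int] | np.ndarray,
    max_gq: int = DEFAULT_MAX_GQ,
    group_label: str = "",
    dense_grid: bool = False,
) -> GQCurve:
    """Build a cumulative-percent GQ curve from pooled scores.

    Scores above ``max_gq`` are discarded first.  The grid covers the
    retained distinct GQ values, or the dense integer range 0..max_gq when
    ``dense_grid`` is set (useful for cross-group alignment).  The final
    value is exactly 100.
    """
    values = np.asarray(gq_values, dtype=np.int64)
    retained = np.sort(values[values <= max_gq])
    if retained.size == 0:
        raise ValueError(
            f"group {group_label!r}: no GQ values at or below {max_gq}"
        )
    if dense_grid:
        grid = np.arange(0, max_gq + 1, dtype=np.int64)
    else:
        grid = np.unique(retained)
    cum = 100.0 * np.searchsorted(retained, grid, side="right") / retained.size
    return GQCurve(
        group_label=group_label,
        grid=grid,
        cum_percent=cum,
        n_pooled=int(retained.size),
        max_gq_included=max_gq,
    )


def _as_curve(x, max_gq: int, label: str) -> GQCurve:
    if isinstance(x, GQCurve):
        return x
    return cumulative_curve(x, max_gq=max_gq, group_label=label)


def ks_compare(
    a,
    b,
    mode: str = KS_CURVE_VALUES,
    max_gq: int = DEFAULT_MAX_GQ,
    method: str = "auto",
) -> KSResult:
    """Two-sided two-sample KS test between two groups' GQ distributions.

    ``a`` and ``b`` are :class:`GQCurve` objects or raw GQ vectors.  In
    ``curve_values`` mode the two samples handed to the test are the
    cumulative-percent values of each curve on the shared integer grid
    0..max_gq.  In ``raw_scores`` mode the samples are the pooled GQ values
    themselves (above-``max_gq`` scores excluded); raw vectors are required.
    ``method`` is passed through to :func:`scipy.stats.ks_2samp` ("auto"
    selects the exact small-sample null, the asymptotic Kolmogorov
    distribution otherwise).
    """
    if mode == KS_CURVE_VALUES:
        curve_a = _as_curve(a, max_gq, "a")
        curve_b = _as_curve(b, max_gq, "b")
        shared = np.arange(0, max_gq + 1)
        sample_a = curve_a.evaluate(shared)
        sample_b = curve_b.evaluate(shared)
        label_a, label_b = curve_a.group_label, curve_b.group_label
    elif mode == KS_RAW_SCORES:
        if isinstance(a, GQCurve) or isinstance(b, GQCurve):
            raise ValueError("raw_scores mode requires raw GQ vectors, not curves")
        sample_a = np.asarray(a, dtype=float)
        sample_b = np.asarray(b, dtype=float)
        sample_a = sample_a[sample_a <= max_gq]
        sample_b = sample_b[sample_b <= max_gq]
        label_a, label_b = "a", "b"
    else:
        raise ValueError(f"unknown KS mode {mode!r}")
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("empty sample in KS comparison")
    result = stats.ks_2samp(sample_a, sample_b, alternative="two-sided", method=method)
    return KSResult(
        group_a=label_a,
        group_b=label_b,
        d_statistic=float(result.statistic),
        p_value=float(min(result.pvalue, 1.0)),
        mode=mode,
        n_a=int(sample_a.size),
        n_b=int(sample_b.size),
    )


def class_gq_summary(
    classified: Sequence[PairClassifiedVariant],
    group_label: str = "",
) -> list[ClassGQSummary]:
    """Mean ± sample SD of query-side GQ for concordant and unique calls.

    No ``max_gq`` exclusion is applied here: the class means use the full
    uncapped score range.  A class with no records yields an ``n=0`` row with
    absent mean/SD; a single record has an absent SD (n−1 denominator).
    """
    if not classified:
        raise ValueError("no classified variants")
    rows: list[ClassGQSummary] = []
    for class_label, short in ((CONCORDANT, "concordant"), (UNIQUE_TO_QUERY, "unique")):
        gqs = np.array(
            [r.gq_query for r in classified if r.class_label == class_label],
            dtype=float,
        )
        if gqs.size == 0:
            rows.append(ClassGQSummary(group_label, short, None, None, 0))
        else:
            sd = float(np.std(gqs, ddof=1)) if gqs.size > 1 else None
            rows.append(
                ClassGQSummary(group_label, short, float(np.mean(gqs)), sd, int(gqs.size))
            )
    return rows
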