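"""End-to-end orchestration: sample sheet → classification, curves, KS, tables.

``run`` reads a sample sheet, forms patient-matched (frozen reference, FFPE
query) comparisons, classifies every pair, pools genotype qualities per
treatment group, and emits the report bundle: per-pair and group-mean class
percentages, cumulative GQ curves, the KS matrix, per-class GQ means, and a
JSON manifest.  Re-running with the same configuration and inputs produces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import (
    QUERY_CLASSES,
    UNIQUE_TO_REFERENCE,
    aggregate_group,
    classify_pair,
    summarize_pair,
)
from .errors import ConfigError
from .gq_stats import (
    DEFAULT_MAX_GQ,
    KS_CURVE_VALUES,
    class_gq_summary,
    cumulative_curve,
    ks_compare,
    pool_group,
)
from .vcf_io import CallSet, read_callset, read_sample_sheet, write_reports

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sample_sheet: Path
    out_dir: Path
    comparisons: list[tuple[str, str]] | None = None  # (reference, query) groups
    ks_mode: str = KS_CURVE_VALUES
    max_gq: int = DEFAULT_MAX_GQ
    seed: int = 0
    log_level: str = "INFO"


def default_comparisons(groups: list[str]) -> list[tuple[str, str]]:
    """All non-frozen groups against the frozen control of the same analyte."""
    out = []
    for group in groups:
        analyte = group.split()[0]
        reference = f"{analyte} FR"
        if group != reference and reference in groups:
            out.append((reference, group))
    return out


@dataclass
class RunResult:
    summaries: pd.DataFrame
    curves: pd.DataFrame
    ks_results: pd.DataFrame
    class_gq: pd.DataFrame
    written: dict[str, Path] = field(default_factory=dict)


def run(config: RunConfig) -> RunResult:
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    entries = read_sample_sheet(config.sample_sheet)
    callsets: list[CallSet] = [
        read_callset(path, meta) for meta, path in entries
    ]
    by_group: dict[str, list[CallSet]] = {}
    for cs in callsets:
        by_group.setdefault(cs.meta.group, []).append(cs)

    comparisons = config.comparisons or default_comparisons(sorted(by_group))
    for ref_group, query_group in comparisons:
        for group in (ref_group, query_group):
            if group not in by_group:
                raise ConfigError(f"comparison group {group!r} not in sample sheet")

    # --- pairwise classification -------------------------------------------
    summary_rows: list[dict] = []
    summaries = []
    classified_by_group: dict[str, list] = {}
    for ref_group, query_group in comparisons:
        ref_by_patient = {
            (cs.meta.patient_id, cs.meta.tissue): cs for cs in by_group[ref_group]
        }
        unmatched = [
            f"{cs.meta.patient_id}/{cs.meta.tissue}"
            for cs in by_group[query_group]
            if (cs.meta.patient_id, cs.meta.tissue) not in ref_by_patient
        ]
        if unmatched:
            raise ConfigError(
                f"comparison {ref_group!r} vs {query_group!r}: no reference "
                f"sample for {unmatched}"
            )
        for query_cs in by_group[query_group]:
            ref_cs = ref_by_patient[(query_cs.meta.patient_id, query_cs.meta.tissue)]
            classified = classify_pair(ref_cs, query_cs)
            classified_by_group.setdefault(query_group, []).extend(classified)
            summary = summarize_pair(
                classified,
                query_cs.total_snps,
                pair_id=(query_cs.meta.patient_id, query_group, ref_group),
            )
            summaries.append(summary)
            row = {
                "level": "pair",
                "patient_id": query_cs.meta.patient_id,
                "tissue": query_cs.meta.tissue,
                "reference_group": ref_group,
                "query_group": query_group,
                "denominator": summary.denominator,
                "unique_to_reference_count": summary.counts[UNIQUE_TO_REFERENCE],
            }
            for label in QUERY_CLASSES:
                row[f"count_{label}"] = summary.counts[label]
                row[f"percent_{label}"] = summary.percents[label]
            summary_rows.append(row)

    group_means = aggregate_group(summaries) if summaries else {}
    for group in sorted(group_means):
        row = {
            "level": "group_mean",
            "patient_id": "",
            "tissue": "",
            "reference_group": "",
            "query_group": group,
            "denominator": pd.NA,
            "unique_to_reference_count": pd.NA,
        }
        for label in QUERY_CLASSES:
            row[f"percent_{label}"] = group_means[group][label]
        summary_rows.append(row)
    summaries_df = pd.DataFrame(summary_rows)

    # --- pooled GQ curves and KS matrix ------------------------------------
    pooled = pool_group(callsets)
    curve_rows: list[dict] = []
    curves = {}
    for group in sorted(pooled):
        curve = cumulative_curve(pooled[group], max_gq=config.max_gq, group_label=group)
        curves[group] = curve
        for gq, pct in zip(curve.grid, curve.cum_percent):
            curve_rows.append(
                {
                    "group": group,
                    "gq": int(gq),
                    "cum_percent": float(pct),
                    "n_pooled": curve.n_pooled,
                }
            )
    curves_df = pd.DataFrame(curve_rows)

    ks_rows: list[dict] = []
    for ref_group, query_group in comparisons:
        if config.ks_mode == KS_CURVE_VALUES:
            result = ks_compare(
                curves[ref_group], curves[query_group],
                mode=config.ks_mode, max_gq=config.max_gq,
            )
        else:
            result = ks_compare(
                pooled[ref_group], pooled[query_group],
                mode=config.ks_mode, max_gq=config.max_gq,
            )
        ks_rows.append(
            {
                "group_a": ref_group,
                "group_b": query_group,
                "d_statistic": result.d_statistic,
                "p_value": result.p_value,
                "mode": result.mode,
                "n_a": result.n_a,
                "n_b": result.n_b,
            }
        )
    ks_df = pd.DataFrame(
        ks_rows,
        columns=["group_a", "group_b", "d_statistic", "p_value", "mode", "n_a", "n_b"],
    )

    # --- per-class GQ means (no max-GQ exclusion) ---------------------------
    gq_rows: list[dict] = []
    for group in sorted(classified_by_group):
        for row in class_gq_summary(classified_by_group[group], group_label=group):
            gq_rows.append(
                {
                    "group": row.group_label,
                    "class": row.class_label,
                    "mean_gq": row.mean_gq,
                    "sd_gq": row.sd_gq,
                    "n": row.n,
                }
            )
    class_gq_df = pd.DataFrame(
        gq_rows, columns=["group", "class", "mean_gq", "sd_gq", "n"]
    )

    manifest = {
        "package_version": __version__,
        "sample_sheet": str(config.sample_sheet),
        "comparisons": [list(c) for c in comparisons],
        "ks_mode": config.ks_mode,
        "max_gq": config.max_gq,
        "seed": config.seed,
        "n_samples": len(callsets),
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "comparisons": [list(c) for c in comparisons],
                    "ks_mode": config.ks_mode,
                    "max_gq": config.max_gq,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    written = write_reports(
        config.out_dir,
        summaries=summaries_df,
        curves=curves_df,
        ks_results=ks_df,
        class_gq=class_gq_df,
        manifest=manifest,
    )
    return RunResult(
        summaries=summaries_df,
        curves=curves_df,
        ks_results=ks_df,
        class_gq=class_gq_df,
        written=written,
    )


def plot_curves(curves_df: pd.DataFrame, out_path: str | Path) -> Path:
    """Plot cumulative-percent GQ curves, one line per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for group, sub in curves_df.groupby("group"):
        ax.step(sub["gq"], sub["cum_percent"], where="post", label=group)
    ax.set_xlabel("GQ score")
    ax.set_ylabel("Cumulative percent of SNPs at or below GQ")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
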