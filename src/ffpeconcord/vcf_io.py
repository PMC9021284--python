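"""Single-sample VCF input/output and uncapped genotype-quality recomputation.

A germline caller emits, per called genotype, a vector of Phred-scaled,
min-normalised genotype likelihoods (``PL``).  Genotype quality (``GQ``) is
the difference between the two smallest PL entries — the Phred-scaled margin
by which the called genotype beats the runner-up.  Callers conventionally cap
GQ at 99; this module recomputes it from PL *without* the cap so that the
full quality range (well above 99) is available to downstream distribution
comparisons.

Only diploid genotypes are supported.  No-call (``./.``) and
homozygous-reference genotypes are never part of a :class:`CallSet`: the
analysis concerns variant calls only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConsistencyError, MalformedRecordError

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int]

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS_ALT = "homozygous_alt"

SNV = "SNV"
INS = "INS"
DEL = "DEL"
MNV = "MNV"

PRESERVATIONS = ("FR", "FFPE_12h", "FFPE_72h")


def compute_gq(pl: Sequence[int], *, cap: bool = False, site: str | None = None) -> int:
    """Genotype quality from a PL vector: second-smallest minus smallest.

    Parameters
    ----------
    pl
        Phred-scaled genotype likelihoods, one per candidate genotype.
    cap
        If True, apply the conventional caller cap of 99.  The default is the
        uncapped value.
    site
        Optional site label used in error messages.

    Raises
    ------
    MalformedRecordError
        If fewer than two PL entries are present (no runner-up genotype).
    """
    values = sorted(int(x) for x in pl)
    if len(values) < 2:
        where = f" at {site}" if site else ""
        raise MalformedRecordError(
            f"PL vector{where} has {len(values)} entries; need at least 2"
        )
    gq = values[1] - values[0]
    return min(gq, 99) if cap else gq


def classify_variant_form(ref_allele: str, called_alt_alleles: Sequence[str]) -> str:
    """Classify a called genotype as SNV, INS, DEL or MNV from its alleles.

    The form is judged against the record's REF allele: single-base
    substitutions are SNVs, length-increasing alleles insertions,
    length-decreasing alleles deletions; same-length multi-base replacements
    and mixed combinations fall into the MNV/other bucket.
    """
    forms = set()
    for alt in called_alt_alleles:
        if len(alt) == len(ref_allele) == 1:
            forms.add(SNV)
        elif len(alt) > len(ref_allele):
            forms.add(INS)
        elif len(alt) < len(ref_allele):
            forms.add(DEL)
        else:
            forms.add(MNV)
    if len(forms) == 1:
        return forms.pop()
    return MNV


@dataclass(frozen=True)
class GenotypeCall:
    """One called (non-reference, non-missing) diploid genotype at one site."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: tuple[str, ...]
    gt_indices: tuple[int, int]  # allele indices, 0 = REF
    phased: bool
    pl: tuple[int, ...] | None
    gq_uncapped: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedRecordError(f"position {self.pos} < 1 at {self.site_label}")
        n_alleles = 1 + len(self.alt_alleles)
        if any(i < 0 or i >= n_alleles for i in self.gt_indices):
            raise MalformedRecordError(
                f"genotype indices {self.gt_indices} out of range at {self.site_label}"
            )
        if self.gt_indices == (0, 0):
            raise MalformedRecordError(
                f"homozygous-reference genotype not allowed in a CallSet ({self.site_label})"
            )

    @property
    def site(self) -> SiteKey:
        return (self.contig, self.pos)

    @property
    def site_label(self) -> str:
        return f"{self.contig}:{self.pos}"

    @property
    def zygosity(self) -> str:
        a, b = self.gt_indices
        return HOMOZYGOUS_ALT if a == b else HETEROZYGOUS

    @property
    def allele_pair(self) -> tuple[str, str]:
        """The two called alleles as concrete strings, order-normalised."""
        alleles = (self.ref_allele, *self.alt_alleles)
        pair = sorted(alleles[i] for i in self.gt_indices)
        return (pair[0], pair[1])

    @property
    def called_alt_alleles(self) -> tuple[str, ...]:
        """Distinct non-reference alleles in the called genotype."""
        alleles = (self.ref_allele, *self.alt_alleles)
        seen: list[str] = []
        for i in self.gt_indices:
            if i != 0 and alleles[i] not in seen:
                seen.append(alleles[i])
        return tuple(seen)

    @property
    def variant_form(self) -> str:
        return classify_variant_form(self.ref_allele, self.called_alt_alleles)


@dataclass(frozen=True)
class SampleMeta:
    """Identity and experimental-group metadata of one sequenced sample."""

    sample_id: str
    patient_id: str
    tissue: str  # kidney / ovary / synthetic
    analyte: str  # DNA / RNA
    preservation: str  # FR / FFPE_12h / FFPE_72h
    org_treated: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.preservation not in PRESERVATIONS:
            raise ValueError(
                f"preservation {self.preservation!r} not one of {PRESERVATIONS}"
            )

    @property
    def group(self) -> str:
        """Treatment-group label, e.g. ``'DNA FFPE_12h ORG'`` or ``'DNA FR'``."""
        label = f"{self.analyte} {self.preservation}"
        return f"{label} ORG" if self.org_treated else label


@dataclass
class CallSet:
    """All variant calls of one sample, keyed by genomic site."""

    meta: SampleMeta
    calls: dict[SiteKey, GenotypeCall] = field(default_factory=dict)

    @property
    def total_snps(self) -> int:
        return len(self.calls)

    def gq_values(self) -> np.ndarray:
        return np.fromiter(
            (c.gq_uncapped for c in self.calls.values()), dtype=np.int64, count=len(self.calls)
        )

    def add(self, call: GenotypeCall) -> None:
        if call.site in self.calls:
            raise ConsistencyError(f"duplicate call at {call.site_label}")
        self.calls[call.site] = call


def read_callset(
    vcf_path: str | Path,
    meta: SampleMeta,
    *,
    sample: str | None = None,
    keep_filters: tuple[str, ...] = ("PASS",),
    keep_unfiltered: bool = True,
) -> CallSet:
    """Read a single-sample VCF into a :class:`CallSet`.

    Homozygous-reference and no-call genotypes are excluded.  ``gq_uncapped``
    is recomputed from PL when PL is present; when only a stored GQ exists the
    (possibly 99-capped) value is used and the record flagged in the log;
    records carrying neither are excluded with a warning.

    Parameters
    ----------
    sample
        Sample name to select from a multi-sample VCF.  Reading a
        multi-sample file without a selector is an error.
    keep_filters, keep_unfiltered
        FILTER values to retain (default: PASS, plus records with no FILTER
        set).
    """
    vcf = VCF(str(vcf_path))
    if len(vcf.samples) != 1:
        if sample is None:
            raise MalformedRecordError(
                f"{vcf_path}: VCF has {len(vcf.samples)} samples; "
                "pass sample= to select one"
            )
        vcf.close()
        vcf = VCF(str(vcf_path), samples=[sample])
        if len(vcf.samples) != 1:
            raise MalformedRecordError(f"{vcf_path}: sample {sample!r} not found")

    callset = CallSet(meta=meta)
    n_fallback_gq = 0
    n_dropped_quality = 0
    for variant in vcf:
        filt = variant.FILTER  # cyvcf2: None for PASS or '.'
        if filt is None:
            if not keep_unfiltered and "PASS" not in keep_filters:
                continue
        elif filt not in keep_filters:
            continue

        gt = variant.genotypes[0]
        allele_indices, phased = gt[:-1], bool(gt[-1])
        if len(allele_indices) != 2:
            raise MalformedRecordError(
                f"non-diploid genotype at {variant.CHROM}:{variant.POS}"
            )
        if any(i < 0 for i in allele_indices):
            continue  # no-call
        if all(i == 0 for i in allele_indices):
            continue  # homozygous reference

        site = f"{variant.CHROM}:{variant.POS}"
        pl_raw = variant.format("PL")
        pl: tuple[int, ...] | None = None
        if pl_raw is not None:
            row = [int(x) for x in np.atleast_2d(pl_raw)[0] if x >= 0]
            if len(row) >= 2:
                pl = tuple(row)
        if pl is not None:
            gq = compute_gq(pl, site=site)
        else:
            stored = variant.gt_quals[0]
            if stored is None or stored < 0 or np.isnan(stored):
                n_dropped_quality += 1
                logger.warning("%s: no PL and no GQ; record excluded", site)
                continue
            gq = int(stored)
            n_fallback_gq += 1

        callset.add(
            GenotypeCall(
                contig=variant.CHROM,
                pos=variant.POS,
                ref_allele=variant.REF,
                alt_alleles=tuple(variant.ALT),
                gt_indices=(int(allele_indices[0]), int(allele_indices[1])),
                phased=phased,
                pl=pl,
                gq_uncapped=gq,
            )
        )
    vcf.close()
    if n_fallback_gq:
        logger.warning(
            "%s: %d records lacked PL; stored (possibly capped) GQ used",
            vcf_path,
            n_fallback_gq,
        )
    return callset


def write_vcf(callset: CallSet, path: str | Path, contig_lengths: Mapping[str, int]) -> Path:
    """Write a :class:`CallSet` as a sorted single-sample VCF 4.2 text file."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
        '"Phred-scaled genotype likelihoods">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + callset.meta.sample_id
    )
    contig_order = {c: i for i, c in enumerate(contig_lengths)}
    for call in sorted(
        callset.calls.values(), key=lambda c: (contig_order.get(c.contig, 1 << 30), c.pos)
    ):
        sep = "|" if call.phased else "/"
        gt = f"{call.gt_indices[0]}{sep}{call.gt_indices[1]}"
        if call.pl is not None:
            pl_txt = ",".join(str(x) for x in call.pl)
            fmt, sample_field = "GT:PL", f"{gt}:{pl_txt}"
        else:
            fmt, sample_field = "GT:GQ", f"{gt}:{min(call.gq_uncapped, 99)}"
        lines.append(
            "\t".join(
                [
                    call.contig,
                    str(call.pos),
                    ".",
                    call.ref_allele,
                    ",".join(call.alt_alleles),
                    ".",
                    "PASS",
                    ".",
                    fmt,
                    sample_field,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_sample_sheet(path: str | Path) -> list[tuple[SampleMeta, Path]]:
    """Read a sample-sheet CSV into metadata/VCF-path pairs.

    Required columns: sample_id, patient_id, tissue, analyte, preservation,
    org_treated, vcf_path.  Relative ``vcf_path`` entries are resolved against
    the sheet's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {
        "sample_id",
        "patient_id",
        "tissue",
        "analyte",
        "preservation",
        "org_treated",
        "vcf_path",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    out: list[tuple[SampleMeta, Path]] = []
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            tissue=row.tissue,
            analyte=row.analyte,
            preservation=row.preservation,
            org_treated=str(row.org_treated).strip().lower() in {"true", "1", "yes"},
        )
        vcf_path = Path(row.vcf_path)
        if not vcf_path.is_absolute():
            vcf_path = path.parent / vcf_path
        out.append((meta, vcf_path))
    return out


_FLOAT_FMT = "%.6f"


def write_reports(
    out_dir: str | Path,
    *,
    summaries: pd.DataFrame | None = None,
    curves: pd.DataFrame | None = None,
    ks_results: pd.DataFrame | None = None,
    class_gq: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write analysis outputs as TSV tables plus a JSON run manifest.

    Tables are written with 6-decimal floats so repeated runs at the same
    configuration are byte-identical.  Empty tables are written with headers.
    Returns a mapping from table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "class_percent": summaries,
        "gq_curves": curves,
        "ks_matrix": ks_results,
        "class_gq_summary": class_gq,
    }
    for name, df in tables.items():
        if df is None:
            continue
        target = out_dir / f"{name}.tsv"
        df.to_csv(target, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[name] = target
    if manifest is not None:
        target = out_dir / "run_manifest.json"
        target.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = target
    return written
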