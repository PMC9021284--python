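"""Four-class SNP concordance classification for patient-matched call-set pairs.

Every site in the union of a reference (frozen) and query (FFPE-side) call
set receives exactly one class:

* ``concordant`` — identical unordered called-allele pair in both samples;
* ``unique_to_query`` / ``unique_to_reference`` — called in only one sample;
* ``zygosity_change`` — shared site, heterozygous in one sample and
  homozygous in the other.  Zygosity dominates: the class applies regardless
  of whether the alleles also differ, and the direction
  (``hetero_to_homo`` / ``homo_to_hetero``) is oriented query relative to
  reference — the direction in which FFPE allelic dropout converts true
  heterozygotes into apparent homozygotes;
* ``genotype_change`` — shared site, same zygosity, different alleles,
  labelled by the allele transition (``T_to_A``, ``INS_to_DEL``, ...) again
  oriented query relative to reference.

Class counts are normalised to percentages of the query sample's total SNP
count; unique-to-reference calls sit outside that budget and are reported as
counts only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError
from .vcf_io import (
    DEL,
    HETEROZYGOUS,
    INS,
    MNV,
    SNV,
    CallSet,
    GenotypeCall,
    SiteKey,
)

CONCORDANT = "concordant"
UNIQUE_TO_QUERY = "unique_to_query"
UNIQUE_TO_REFERENCE = "unique_to_reference"
ZYGOSITY_CHANGE = "zygosity_change"
GENOTYPE_CHANGE = "genotype_change"

HET_TO_HOM = "hetero_to_homo"
HOM_TO_HET = "homo_to_hetero"
NOT_APPLICABLE = "not_applicable"

#: Classes whose calls are present in the query sample; together they account
#: for 100% of the query sample's SNPs.
QUERY_CLASSES = (CONCORDANT, UNIQUE_TO_QUERY, ZYGOSITY_CHANGE, GENOTYPE_CHANGE)


@dataclass(frozen=True)
class PairClassifiedVariant:
    site: SiteKey
    class_label: str
    zygosity_direction: str = NOT_APPLICABLE
    genotype_transition: str = NOT_APPLICABLE
    gq_query: int | None = None
    gq_reference: int | None = None


@dataclass
class ConcordanceSummary:
    """Class counts and query-anchored percentages for one matched pair."""

    pair_id: tuple[str, str, str]  # (patient, query group, reference group)
    counts: dict[str, int]
    percents: dict[str, float]
    denominator: int


def allele_symbol(call: GenotypeCall) -> str:
    """The transition-label symbol of a call: its alt base, INS, DEL or MNV.

    SNVs are labelled by the substituted base; alleles whose length differs
    from REF map to INS/DEL; multi-nucleotide and mixed (two distinct
    non-reference alleles) genotypes map to MNV.
    """
    alts = call.called_alt_alleles
    if len(alts) != 1:
        return MNV
    alt = alts[0]
    if len(alt) == len(call.ref_allele) == 1:
        return alt
    if len(alt) > len(call.ref_allele):
        return INS
    if len(alt) < len(call.ref_allele):
        return DEL
    return MNV


def _check_ref_consistency(ref_call: GenotypeCall, query_call: GenotypeCall) -> None:
    """REF strings at a shared site must come from the same reference genome.

    Indel records anchor different REF lengths at the same position, so the
    shorter REF must be a prefix of the longer; anything else means the two
    VCFs were called against different references.
    """
    a, b = ref_call.ref_allele, query_call.ref_allele
    if not (a.startswith(b) or b.startswith(a)):
        raise ConsistencyError(
            f"REF disagreement at {ref_call.site_label}: {a!r} vs {b!r}"
        )


def classify_pair(reference: CallSet, query: CallSet) -> list[PairClassifiedVariant]:
    """Classify every site in the union of two patient-matched call sets.

    Precedence at shared sites: identical allele pair → concordant; differing
    zygosity → zygosity change (even if the alleles also differ); same
    zygosity with different alleles → genotype change.
    """
    if reference.meta.patient_id != query.meta.patient_id:
        raise ConsistencyError(
            "patient mismatch: "
            f"{reference.meta.patient_id!r} vs {query.meta.patient_id!r}"
        )
    union = sorted(set(reference.calls) | set(query.calls))
    out: list[PairClassifiedVariant] = []
    for site in union:
        ref_call = reference.calls.get(site)
        query_call = query.calls.get(site)
        if ref_call is None:
            out.append(
                PairClassifiedVariant(
                    site=site,
                    class_label=UNIQUE_TO_QUERY,
                    gq_query=query_call.gq_uncapped,
                )
            )
            continue
        if query_call is None:
            out.append(
                PairClassifiedVariant(
                    site=site,
                    class_label=UNIQUE_TO_REFERENCE,
                    gq_reference=ref_call.gq_uncapped,
                )
            )
            continue
        _check_ref_consistency(ref_call, query_call)
        gqs = dict(gq_query=query_call.gq_uncapped, gq_reference=ref_call.gq_uncapped)
        if ref_call.allele_pair == query_call.allele_pair:
            out.append(PairClassifiedVariant(site=site, class_label=CONCORDANT, **gqs))
        elif ref_call.zygosity != query_call.zygosity:
            direction = (
                HET_TO_HOM if ref_call.zygosity == HETEROZYGOUS else HOM_TO_HET
            )
            out.append(
                PairClassifiedVariant(
                    site=site,
                    class_label=ZYGOSITY_CHANGE,
                    zygosity_direction=direction,
                    **gqs,
                )
            )
        else:
            transition = f"{allele_symbol(ref_call)}_to_{allele_symbol(query_call)}"
            out.append(
                PairClassifiedVariant(
                    site=site,
                    class_label=GENOTYPE_CHANGE,
                    genotype_transition=transition,
                    **gqs,
                )
            )
    return out


def summarize_pair(
    classified: Sequence[PairClassifiedVariant],
    query_total: int,
    pair_id: tuple[str, str, str] = ("", "", ""),
) -> ConcordanceSummary:
    """Normalise class counts by the query sample's total SNP count.

    The four query-containing classes sum to 100%; unique-to-reference calls
    are carried as a count only.
    """
    if query_total <= 0:
        raise ValueError("query_total must be positive")
    counts = {label: 0 for label in (*QUERY_CLASSES, UNIQUE_TO_REFERENCE)}
    for record in classified:
        counts[record.class_label] += 1
    n_query = sum(counts[label] for label in QUERY_CLASSES)
    if query_total < n_query:
        raise ValueError(
            f"query_total {query_total} smaller than classified query calls {n_query}"
        )
    percents = {label: 100.0 * counts[label] / query_total for label in QUERY_CLASSES}
    return ConcordanceSummary(
        pair_id=pair_id, counts=counts, percents=percents, denominator=query_total
    )


def aggregate_group(
    summaries: Iterable[ConcordanceSummary],
    grouping: Callable[[ConcordanceSummary], str] = lambda s: s.pair_id[1],
) -> dict[str, dict[str, float]]:
    """Mean per-class percentages across patient pairs within each group.

    ``grouping`` maps a summary to its group key (default: the query group of
    the pair id).  Raises on an empty input.
    """
    buckets: dict[str, list[ConcordanceSummary]] = {}
    for summary in summaries:
        buckets.setdefault(grouping(summary), []).append(summary)
    if not buckets:
        raise ValueError("no summaries to aggregate")
    out: dict[str, dict[str, float]] = {}
    for group, members in buckets.items():
        out[group] = {
            label: float(np.mean([m.percents[label] for m in members]))
            for label in QUERY_CLASSES
        }
    return out
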