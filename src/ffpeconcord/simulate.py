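"""Synthetic patient-matched frozen/FFPE call-set pairs with known truth.

The generator emulates the artifact structure that formalin fixation imposes
on germline variant calls, so the whole concordance analysis can run at desk
scale against a known ground truth:

* most calls are either concordant between preparations or unique to one of
  them (the unique fraction on the FFPE side is the dominant artifact class);
* a few percent of shared sites flip zygosity, biased het→hom — the
  signature of allelic dropout, where one allele of a true heterozygote is
  preferentially lost during fixation/extraction;
* a sub-0.1% sliver of shared sites changes genotype outright, dominated by
  insertion/deletion transitions;
* concordant calls carry far higher genotype quality than artifact calls —
  the two GQ-generating distributions are discretised gammas whose modes sit
  orders of magnitude apart, and artifact GQ is uncapped so values above 99
  and 300 occur.

Class rates are configured as fractions of the FFPE-side (query) call set,
which is also the denominator the concordance summary uses, so configured
rates are directly recoverable from classifier output.

No read-level or sequence-context modelling is attempted: classification
never inspects flanking sequence, so a handful of toy contigs with random
positions suffices.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concordance import (
    CONCORDANT,
    GENOTYPE_CHANGE,
    HET_TO_HOM,
    HOM_TO_HET,
    NOT_APPLICABLE,
    UNIQUE_TO_QUERY,
    UNIQUE_TO_REFERENCE,
    ZYGOSITY_CHANGE,
    allele_symbol,
)
from .errors import ConfigError
from .vcf_io import (
    DEL,
    HETEROZYGOUS,
    INS,
    CallSet,
    GenotypeCall,
    SampleMeta,
    write_vcf,
)

BASES = ("A", "C", "G", "T")

#: Toy reference contigs (name → length); positions are drawn without
#: replacement, no real genome is involved.
CONTIGS: dict[str, int] = {
    "sim1": 8_000_000,
    "sim2": 6_000_000,
    "sim3": 5_000_000,
    "sim4": 4_000_000,
}

#: Default genotype-transition weights: indel transitions dominate, with
#: T→A and A→G the most common base substitutions.
DEFAULT_TRANSITION_WEIGHTS: dict[tuple[str, str], float] = {
    (INS, DEL): 0.30,
    (DEL, INS): 0.22,
    (INS, INS): 0.08,
    (DEL, DEL): 0.06,
    ("T", "A"): 0.12,
    ("A", "G"): 0.09,
    ("A", "T"): 0.05,
    ("C", "T"): 0.04,
    ("G", "A"): 0.04,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one frozen/FFPE pair simulation.

    Rates ``p_unique_artifact``, ``p_zygosity_change`` and
    ``p_genotype_change`` are target fractions of the *query* (FFPE-side)
    call set — the same denominator the concordance summary uses.
    ``p_missed_in_query`` is the per-reference-site probability that a frozen
    call is absent from the FFPE sample.  GQ distributions are gamma
    (shape, scale) pairs, discretised and clipped to [0, 3000].
    """

    seed: int = 0
    n_patients: int = 4
    n_true_variants: int = 10_000
    het_fraction: float = 0.65
    p_unique_artifact: float = 0.609
    p_missed_in_query: float = 0.30
    p_zygosity_change: float = 0.022
    zygosity_het_to_hom_bias: float = 0.9
    p_genotype_change: float = 0.0003
    genotype_transition_weights: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_WEIGHTS)
    )
    gq_concordant_params: tuple[float, float] = (2.5, 120.0)
    gq_artifact_params: tuple[float, float] = (1.5, 8.0)
    indel_fraction: float = 0.10
    max_gq_value: int = 3000

    def __post_init__(self) -> None:
        probs = {
            "het_fraction": self.het_fraction,
            "p_unique_artifact": self.p_unique_artifact,
            "p_missed_in_query": self.p_missed_in_query,
            "p_zygosity_change": self.p_zygosity_change,
            "p_genotype_change": self.p_genotype_change,
            "indel_fraction": self.indel_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if not 0.5 <= self.zygosity_het_to_hom_bias <= 1.0:
            raise ConfigError("zygosity_het_to_hom_bias must lie in [0.5, 1]")
        if self.p_zygosity_change + self.p_genotype_change + self.p_missed_in_query > 1:
            raise ConfigError("artifact rates sum above 1")
        if self.p_unique_artifact >= 1.0:
            raise ConfigError("p_unique_artifact must be < 1")
        if not 0.0 < self.het_fraction < 1.0:
            raise ConfigError("het_fraction must be strictly inside (0, 1)")
        # Per-shared-site conditional probabilities must stay feasible.
        q_z, q_g = self.shared_site_rates()
        het_rate = q_z * self.zygosity_het_to_hom_bias / self.het_fraction
        hom_rate = (
            q_z * (1 - self.zygosity_het_to_hom_bias) / (1 - self.het_fraction)
        )
        if het_rate + q_g > 1 or hom_rate + q_g > 1:
            raise ConfigError(
                "infeasible rates: per-site zygosity/genotype change "
                "probability exceeds 1 for the configured het_fraction"
            )
        for (src, dst), weight in self.genotype_transition_weights.items():
            if weight < 0:
                raise ConfigError(f"negative transition weight for {src}->{dst}")

    def shared_site_rates(self) -> tuple[float, float]:
        """Per-shared-site zygosity/genotype change probabilities.

        Query-anchored rates p are converted with q = p / (1 − p_unique) so
        that changed sites make up fraction p of the final query call set.
        """
        denom = 1.0 - self.p_unique_artifact
        return (self.p_zygosity_change / denom, self.p_genotype_change / denom)


@dataclass
class SimTruth:
    """Per-site ground truth of one simulated pair."""

    table: pd.DataFrame  # contig, pos, true_class, subtype, gq_reference, gq_query

    def class_counts(self) -> pd.Series:
        return self.table["true_class"].value_counts()


def _patient_rng(seed: int, *tokens: str) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(parts)


def _draw_gq(rng: np.random.Generator, params: tuple[float, float], cap: int) -> int:
    shape, scale = params
    return int(min(cap, round(rng.gamma(shape, scale))))


def _pl_vector(
    rng: np.random.Generator, gt: tuple[int, int], n_alts: int, gq: int
) -> tuple[int, ...]:
    """A PL vector whose two smallest entries are 0 and ``gq`` exactly."""
    n_genotypes = (n_alts + 1) * (n_alts + 2) // 2
    i, j = sorted(gt)
    called = j * (j + 1) // 2 + i
    pl = gq + rng.integers(1, 500, size=n_genotypes)
    pl[called] = 0
    others = [k for k in range(n_genotypes) if k != called]
    pl[others[int(rng.integers(0, len(others)))]] = gq
    return tuple(int(x) for x in pl)


def _random_suffix(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[int(i)] for i in rng.integers(0, 4, size=length))


def _random_alleles(rng: np.random.Generator, indel_fraction: float) -> tuple[str, str]:
    """Draw (REF, ALT) for a random variant: SNV, insertion or deletion."""
    base = BASES[int(rng.integers(0, 4))]
    if rng.random() < indel_fraction:
        suffix = _random_suffix(rng, int(rng.integers(1, 4)))
        if rng.random() < 0.5:
            return base, base + suffix  # insertion
        return base + suffix, base  # deletion
    alt = BASES[int(rng.integers(0, 3))]
    if alt == base:  # skip the REF base in the 3-way draw
        alt = BASES[3]
    return base, alt


def _make_call(
    rng: np.random.Generator,
    contig: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    het: bool,
    gq: int,
) -> GenotypeCall:
    gt = (0, 1) if het else (1, 1)
    return GenotypeCall(
        contig=contig,
        pos=pos,
        ref_allele=ref_allele,
        alt_alleles=(alt_allele,),
        gt_indices=gt,
        phased=False,
        pl=_pl_vector(rng, gt, 1, gq),
        gq_uncapped=gq,
    )


def _unique_sites(
    rng: np.random.Generator, n: int, taken: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Draw n site keys without replacement, avoiding already-taken keys."""
    names = list(CONTIGS)
    lengths = np.array([CONTIGS[c] for c in names])
    weights = lengths / lengths.sum()
    sites: list[tuple[str, int]] = []
    seen = set(taken)
    while len(sites) < n:
        batch = max(64, int((n - len(sites)) * 1.2))
        contigs = rng.choice(len(names), size=batch, p=weights)
        for ci in contigs:
            pos = int(rng.integers(1, lengths[ci] + 1))
            key = (names[int(ci)], pos)
            if key not in seen:
                seen.add(key)
                sites.append(key)
                if len(sites) == n:
                    break
    return sites


def simulate_reference(
    config: SimConfig,
    patient_id: str,
    sample_id: str | None = None,
    tissue: str = "synthetic",
    analyte: str = "DNA",
) -> CallSet:
    """Generate the frozen-side (reference) call set of one patient."""
    rng = _patient_rng(config.seed, patient_id, "reference")
    meta = SampleMeta(
        sample_id=sample_id or f"{patient_id}_FR",
        patient_id=patient_id,
        tissue=tissue,
        analyte=analyte,
        preservation="FR",
        org_treated=False,
    )
    callset = CallSet(meta=meta)
    for contig, pos in _unique_sites(rng, config.n_true_variants, set()):
        ref_allele, alt_allele = _random_alleles(rng, config.indel_fraction)
        het = rng.random() < config.het_fraction
        gq = _draw_gq(rng, config.gq_concordant_params, config.max_gq_value)
        callset.add(_make_call(rng, contig, pos, ref_allele, alt_allele, het, gq))
    return callset


def _transition_target(
    rng: np.random.Generator,
    config: SimConfig,
    source_symbol: str,
    ref_base: str,
    het: bool,
) -> str:
    """Draw the target symbol of a genotype change given the source call.

    A base target equal to the record's REF base is excluded (the "alt"
    would be the reference allele).  A homozygous DEL→DEL transition is also
    excluded: both calls would carry the identical anchor-base allele pair
    and be indistinguishable from a concordant call.
    """
    options: list[str] = []
    weights: list[float] = []
    for (src, dst), weight in config.genotype_transition_weights.items():
        if src != source_symbol or weight <= 0:
            continue
        if dst in BASES and (dst == src or dst == ref_base):
            continue  # target must be a genuine non-reference substitution
        if source_symbol == DEL and dst == DEL and not het:
            continue
        options.append(dst)
        weights.append(weight)
    if not options:  # no configured outgoing transition: any other base
        options = [b for b in BASES if b != source_symbol and b != ref_base]
        weights = [1.0] * len(options)
    probs = np.asarray(weights) / np.sum(weights)
    return options[int(rng.choice(len(options), p=probs))]


def _realize_target_call(
    rng: np.random.Generator,
    source: GenotypeCall,
    target_symbol: str,
    het: bool,
    gq: int,
) -> GenotypeCall:
    """Build the query-side call realizing a genotype transition.

    The new record anchors at the same position; indel REF strings share the
    source record's anchor base so both VCFs stay consistent with one
    reference genome.
    """
    anchor = source.ref_allele[0]
    if target_symbol == INS:
        while True:
            alt = anchor + _random_suffix(rng, int(rng.integers(1, 4)))
            if (anchor, alt) != (source.ref_allele, source.alt_alleles[0]):
                break
        ref_allele = anchor
    elif target_symbol == DEL:
        if len(source.ref_allele) > 1:
            # nested deletion: extend/truncate the source REF so one REF
            # string is a prefix of the other
            length = len(source.ref_allele) - 1
            new_len = int(rng.integers(1, 4))
            while new_len == length:
                new_len = int(rng.integers(1, 4))
            suffix = source.ref_allele[1:]
            if new_len < length:
                ref_allele = anchor + suffix[:new_len]
            else:
                ref_allele = anchor + suffix + _random_suffix(rng, new_len - length)
        else:
            ref_allele = anchor + _random_suffix(rng, int(rng.integers(1, 4)))
        alt = anchor
    else:  # base substitution
        ref_allele = anchor
        alt = target_symbol
    return _make_call(rng, source.contig, source.pos, ref_allele, alt, het, gq)


def derive_query(
    reference: CallSet,
    config: SimConfig,
    sample_id: str,
    preservation: str = "FFPE_12h",
    org_treated: bool = False,
) -> tuple[CallSet, SimTruth]:
    """Derive the FFPE-side (query) call set and truth table from a reference.

    Per reference site exactly one fate applies: dropped from the query,
    zygosity flip (direction-biased), genotype transition, or kept
    concordant.  Unique artifact calls are then added at new sites so the
    unique class makes up ``p_unique_artifact`` of the query call set.
    """
    rng = _patient_rng(
        config.seed, reference.meta.patient_id, "query", sample_id
    )
    meta = replace(
        reference.meta,
        sample_id=sample_id,
        preservation=preservation,
        org_treated=org_treated,
    )
    query = CallSet(meta=meta)
    q_z, q_g = config.shared_site_rates()
    bias = config.zygosity_het_to_hom_bias
    h = config.het_fraction
    truth_rows: list[dict] = []

    def record(call_ref, call_query, true_class, subtype=NOT_APPLICABLE):
        contig, pos = (call_ref or call_query).site
        truth_rows.append(
            {
                "contig": contig,
                "pos": pos,
                "true_class": true_class,
                "subtype": subtype,
                "gq_reference": call_ref.gq_uncapped if call_ref else pd.NA,
                "gq_query": call_query.gq_uncapped if call_query else pd.NA,
            }
        )

    for site in sorted(reference.calls):
        ref_call = reference.calls[site]
        if rng.random() < config.p_missed_in_query:
            record(ref_call, None, UNIQUE_TO_REFERENCE)
            continue
        het = ref_call.zygosity == HETEROZYGOUS
        # direction-aware zygosity-flip rate keeps the overall change rate at
        # q_z and the het→hom share at the configured bias
        p_flip = q_z * bias / h if het else q_z * (1 - bias) / (1 - h)
        u = rng.random()
        if u < p_flip:
            gq = _draw_gq(rng, config.gq_artifact_params, config.max_gq_value)
            flipped = _make_call(
                rng,
                ref_call.contig,
                ref_call.pos,
                ref_call.ref_allele,
                ref_call.alt_alleles[0],
                het=not het,
                gq=gq,
            )
            query.add(flipped)
            record(
                ref_call, flipped, ZYGOSITY_CHANGE, HET_TO_HOM if het else HOM_TO_HET
            )
        elif u < p_flip + q_g:
            source_symbol = allele_symbol(ref_call)
            target = _transition_target(
                rng, config, source_symbol, ref_call.ref_allele[0], het
            )
            gq = _draw_gq(rng, config.gq_artifact_params, config.max_gq_value)
            changed = _realize_target_call(rng, ref_call, target, het, gq)
            query.add(changed)
            record(
                ref_call, changed, GENOTYPE_CHANGE, f"{source_symbol}_to_{target}"
            )
        else:
            gq = _draw_gq(rng, config.gq_concordant_params, config.max_gq_value)
            kept = _make_call(
                rng,
                ref_call.contig,
                ref_call.pos,
                ref_call.ref_allele,
                ref_call.alt_alleles[0],
                het=het,
                gq=gq,
            )
            query.add(kept)
            record(ref_call, kept, CONCORDANT)

    n_shared = query.total_snps
    p_u = config.p_unique_artifact
    n_artifacts = int(round(n_shared * p_u / (1.0 - p_u)))
    taken = set(reference.calls) | set(query.calls)
    for contig, pos in _unique_sites(rng, n_artifacts, taken):
        ref_allele, alt_allele = _random_alleles(rng, config.indel_fraction)
        het = rng.random() < config.het_fraction
        gq = _draw_gq(rng, config.gq_artifact_params, config.max_gq_value)
        artifact = _make_call(rng, contig, pos, ref_allele, alt_allele, het, gq)
        query.add(artifact)
        record(None, artifact, UNIQUE_TO_QUERY)

    truth = SimTruth(
        pd.DataFrame(
            truth_rows,
            columns=["contig", "pos", "true_class", "subtype", "gq_reference", "gq_query"],
        )
    )
    return query, truth


def simulate_pair(
    config: SimConfig, patient_id: str
) -> tuple[CallSet, CallSet, SimTruth]:
    """One patient-matched (frozen reference, FFPE query, truth) triple."""
    reference = simulate_reference(config, patient_id)
    query, truth = derive_query(
        reference, config, sample_id=f"{patient_id}_FFPE"
    )
    return reference, query, truth


#: Per-group configuration deltas for the study-shaped fixture: untreated
#: FFPE has a ~60% unique fraction and low artifact GQ; organocatalyst (ORG)
#: treatment raises concordance, raises artifact GQ, and (as observed in
#: FFPE series) raises the het→hom-biased zygosity-change share.
DEFAULT_GROUP_OVERRIDES: dict[str, dict] = {
    "FFPE_12h": dict(
        p_unique_artifact=0.609,
        p_zygosity_change=0.022,
        p_genotype_change=0.0003,
        gq_artifact_params=(1.5, 8.0),
    ),
    "FFPE_72h": dict(
        p_unique_artifact=0.606,
        p_zygosity_change=0.028,
        p_genotype_change=0.0003,
        gq_artifact_params=(1.5, 6.0),
    ),
    "FFPE_12h ORG": dict(
        p_unique_artifact=0.50,
        p_zygosity_change=0.0378,
        p_genotype_change=0.0006,
        gq_artifact_params=(1.5, 32.0),
        gq_concordant_params=(2.5, 154.0),
    ),
    "FFPE_72h ORG": dict(
        p_unique_artifact=0.512,
        p_zygosity_change=0.053,
        p_genotype_change=0.0006,
        gq_artifact_params=(1.5, 30.0),
        gq_concordant_params=(2.5, 150.0),
    ),
}

#: Study layout: the kidney arm lacks 72-h formalin groups.
TISSUE_GROUPS: dict[str, tuple[str, ...]] = {
    "kidney": ("FFPE_12h", "FFPE_12h ORG"),
    "ovary": ("FFPE_12h", "FFPE_72h", "FFPE_12h ORG", "FFPE_72h ORG"),
}


def _group_fields(group: str) -> tuple[str, bool]:
    parts = group.split()
    return parts[0], len(parts) > 1 and parts[1] == "ORG"


def make_study_fixture(
    out_dir: str | Path,
    base_config: SimConfig | None = None,
    group_overrides: Mapping[str, Mapping] | None = None,
    tissue_groups: Mapping[str, tuple[str, ...]] | None = None,
) -> Path:
    """Write a study-shaped set of VCFs, truth tables and a sample sheet.

    For every patient × tissue a single frozen reference is generated and
    each FFPE group's query is derived from it, so all comparisons within a
    patient share the same frozen control.  Returns the sample-sheet path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_config or SimConfig()
    overrides = dict(DEFAULT_GROUP_OVERRIDES if group_overrides is None else group_overrides)
    layout = dict(TISSUE_GROUPS if tissue_groups is None else tissue_groups)

    rows: list[dict] = []

    def emit(callset: CallSet, truth: SimTruth | None = None) -> None:
        vcf_name = f"{callset.meta.sample_id}.vcf"
        write_vcf(callset, out_dir / vcf_name, CONTIGS)
        if truth is not None:
            truth.table.to_csv(
                out_dir / f"{callset.meta.sample_id}.truth.tsv", sep="\t", index=False
            )
        rows.append(
            {
                "sample_id": callset.meta.sample_id,
                "patient_id": callset.meta.patient_id,
                "tissue": callset.meta.tissue,
                "analyte": callset.meta.analyte,
                "preservation": callset.meta.preservation,
                "org_treated": callset.meta.org_treated,
                "vcf_path": vcf_name,
            }
        )

    for tissue, groups in layout.items():
        for i in range(1, base.n_patients + 1):
            patient = f"{tissue[0].upper()}{i}"
            reference = simulate_reference(
                base, patient, sample_id=f"{patient}_{tissue}_FR", tissue=tissue
            )
            emit(reference)
            for group in groups:
                config = replace(base, **overrides.get(group, {}))
                preservation, org = _group_fields(group)
                sample_id = f"{patient}_{tissue}_{group.replace(' ', '_')}"
                query, truth = derive_query(
                    reference,
                    config,
                    sample_id=sample_id,
                    preservation=preservation,
                    org_treated=org,
                )
                emit(query, truth)

    sheet = pd.DataFrame(rows)
    sheet_path = out_dir / "sample_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    return sheet_path
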