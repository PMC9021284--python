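from collections import Counter

import numpy as np
import pytest

from ffpeconcord.concordance import (
    CONCORDANT,
    GENOTYPE_CHANGE,
    HET_TO_HOM,
    HOM_TO_HET,
    NOT_APPLICABLE,
    QUERY_CLASSES,
    UNIQUE_TO_QUERY,
    UNIQUE_TO_REFERENCE,
    ZYGOSITY_CHANGE,
    aggregate_group,
    classify_pair,
    summarize_pair,
)
from ffpeconcord.errors import ConsistencyError
from ffpeconcord.simulate import SimConfig, simulate_pair
from ffpeconcord.vcf_io import CallSet, GenotypeCall, SampleMeta


def meta(patient="P1", sample="S", preservation="FR"):
    return SampleMeta(
        sample_id=sample,
        patient_id=patient,
        tissue="synthetic",
        analyte="DNA",
        preservation=preservation,
    )


def call(contig, pos, ref, alts, gt, gq=30):
    n_genotypes = (len(alts) + 1) * (len(alts) + 2) // 2
    pl = [gq + 10] * n_genotypes
    i, j = sorted(gt)
    pl[j * (j + 1) // 2 + i] = 0
    pl[[k for k in range(n_genotypes) if pl[k] != 0][0]] = gq
    return GenotypeCall(contig, pos, ref, tuple(alts), tuple(gt), False, tuple(pl), gq)


def callset(calls, patient="P1", sample="S", preservation="FR"):
    cs = CallSet(meta=meta(patient, sample, preservation))
    for c in calls:
        cs.add(c)
    return cs


def classify_single(ref_call, query_call):
    ref = callset([ref_call] if ref_call else [], sample="R")
    query = callset([query_call] if query_call else [], sample="Q", preservation="FFPE_12h")
    records = classify_pair(ref, query)
    assert len(records) == 1
    return records[0]


class TestClassifyExamples:
    def test_identical_calls_are_concordant(self):
        r = classify_single(
            call("chr1", 100, "A", ["G"], (0, 1)), call("chr1", 100, "A", ["G"], (0, 1))
        )
        assert r.class_label == CONCORDANT
        assert r.zygosity_direction == NOT_APPLICABLE

    def test_site_in_query_only_is_unique_to_query(self):
        r = classify_single(None, call("chr2", 5, "C", ["T"], (0, 1)))
        assert r.class_label == UNIQUE_TO_QUERY
        assert r.gq_reference is None and r.gq_query is not None

    def test_het_to_hom_same_allele(self):
        r = classify_single(
            call("chr1", 100, "A", ["G"], (0, 1)), call("chr1", 100, "A", ["G"], (1, 1))
        )
        assert (r.class_label, r.zygosity_direction) == (ZYGOSITY_CHANGE, HET_TO_HOM)

    def test_zygosity_dominates_allele_change(self):
        # het A/G vs hom T/T: alleles differ too, but zygosity takes precedence
        r = classify_single(
            call("chr1", 100, "A", ["G"], (0, 1)), call("chr1", 100, "A", ["T"], (1, 1))
        )
        assert (r.class_label, r.zygosity_direction) == (ZYGOSITY_CHANGE, HET_TO_HOM)
        assert r.genotype_transition == NOT_APPLICABLE

    def test_snv_genotype_change_labelled_by_alt_bases(self):
        r = classify_single(
            call("chr1", 200, "A", ["T"], (0, 1)), call("chr1", 200, "A", ["G"], (0, 1))
        )
        assert (r.class_label, r.genotype_transition) == (GENOTYPE_CHANGE, "T_to_G")

    def test_insertion_to_deletion_transition(self):
        r = classify_single(
            call("chr1", 300, "A", ["AT"], (0, 1)),
            call("chr1", 300, "ATT", ["A"], (0, 1)),
        )
        assert (r.class_label, r.genotype_transition) == (GENOTYPE_CHANGE, "INS_to_DEL")


class TestClassifyErrors:
    def test_patient_mismatch(self):
        ref = callset([], patient="P1")
        query = callset([], patient="P2", preservation="FFPE_12h")
        with pytest.raises(ConsistencyError, match="patient"):
            classify_pair(ref, query)

    def test_incompatible_ref_alleles(self):
        with pytest.raises(ConsistencyError, match="chr1:100"):
            classify_single(
                call("chr1", 100, "A", ["G"], (0, 1)),
                call("chr1", 100, "T", ["G"], (0, 1)),
            )

    def test_nested_indel_refs_are_consistent(self):
        # same genome anchors REF strings of different length at one position
        r = classify_single(
            call("chr1", 100, "A", ["G"], (0, 1)),
            call("chr1", 100, "AT", ["A"], (0, 1)),
        )
        assert r.class_label == GENOTYPE_CHANGE


class TestSummarize:
    def test_percent_arithmetic(self):
        records = (
            [_rec(CONCORDANT)] * 368
            + [_rec(UNIQUE_TO_QUERY)] * 600
            + [_rec(ZYGOSITY_CHANGE)] * 30
            + [_rec(GENOTYPE_CHANGE)] * 2
        )
        summary = summarize_pair(records, 1000)
        assert summary.percents == {
            CONCORDANT: 36.8,
            UNIQUE_TO_QUERY: 60.0,
            ZYGOSITY_CHANGE: 3.0,
            GENOTYPE_CHANGE: 0.2,
        }

    def test_all_concordant_is_100_percent(self):
        summary = summarize_pair([_rec(CONCORDANT)] * 7, 7)
        assert summary.percents[CONCORDANT] == 100.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            summarize_pair([], 0)

    def test_percents_sum_to_100(self, small_pair):
        reference, query, _ = small_pair
        summary = summarize_pair(classify_pair(reference, query), query.total_snps)
        assert sum(summary.percents.values()) == pytest.approx(100.0, abs=1e-9)


def _rec(label):
    from ffpeconcord.concordance import PairClassifiedVariant

    return PairClassifiedVariant(site=("chr1", 1), class_label=label)


class TestAggregate:
    def test_single_summary_is_identity(self):
        summary = summarize_pair([_rec(CONCORDANT)] * 4, 4, pair_id=("P1", "q", "r"))
        out = aggregate_group([summary])
        assert out["q"][CONCORDANT] == 100.0

    def test_identical_summaries_average_to_same(self):
        s = summarize_pair(
            [_rec(CONCORDANT)] * 3 + [_rec(UNIQUE_TO_QUERY)], 4, pair_id=("P1", "q", "r")
        )
        t = summarize_pair(
            [_rec(CONCORDANT)] * 3 + [_rec(UNIQUE_TO_QUERY)], 4, pair_id=("P2", "q", "r")
        )
        assert aggregate_group([s, t])["q"] == s.percents

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])


# --- independent oracle: exhaustive per-site case analysis ------------------


def oracle_classify(reference: CallSet, query: CallSet) -> dict:
    """Re-derive per-site labels from first principles, via multisets."""
    labels = {}
    for site in set(reference.calls) | set(query.calls):
        a = reference.calls.get(site)
        b = query.calls.get(site)
        if a is None:
            labels[site] = (UNIQUE_TO_QUERY, NOT_APPLICABLE)
        elif b is None:
            labels[site] = (UNIQUE_TO_REFERENCE, NOT_APPLICABLE)
        else:
            alleles_a = Counter((a.ref_allele, *a.alt_alleles)[i] for i in a.gt_indices)
            alleles_b = Counter((b.ref_allele, *b.alt_alleles)[i] for i in b.gt_indices)
            n_distinct_a = len(alleles_a)
            n_distinct_b = len(alleles_b)
            if alleles_a == alleles_b:
                labels[site] = (CONCORDANT, NOT_APPLICABLE)
            elif n_distinct_a != n_distinct_b:
                sub = HET_TO_HOM if n_distinct_a == 2 else HOM_TO_HET
                labels[site] = (ZYGOSITY_CHANGE, sub)
            else:
                labels[site] = (GENOTYPE_CHANGE, NOT_APPLICABLE)
    return labels


def busy_config(seed):
    """Elevated artifact rates so every class is well represented."""
    return SimConfig(
        seed=seed,
        n_true_variants=1000,
        p_unique_artifact=0.40,
        p_missed_in_query=0.30,
        p_zygosity_change=0.08,
        zygosity_het_to_hom_bias=0.8,
        p_genotype_change=0.05,
        indel_fraction=0.25,
    )


class TestClassifierProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_oracle(self, seed):
        reference, query, _ = simulate_pair(busy_config(seed), "P1")
        records = {r.site: r for r in classify_pair(reference, query)}
        expected = oracle_classify(reference, query)
        assert set(records) == set(expected)
        for site, (label, sub) in expected.items():
            assert records[site].class_label == label, site
            if label == ZYGOSITY_CHANGE:
                assert records[site].zygosity_direction == sub, site

    def test_partition_of_union(self, small_pair):
        reference, query, _ = small_pair
        records = classify_pair(reference, query)
        union = set(reference.calls) | set(query.calls)
        assert len(records) == len(union)
        assert {r.site for r in records} == union
        counts = Counter(r.class_label for r in records)
        assert sum(counts.values()) == len(union)

    def test_swap_symmetry(self, small_pair):
        reference, query, _ = small_pair
        fwd = classify_pair(reference, query)
        rev = classify_pair(query, reference)
        fc = Counter(r.class_label for r in fwd)
        rc = Counter(r.class_label for r in rev)
        assert fc[CONCORDANT] == rc[CONCORDANT]
        assert fc[UNIQUE_TO_QUERY] == rc[UNIQUE_TO_REFERENCE]
        assert fc[UNIQUE_TO_REFERENCE] == rc[UNIQUE_TO_QUERY]
        fz = Counter(r.zygosity_direction for r in fwd if r.class_label == ZYGOSITY_CHANGE)
        rz = Counter(r.zygosity_direction for r in rev if r.class_label == ZYGOSITY_CHANGE)
        assert fz[HET_TO_HOM] == rz[HOM_TO_HET]
        assert fz[HOM_TO_HET] == rz[HET_TO_HOM]
        rev_by_site = {r.site: r for r in rev}
        for r in fwd:
            if r.class_label == GENOTYPE_CHANGE:
                src, _, dst = r.genotype_transition.partition("_to_")
                assert rev_by_site[r.site].genotype_transition == f"{dst}_to_{src}"

    def test_pure_dropout_yields_only_het_to_hom(self):
        config = SimConfig(
            seed=2,
            n_true_variants=3000,
            p_zygosity_change=0.05,
            zygosity_het_to_hom_bias=1.0,
        )
        reference, query, _ = simulate_pair(config, "P1")
        zyg = [r for r in classify_pair(reference, query) if r.class_label == ZYGOSITY_CHANGE]
        assert zyg
        assert all(r.zygosity_direction == HET_TO_HOM for r in zyg)

    def test_recovers_generative_rates_within_3_se(self):
        config = SimConfig(seed=4, n_true_variants=10_000)
        reference, query, _ = simulate_pair(config, "P1")
        summary = summarize_pair(classify_pair(reference, query), query.total_snps)
        n = query.total_snps
        targets = {
            UNIQUE_TO_QUERY: config.p_unique_artifact,
            ZYGOSITY_CHANGE: config.p_zygosity_change,
            GENOTYPE_CHANGE: config.p_genotype_change,
        }
        for label, p in targets.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(summary.percents[label] / 100 - p) <= 3 * se + 1 / n, label
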