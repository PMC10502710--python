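"""Deletion detection, zygosity calling and population frequencies."""

import numpy as np
import pytest

from adalink.assignment import SegmentAssignment, AntibodyAssignment
from adalink.genotype import (
    GenotypeCall,
    allele_population_frequency,
    antibody_genomic_scores,
    call_zygosity,
    deletion_frequency,
    detect_deletions,
    genotype_population,
)
from adalink.germline import parse_allele_name
from adalink.usage import usage_table
from tests.test_usage import sample_from_counts

GENE = "IGHV1-1"
OTHER = "IGHV2-1"


def cohort_with_counts(gene_counts, other=5000):
    """One sample per entry; each subject has `other` reads of a filler gene."""
    samples = []
    for i, n in enumerate(gene_counts):
        counts = {("heavy", f"{OTHER}*01", "IGHJ1*01"): other}
        if n:
            counts[("heavy", f"{GENE}*01", "IGHJ1*01")] = n
        samples.append(sample_from_counts(f"s{i}", counts))
    return samples


class TestDetectDeletions:
    def test_abundant_gene_never_candidate(self):
        samples = cohort_with_counts([100, 110, 90, 105])  # ~2% everywhere
        calls = [c for c in detect_deletions(samples) if str(c.gene) == GENE]
        assert not any(c.deleted for c in calls)
        assert all(np.isnan(c.p_value) for c in calls)  # nobody was a candidate

    def test_zero_count_subject_deleted_with_closed_form_p(self):
        samples = cohort_with_counts([100, 110, 90, 0])
        calls = {c.subject_id: c for c in detect_deletions(samples) if str(c.gene) == GENE}
        call = calls["s3"]
        null = (100 + 110 + 90) / (3 * 5100)  # pooled non-candidate fraction
        assert call.null_percent == pytest.approx(null)
        # lower-tail binomial at k=0 is (1-p)^n
        assert call.p_value == pytest.approx((1 - null) ** 5000, rel=1e-9)
        assert call.deleted

    def test_insufficient_evidence_not_deleted(self):
        # candidate has few reads total: 0 observed out of 200 with null ~2%
        samples = cohort_with_counts([100, 110, 90], other=5000)
        weak = sample_from_counts("weak", {("heavy", f"{OTHER}*01", "IGHJ1*01"): 200})
        calls = {
            c.subject_id: c
            for c in detect_deletions(samples + [weak])
            if str(c.gene) == GENE
        }
        call = calls["weak"]
        # p = 0.98^200 ~ 0.018 > 0.01 -> not deleted at FDR 0.01
        assert call.p_value > 0.01
        assert not call.deleted

    def test_all_candidates_untestable(self):
        # gene present but below threshold in every subject: no null exists
        samples = cohort_with_counts([1, 1, 1])
        with pytest.warns(UserWarning, match="no null"):
            calls = [c for c in detect_deletions(samples) if str(c.gene) == GENE]
        assert not any(c.deleted for c in calls)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            detect_deletions(cohort_with_counts([100]))


def test_deletion_frequency_counts_deleted_over_all():
    samples = cohort_with_counts([100, 105, 95, 110, 98, 102, 108, 0, 0, 0])
    freq = deletion_frequency(detect_deletions(samples))
    assert freq.loc[GENE] == pytest.approx(0.3)
    assert freq.loc[OTHER] == 0.0


class TestCallZygosity:
    def _sample(self, abundances, total=1000):
        counts = {
            ("heavy", f"{GENE}*{i + 1:02d}", "IGHJ1*01"): int(round(frac * total))
            for i, frac in enumerate(abundances)
        }
        return sample_from_counts("s1", counts)

    def test_dominant_allele_homozygous(self):
        call = call_zygosity(self._sample([0.95, 0.05]), parse_allele_name(GENE))
        assert call.status == "homozygous"
        assert [str(a) for a in call.alleles] == [f"{GENE}*01"]

    def test_two_candidates_heterozygous(self):
        call = call_zygosity(self._sample([0.60, 0.35, 0.05]), parse_allele_name(GENE))
        assert call.status == "heterozygous"
        assert [str(a) for a in call.alleles] == [f"{GENE}*01", f"{GENE}*02"]

    def test_three_way_tie_takes_top_two_deterministically(self):
        call = call_zygosity(self._sample([0.34, 0.33, 0.33]), parse_allele_name(GENE))
        assert call.status == "heterozygous"
        assert [str(a) for a in call.alleles] == [f"{GENE}*01", f"{GENE}*02"]

    def test_no_candidate_unresolved(self):
        abundances = [0.2, 0.2, 0.2, 0.2, 0.2]  # nothing strictly above 20%
        call = call_zygosity(self._sample(abundances), parse_allele_name(GENE))
        assert call.status == "unresolved"
        assert call.alleles == ()

    def test_no_reads_errors(self):
        sample = sample_from_counts("s1", {("heavy", f"{OTHER}*01", "IGHJ1*01"): 10})
        with pytest.raises(ValueError, match="no reads"):
            call_zygosity(sample, parse_allele_name(GENE))


class TestPopulationFrequencies:
    def _call(self, subject, status, alleles):
        return GenotypeCall(
            subject, parse_allele_name(GENE), status,
            tuple(parse_allele_name(a) for a in alleles), {},
        )

    def test_carrier_counting(self):
        calls = [self._call(f"h{i}", "homozygous", [f"{GENE}*01"]) for i in range(4)]
        calls += [
            self._call(f"e{i}", "heterozygous", [f"{GENE}*01", f"{GENE}*02"])
            for i in range(6)
        ]
        freqs = allele_population_frequency(calls)
        assert freqs.allele_frequency.loc[f"{GENE}*01"] == pytest.approx(1.0)
        assert freqs.allele_frequency.loc[f"{GENE}*02"] == pytest.approx(0.6)

    def test_all_homozygous_same_allele(self):
        calls = [self._call(f"h{i}", "homozygous", [f"{GENE}*01"]) for i in range(5)]
        freqs = allele_population_frequency(calls)
        assert freqs.allele_frequency.loc[f"{GENE}*01"] == 1.0

    def test_deleted_and_unresolved_excluded_from_denominator(self):
        calls = [self._call(f"h{i}", "homozygous", [f"{GENE}*01"]) for i in range(2)]
        calls.append(self._call("d1", "deleted", []))
        calls.append(self._call("u1", "unresolved", []))
        freqs = allele_population_frequency(calls)
        assert freqs.allele_frequency.loc[f"{GENE}*01"] == pytest.approx(1.0)
        assert freqs.gene_deletion.loc[GENE] == pytest.approx(0.25)  # 1 of 4 subjects
        assert freqs.n_carriers.loc[GENE] == 2

    def test_uncarried_gene_warns(self):
        calls = [self._call("d1", "deleted", []), self._call("d2", "deleted", [])]
        with pytest.warns(UserWarning, match="no resolved carriers"):
            freqs = allele_population_frequency(calls)
        assert GENE not in freqs.allele_frequency.index


class TestGenomicScores:
    def _assignment(self, heavy, light):
        segs = {
            ("heavy", "V"): SegmentAssignment(
                "V", frozenset({parse_allele_name(heavy)}), 0
            ),
            ("light", "V"): SegmentAssignment(
                "V", frozenset({parse_allele_name(light)}), 0
            ),
        }
        return AntibodyAssignment("drug", segs)

    def test_hand_computed_products(self):
        heavy_calls = [
            GenotypeCall(f"s{i}", parse_allele_name(GENE), "homozygous",
                         (parse_allele_name(f"{GENE}*01"),), {})
            for i in range(9)
        ] + [GenotypeCall("s9", parse_allele_name(GENE), "deleted", (), {})]
        light_calls = [
            GenotypeCall(f"s{i}", parse_allele_name("IGKV1-1"), "heterozygous",
                         (parse_allele_name("IGKV1-1*01"), parse_allele_name("IGKV1-1*02")), {})
            for i in range(10)
        ]
        freqs = allele_population_frequency(heavy_calls + light_calls)
        heavy_sample = sample_from_counts(
            "s1", {("heavy", f"{GENE}*01", "IGHJ1*01"): 30,
                   ("heavy", f"{OTHER}*01", "IGHJ1*01"): 70}
        )
        light_sample = sample_from_counts(
            "s1", {("light", "IGKV1-1*01", "IGKJ1*01"): 100}
        )
        heavy_usage = usage_table([heavy_sample], "gene", "V", "heavy")
        light_usage = usage_table([light_sample], "gene", "V", "light")
        scores = antibody_genomic_scores(
            self._assignment(f"{GENE}*01", "IGKV1-1*01"), freqs, heavy_usage, light_usage
        )
        # allele freq: heavy 9/9 carriers = 1.0; light heterozygous everywhere = 1.0
        assert scores["allele_freq_product"] == pytest.approx(1.0)
        # non-deletion: heavy 1 - 0.1, light 1.0
        assert scores["gene_nondeletion_product"] == pytest.approx(0.9)
        # gene usage: heavy 0.3, light 1.0
        assert scores["gene_usage_product"] == pytest.approx(0.3)


class TestGenotypePopulation:
    def test_deleted_subjects_flagged(self):
        samples = cohort_with_counts([100, 105, 95, 0])
        deletions = detect_deletions(samples)
        calls = genotype_population(samples, deletions)
        by_key = {(c.subject_id, str(c.gene)): c for c in calls}
        assert by_key[("s3", GENE)].status == "deleted"
        assert by_key[("s0", GENE)].status == "homozygous"
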