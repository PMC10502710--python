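"""AIRR loading, read filtering and usage quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adalink.assignment import SegmentAssignment
from adalink.germline import parse_allele_name
from adalink.usage import (
    RepertoireSample,
    antibody_usage,
    cohort_usage_correlation,
    filter_samples,
    load_airr,
    usage_for_segment,
    usage_table,
)


def write_tsv(path, rows):
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sample_from_counts(subject, counts, cohort=None):
    """counts: {(chain, v_name, j_name): n}"""
    sample = RepertoireSample(subject_id=subject, cohort=cohort)
    for (chain, v, j), n in counts.items():
        sample.add_reads(
            chain, (parse_allele_name(v),), (parse_allele_name(j),), count=n
        )
    return sample


class TestLoadAirr:
    def test_loci_mapped_to_chains(self, tmp_path):
        path = tmp_path / "s1.tsv"
        write_tsv(
            path,
            [
                {"sequence_id": "r1", "v_call": "IGHV1-1*01", "j_call": "IGHJ1*01", "locus": "IGH"},
                {"sequence_id": "r2", "v_call": "IGKV1-1*01", "j_call": "IGKJ1*01", "locus": "IGK"},
                {"sequence_id": "r3", "v_call": "IGHV1-1*01", "j_call": "IGHJ1*01", "locus": "IGH"},
            ],
        )
        sample = load_airr(path)
        assert sample.subject_id == "s1"
        assert sample.total_reads("heavy") == 2
        assert sample.total_reads("light") == 1

    def test_multi_allele_call_credits_both(self, tmp_path):
        path = tmp_path / "s1.tsv"
        write_tsv(
            path,
            [{"sequence_id": "r1", "v_call": "IGHV1-2*02,IGHV1-2*04",
              "j_call": "IGHJ1*01", "locus": "IGH"}],
        )
        sample = load_airr(path)
        counts = sample.allele_counts("heavy", "V")
        assert counts[parse_allele_name("IGHV1-2*02")] == 1
        assert counts[parse_allele_name("IGHV1-2*04")] == 1
        # but the read counts once at gene level
        assert sample.gene_counts("heavy", "V")[parse_allele_name("IGHV1-2")] == 1

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_tsv(path, [{"sequence_id": "r1", "j_call": "IGHJ1*01", "locus": "IGH"}])
        with pytest.raises(ValueError, match="v_call"):
            load_airr(path)

    def test_unparsable_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "s1.tsv"
        write_tsv(
            path,
            [
                {"sequence_id": "r1", "v_call": "IGHV1-1*01", "j_call": "IGHJ1*01", "locus": "IGH"},
                {"sequence_id": "r2", "v_call": "garbage", "j_call": "IGHJ1*01", "locus": "IGH"},
            ],
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            sample = load_airr(path)
        assert sample.total_reads() == 1


class TestFilterSamples:
    def _sample(self, subject, n):
        return sample_from_counts(subject, {("heavy", "IGHV1-1*01", "IGHJ1*01"): n})

    def test_boundary_is_kept(self):
        samples = [self._sample(s, n) for s, n in [("a", 1999), ("b", 2000), ("c", 5000)]]
        kept = filter_samples(samples, min_reads=2000)
        assert [s.subject_id for s in kept] == ["b", "c"]

    def test_zero_threshold_is_identity(self):
        samples = [self._sample("a", 1)]
        assert filter_samples(samples, min_reads=0) == samples

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_samples([], min_reads=0)

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="below"):
            filter_samples([self._sample("a", 10)], min_reads=2000)


class TestUsageTable:
    def test_fraction_of_same_chain_reads(self):
        sample = sample_from_counts(
            "s1",
            {
                ("heavy", "IGHV1-1*01", "IGHJ1*01"): 2,
                ("heavy", "IGHV2-1*01", "IGHJ1*01"): 2,
                ("light", "IGKV1-1*01", "IGKJ1*01"): 4,
            },
        )
        table = usage_table([sample], "allele", "V", "heavy")
        assert table.median.loc["IGHV1-1*01"] == pytest.approx(0.5)

    def test_median_over_subjects(self):
        samples = [
            sample_from_counts(s, {
                ("heavy", "IGHV1-1*01", "IGHJ1*01"): n,
                ("heavy", "IGHV2-1*01", "IGHJ1*01"): 100 - n,
            })
            for s, n in [("a", 1), ("b", 2), ("c", 4)]
        ]
        table = usage_table(samples, "allele", "V", "heavy")
        assert table.median.loc["IGHV1-1*01"] == pytest.approx(0.02)

    def test_absent_allele_zero_imputed(self):
        samples = [
            sample_from_counts("a", {("heavy", "IGHV1-1*01", "IGHJ1*01"): 10}),
            sample_from_counts("b", {("heavy", "IGHV2-1*01", "IGHJ1*01"): 10}),
        ]
        table = usage_table(samples, "allele", "V", "heavy")
        assert table.per_subject.loc["IGHV1-1*01", "b"] == 0.0
        assert table.median.loc["IGHV1-1*01"] == pytest.approx(0.5)

    def test_reference_names_included(self, toy_reference):
        samples = [sample_from_counts("a", {("heavy", "IGHV1-1*01", "IGHJ1*01"): 10})]
        table = usage_table(samples, "allele", "V", "heavy", reference=toy_reference)
        assert table.median.loc["IGHV2-1*01"] == 0.0

    def test_single_call_fractions_sum_to_one(self, small_study):
        table = usage_table(small_study.samples, "allele", "V", "heavy")
        sums = table.per_subject.sum(axis=0)
        assert np.allclose(sums, 1.0)

    def test_gene_usage_bounds_allele_usage(self, small_study):
        allele = usage_table(small_study.samples, "allele", "V", "light")
        gene = usage_table(small_study.samples, "gene", "V", "light")
        summed = allele.per_subject.groupby(
            lambda name: str(parse_allele_name(name).gene_name())
        ).sum()
        # single-allele calls: gene usage equals the sum of its alleles' usage
        assert np.allclose(
            summed.sort_index().values, gene.per_subject.sort_index().values
        )

    def test_median_permutation_invariant(self, small_study):
        table = usage_table(small_study.samples, "allele", "V", "heavy")
        reversed_table = usage_table(small_study.samples[::-1], "allele", "V", "heavy")
        pd.testing.assert_series_equal(table.median, reversed_table.median)


class TestAntibodyUsage:
    def _tables(self):
        heavy = sample_from_counts(
            "a",
            {
                ("heavy", "IGHV1-1*01", "IGHJ1*01"): 8,
                ("heavy", "IGHV1-1*02", "IGHJ1*01"): 2,
                ("heavy", "IGHV2-1*01", "IGHJ1*01"): 90,
            },
        )
        light = sample_from_counts(
            "a", {("light", "IGKV1-1*01", "IGKJ1*01"): 20,
                  ("light", "IGLV1-1*01", "IGLJ1*01"): 80}
        )
        return (
            usage_table([heavy], "allele", "V", "heavy"),
            usage_table([light], "allele", "V", "light"),
        )

    def _assignment(self, heavy_alleles, light_alleles):
        from adalink.assignment import AntibodyAssignment

        segs = {
            ("heavy", "V"): SegmentAssignment(
                "V", frozenset(parse_allele_name(a) for a in heavy_alleles), 0
            ),
            ("light", "V"): SegmentAssignment(
                "V", frozenset(parse_allele_name(a) for a in light_alleles), 0
            ),
        }
        return AntibodyAssignment("drug", segs)

    def test_single_allele(self):
        heavy_t, light_t = self._tables()
        asg = self._assignment(["IGHV1-1*01"], ["IGKV1-1*01"])
        heavy, light, product = antibody_usage(asg, heavy_t, light_t)
        assert heavy == pytest.approx(0.08)
        assert light == pytest.approx(0.2)
        assert product == pytest.approx(0.016)

    def test_ties_summed(self):
        heavy_t, light_t = self._tables()
        asg = self._assignment(["IGHV1-1*01", "IGHV1-1*02"], ["IGKV1-1*01"])
        heavy, _, _ = antibody_usage(asg, heavy_t, light_t)
        assert heavy == pytest.approx(0.10)

    def test_absent_allele_warns_and_scores_zero(self):
        heavy_t, light_t = self._tables()
        asg = self._assignment(["IGHV9-9*01"], ["IGKV1-1*01"])
        with pytest.warns(UserWarning, match="absent"):
            heavy, _, product = antibody_usage(asg, heavy_t, light_t)
        assert heavy == 0.0
        assert product == 0.0


class TestCohortCorrelation:
    def _cohorts(self, flip=False):
        genes = [f"IGHV1-{i}*01" for i in range(1, 6)]
        weights = [50, 30, 10, 7, 3]
        samples = []
        for cohort in ("healthy", "disease"):
            w = weights if (cohort == "healthy" or not flip) else weights[::-1]
            counts = {("heavy", g, "IGHJ1*01"): n for g, n in zip(genes, w)}
            samples.append(sample_from_counts(f"{cohort}_1", counts, cohort=cohort))
        return samples

    def test_identical_cohorts_rho_one(self):
        samples = self._cohorts()
        rho, _ = cohort_usage_correlation(samples, "healthy", "disease")
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        samples = self._cohorts(flip=True)
        rho, _ = cohort_usage_correlation(samples, "healthy", "disease")
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_on_toy_table(self):
        samples = self._cohorts(flip=True)
        rho, _ = cohort_usage_correlation(samples, "healthy", "disease")
        a = np.array([50, 30, 10, 7, 3])
        b = a[::-1]
        expected = stats.spearmanr(a / a.sum(), b / b.sum()).statistic
        assert rho == pytest.approx(expected)

    def test_empty_cohort_errors(self):
        samples = self._cohorts()
        with pytest.raises(ValueError, match="empty cohort"):
            cohort_usage_correlation(samples, "healthy", "nonexistent")
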