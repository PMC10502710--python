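"""Per-subject immunoglobulin genotype inference from repertoire counts.

Two genomic signals are inferred from read counts alone:

* **Gene deletion** — a V gene absent from a subject's genome shows
  (near-)zero repertoire usage.  Subjects whose usage of a gene falls
  below a candidate threshold (default 0.1% of same-chain reads) are
  tested with a one-sided binomial test against the pooled usage of the
  gene in non-candidate subjects, with Benjamini-Hochberg control per
  gene (deletion declared at FDR < 0.01).

* **Zygosity** — within a carried gene, allele abundances (fraction of
  the gene's reads per allele) separate true alleles from mutation- or
  misassignment-driven noise: alleles above 20% abundance are genotype
  candidates; one candidate means homozygous, two or more means
  heterozygous for the top two.

Population summaries follow: deletion frequency of a gene is the
fraction of all subjects in which it is deleted; carrier frequency of
an allele is the fraction of the gene's carriers whose genotype
includes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .germline import AlleleName
from .usage import RepertoireSample, UsageTable, usage_for_segment

__all__ = [
    "DeletionCall",
    "GenotypeCall",
    "PopulationFrequencies",
    "detect_deletions",
    "deletion_frequency",
    "call_zygosity",
    "genotype_population",
    "allele_population_frequency",
    "antibody_genomic_scores",
]

CHAIN_OF_LOCUS = {"IGH": "heavy", "IGK": "light", "IGL": "light"}


@dataclass(frozen=True)
class DeletionCall:
    subject_id: str
    gene: AlleleName
    observed_count: int
    total_reads: int
    null_percent: float
    p_value: float  # NaN for non-candidates / untestable genes
    fdr: float
    deleted: bool


@dataclass(frozen=True)
class GenotypeCall:
    """Genotype of one subject at one gene.

    status: deleted | homozygous | heterozygous | unresolved.
    ``alleles`` holds 0, 1 or 2 names; ``candidate_abundances`` the
    observed per-allele fractions of the gene's reads.
    """

    subject_id: str
    gene: AlleleName
    status: str
    alleles: tuple[AlleleName, ...]
    candidate_abundances: Mapping[AlleleName, float]

    def __post_init__(self) -> None:
        if self.status not in ("deleted", "homozygous", "heterozygous", "unresolved"):
            raise ValueError(f"unknown status {self.status!r}")
        expected = {"deleted": 0, "unresolved": 0, "homozygous": 1, "heterozygous": 2}
        if len(self.alleles) != expected[self.status]:
            raise ValueError(f"{self.status} call with {len(self.alleles)} alleles")


def _genes_by_chain(samples: Sequence[RepertoireSample], segment: str) -> dict:
    genes: dict[AlleleName, str] = {}
    for sample in samples:
        for chain in ("heavy", "light"):
            for gene in sample.gene_counts(chain, segment):
                genes[gene] = chain
    return genes


def detect_deletions(
    samples: Sequence[RepertoireSample],
    candidate_threshold: float = 0.001,
    fdr_threshold: float = 0.01,
    segment: str = "V",
) -> list[DeletionCall]:
    """Call per-subject gene deletions across a cohort.

    For each gene (restricted to reads of its own chain): subjects with
    usage below ``candidate_threshold`` are deletion candidates; the
    null usage is the pooled fraction over non-candidate subjects; each
    candidate gets a one-sided lower-tail binomial test, BH-adjusted
    within the gene's candidate set.  Genes with no non-candidate
    subject cannot be tested and their candidates stay undeleted.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to calibrate the deletion test")
    calls: list[DeletionCall] = []
    for gene, chain in sorted(_genes_by_chain(samples, segment).items(), key=lambda kv: str(kv[0])):
        counts = np.array([s.gene_counts(chain, segment).get(gene, 0) for s in samples])
        totals = np.array([s.total_reads(chain) for s in samples])
        with np.errstate(invalid="ignore"):
            percents = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        is_candidate = percents < candidate_threshold
        non_cand_reads = int(counts[~is_candidate].sum())
        non_cand_total = int(totals[~is_candidate].sum())
        if non_cand_total == 0:
            warnings.warn(
                f"{gene}: every subject is a deletion candidate; no null available, "
                "candidates left untested",
                stacklevel=2,
            )
            null_percent = float("nan")
            p_values = np.full(int(is_candidate.sum()), np.nan)
        else:
            null_percent = non_cand_reads / non_cand_total
            p_values = np.array(
                [
                    stats.binomtest(int(k), int(n), null_percent, alternative="less").pvalue
                    for k, n in zip(counts[is_candidate], totals[is_candidate])
                ]
            )
        fdrs = np.full_like(p_values, np.nan)
        if p_values.size and not np.isnan(p_values).any():
            fdrs = multipletests(p_values, method="fdr_bh")[1]
        cand_iter = iter(range(p_values.size))
        for i, sample in enumerate(samples):
            if is_candidate[i]:
                j = next(cand_iter)
                p, q = float(p_values[j]), float(fdrs[j])
                deleted = bool(np.isfinite(q) and q < fdr_threshold)
            else:
                p = q = float("nan")
                deleted = False
            calls.append(
                DeletionCall(
                    subject_id=sample.subject_id,
                    gene=gene,
                    observed_count=int(counts[i]),
                    total_reads=int(totals[i]),
                    null_percent=float(null_percent),
                    p_value=p,
                    fdr=q,
                    deleted=deleted,
                )
            )
    return calls


def deletion_frequency(calls: Iterable[DeletionCall]) -> pd.Series:
    """Per-gene deletion frequency: deleted subjects / all subjects."""
    frame = pd.DataFrame(
        {"gene": [str(c.gene) for c in calls], "deleted": [c.deleted for c in calls]}
    )
    if frame.empty:
        raise ValueError("no deletion calls")
    return frame.groupby("gene")["deleted"].mean().rename("deletion_frequency")


def call_zygosity(
    sample: RepertoireSample,
    gene: AlleleName,
    abundance_threshold: float = 0.20,
    segment: str = "V",
) -> GenotypeCall:
    """Zygosity of one carried gene from within-gene allele abundances.

    Alleles strictly above ``abundance_threshold`` of the gene's reads
    are genotype candidates: one candidate -> homozygous, two or more ->
    heterozygous for the top two (ties broken by abundance descending,
    then allele name).  No candidate at all -> unresolved (excluded from
    population allele-frequency denominators).
    """
    chain = CHAIN_OF_LOCUS[gene.locus]
    gene_reads = sample.gene_counts(chain, segment).get(gene.gene_name(), 0)
    if gene_reads == 0:
        raise ValueError(f"{sample.subject_id}: no reads for {gene}")
    allele_counts = {
        allele: n
        for allele, n in sample.allele_counts(chain, segment).items()
        if allele.gene_name() == gene.gene_name()
    }
    abundances = {a: n / gene_reads for a, n in allele_counts.items()}
    candidates = sorted(
        (a for a, frac in abundances.items() if frac > abundance_threshold),
        key=lambda a: (-abundances[a], str(a)),
    )
    if not candidates:
        status, alleles = "unresolved", ()
    elif len(candidates) == 1:
        status, alleles = "homozygous", (candidates[0],)
    else:
        status, alleles = "heterozygous", tuple(candidates[:2])
    return GenotypeCall(
        subject_id=sample.subject_id,
        gene=gene.gene_name(),
        status=status,
        alleles=alleles,
        candidate_abundances=abundances,
    )


def genotype_population(
    samples: Sequence[RepertoireSample],
    deletion_calls: Iterable[DeletionCall],
    abundance_threshold: float = 0.20,
    segment: str = "V",
) -> list[GenotypeCall]:
    """Genotype every subject at every gene, honoring deletion calls.

    Subjects deleted for a gene get a ``deleted`` call; carriers with no
    reads for the gene are ``unresolved``.
    """
    deleted_pairs = {(c.subject_id, str(c.gene)) for c in deletion_calls if c.deleted}
    genes = sorted(_genes_by_chain(samples, segment), key=str)
    calls: list[GenotypeCall] = []
    for sample in samples:
        for gene in genes:
            if (sample.subject_id, str(gene)) in deleted_pairs:
                calls.append(GenotypeCall(sample.subject_id, gene, "deleted", (), {}))
                continue
            chain = CHAIN_OF_LOCUS[gene.locus]
            if sample.gene_counts(chain, segment).get(gene, 0) == 0:
                calls.append(GenotypeCall(sample.subject_id, gene, "unresolved", (), {}))
                continue
            calls.append(call_zygosity(sample, gene, abundance_threshold, segment))
    return calls


@dataclass
class PopulationFrequencies:
    """Population-level genotype summary.

    ``gene_deletion``: per-gene fraction of subjects with the gene
    deleted.  ``allele_frequency``: per-allele fraction of the gene's
    resolved carriers whose genotype includes the allele (heterozygotes
    count for both alleles, so a gene's allele frequencies may sum to
    more than 1).
    """

    gene_deletion: pd.Series  # index: gene name (str)
    allele_frequency: pd.Series  # index: allele name (str)
    n_carriers: pd.Series  # index: gene name (str), resolved carriers

    def allele_freq_of(self, allele: AlleleName | str) -> float:
        key = str(allele)
        if key not in self.allele_frequency.index:
            warnings.warn(f"{key}: no population frequency known; using 0", stacklevel=2)
            return 0.0
        return float(self.allele_frequency.loc[key])

    def nondeletion_of(self, gene: AlleleName | str) -> float:
        key = str(gene)
        if key not in self.gene_deletion.index:
            warnings.warn(f"{key}: no deletion frequency known; assuming never deleted",
                          stacklevel=2)
            return 1.0
        return float(1.0 - self.gene_deletion.loc[key])


def allele_population_frequency(
    genotype_calls: Sequence[GenotypeCall],
) -> PopulationFrequencies:
    """Summarize genotype calls into population frequencies.

    Deletion frequency uses all subjects as denominator; allele carrier
    frequencies use only resolved carriers (homozygous or heterozygous)
    of the gene — unresolved subjects are excluded from both sides.
    """
    if not genotype_calls:
        raise ValueError("no genotype calls")
    rows = pd.DataFrame(
        {
            "gene": [str(c.gene) for c in genotype_calls],
            "status": [c.status for c in genotype_calls],
        }
    )
    gene_deletion = (
        rows.assign(deleted=rows["status"] == "deleted").groupby("gene")["deleted"].mean()
    ).rename("deletion_frequency")
    resolved = rows["status"].isin(["homozygous", "heterozygous"])
    n_carriers = rows[resolved].groupby("gene").size().rename("n_carriers")
    carrier_counts: dict[str, int] = {}
    gene_of_allele: dict[str, str] = {}
    for call in genotype_calls:
        for allele in set(call.alleles):
            key = str(allele)
            carrier_counts[key] = carrier_counts.get(key, 0) + 1
            gene_of_allele[key] = str(call.gene)
    freq = {}
    for allele, n in carrier_counts.items():
        gene = gene_of_allele[allele]
        if gene not in n_carriers.index or n_carriers.loc[gene] == 0:
            warnings.warn(f"{gene}: carried by nobody, allele frequency omitted", stacklevel=2)
            continue
        freq[allele] = n / n_carriers.loc[gene]
    allele_frequency = pd.Series(freq, dtype=float).sort_index().rename("allele_frequency")
    uncarried = sorted(set(gene_deletion.index) - set(n_carriers.index))
    if uncarried:
        warnings.warn(
            f"genes with no resolved carriers (allele frequencies undefined): {uncarried}",
            stacklevel=2,
        )
    return PopulationFrequencies(
        gene_deletion=gene_deletion.sort_index(),
        allele_frequency=allele_frequency,
        n_carriers=n_carriers.reindex(gene_deletion.index, fill_value=0),
    )


def antibody_genomic_scores(
    assignment,
    freqs: PopulationFrequencies,
    heavy_gene_usage: UsageTable,
    light_gene_usage: UsageTable,
) -> dict[str, float]:
    """Decompose an antibody's V-allele usage into three genomic factors.

    For each chain's closest V allele(s): the population allele
    frequency, the gene non-deletion frequency, and the gene-level
    repertoire usage (each summed over ties, genes counted once); each
    factor is the product of its heavy- and light-chain scores.
    """
    if heavy_gene_usage.level != "gene" or light_gene_usage.level != "gene":
        raise ValueError("gene-level usage tables required")
    scores = {"allele_freq_product": 1.0, "gene_nondeletion_product": 1.0,
              "gene_usage_product": 1.0}
    for chain, table in (("heavy", heavy_gene_usage), ("light", light_gene_usage)):
        seg = assignment[(chain, "V")]
        genes = sorted({a.gene_name() for a in seg.closest}, key=str)
        scores["allele_freq_product"] *= sum(
            freqs.allele_freq_of(a) for a in seg.sorted_alleles
        )
        scores["gene_nondeletion_product"] *= sum(freqs.nondeletion_of(g) for g in genes)
        scores["gene_usage_product"] *= usage_for_segment(seg, table)
    return scores
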