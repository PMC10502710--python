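"""Allele- and gene-usage quantification from AIRR-format BCR repertoires.

A repertoire sample is a subject's collection of per-read germline V/J
calls (as delivered by AIRR Rearrangement TSV files, e.g. from OAS).
Usage of an allele is the fraction of a subject's same-chain reads
carrying that allele; the population-level statistic is the median of
the per-subject fractions, with subjects lacking the allele contributing
zero.  Gene-level usage credits a read to a gene once even when the
read's call lists several alleles of it.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .germline import AlleleName, AlleleNameError, GermlineReference, parse_allele_name

__all__ = [
    "RepertoireSample",
    "UsageTable",
    "load_airr",
    "write_airr",
    "filter_samples",
    "usage_table",
    "usage_for_segment",
    "antibody_usage",
    "cohort_usage_correlation",
]

logger = logging.getLogger(__name__)

LOCUS_TO_CHAIN = {"IGH": "heavy", "IGK": "light", "IGL": "light"}
AIRR_REQUIRED = ("sequence_id", "v_call", "j_call", "locus")


@dataclass
class RepertoireSample:
    """One subject's per-read V/J calls, aggregated by call signature.

    Reads with identical (chain, V-call-set, J-call-set) are collapsed
    into a count; per-allele and per-gene count tables are derived on
    demand.
    """

    subject_id: str
    cohort: str | None = None
    # chain -> Counter[(v_alleles, j_alleles)] with alleles as sorted tuples
    _reads: dict[str, Counter] = field(default_factory=dict)

    def add_reads(
        self,
        chain: str,
        v_alleles: Sequence[AlleleName],
        j_alleles: Sequence[AlleleName],
        count: int = 1,
    ) -> None:
        key = (tuple(sorted(v_alleles, key=str)), tuple(sorted(j_alleles, key=str)))
        self._reads.setdefault(chain, Counter())[key] += count

    def total_reads(self, chain: str | None = None) -> int:
        if chain is not None:
            return sum(self._reads.get(chain, Counter()).values())
        return sum(self.total_reads(c) for c in self._reads)

    def allele_counts(self, chain: str, segment: str) -> Counter:
        """Reads per allele; a multi-allele call credits every listed allele."""
        idx = 0 if segment == "V" else 1
        counts: Counter = Counter()
        for key, n in self._reads.get(chain, Counter()).items():
            for allele in key[idx]:
                counts[allele] += n
        return counts

    def gene_counts(self, chain: str, segment: str) -> Counter:
        """Reads per gene; a read counts once per distinct gene in its call."""
        idx = 0 if segment == "V" else 1
        counts: Counter = Counter()
        for key, n in self._reads.get(chain, Counter()).items():
            for gene in {a.gene_name() for a in key[idx]}:
                counts[gene] += n
        return counts

    def counts(self, chain: str, segment: str, level: str) -> Counter:
        if level == "allele":
            return self.allele_counts(chain, segment)
        if level == "gene":
            return self.gene_counts(chain, segment)
        raise ValueError(f"level must be 'allele' or 'gene', got {level!r}")


def _parse_call(raw: str) -> tuple[AlleleName, ...]:
    return tuple(parse_allele_name(tok) for tok in str(raw).split(",") if tok.strip())


def load_airr(
    path: str | Path,
    subject_id: str | None = None,
    cohort: str | None = None,
) -> RepertoireSample:
    """Load one subject's AIRR Rearrangement TSV into a repertoire sample.

    Requires the columns sequence_id, v_call, j_call and locus.
    Multi-allele calls (comma-separated) are split; rows whose calls or
    locus cannot be interpreted are skipped and counted in a warning.
    The subject id defaults to a ``subject`` column (must be unique) or
    the file stem.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AIRR_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory AIRR columns {missing}")
    if subject_id is None:
        if "subject" in table.columns:
            subjects = table["subject"].unique()
            if len(subjects) != 1:
                raise ValueError(f"{path}: expected one subject per file, found {len(subjects)}")
            subject_id = str(subjects[0])
        else:
            subject_id = path.stem
    sample = RepertoireSample(subject_id=subject_id, cohort=cohort)
    skipped = 0
    for row in table.itertuples(index=False):
        try:
            chain = LOCUS_TO_CHAIN[row.locus]
            v_alleles = _parse_call(row.v_call)
            j_alleles = _parse_call(row.j_call)
            if not v_alleles or not j_alleles:
                raise AlleleNameError("empty call")
        except (KeyError, AlleleNameError):
            skipped += 1
            continue
        sample.add_reads(chain, v_alleles, j_alleles)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} rows with unparsable calls", stacklevel=2)
    return sample


def write_airr(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-read records (sequence_id, v_call, j_call, locus, ...) as AIRR TSV."""
    missing = [c for c in AIRR_REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"cannot write AIRR TSV, missing columns {missing}")
    records.to_csv(path, sep="\t", index=False)


def filter_samples(
    samples: Sequence[RepertoireSample], min_reads: int = 2000
) -> list[RepertoireSample]:
    """Drop samples with fewer than ``min_reads`` total reads (both chains).

    The default mirrors the standard low-depth exclusion for bulk BCR
    repertoires; a subject with exactly ``min_reads`` reads is kept.
    """
    kept = [s for s in samples if s.total_reads() >= min_reads]
    dropped = len(samples) - len(kept)
    if dropped:
        logger.info("filter_samples: removed %d of %d samples below %d reads",
                    dropped, len(samples), min_reads)
    if not kept:
        raise ValueError(f"all {len(samples)} samples fall below {min_reads} reads")
    return kept


@dataclass
class UsageTable:
    """Per-subject usage fractions and their population median.

    ``per_subject`` is names x subjects (fractions of same-chain reads,
    zero-imputed for subject-absent names); ``median`` is the row-wise
    median.  Fractions are kept on the 0-1 scale internally.
    """

    level: str  # "allele" | "gene"
    segment: str  # "V" | "J"
    chain: str  # "heavy" | "light"
    per_subject: pd.DataFrame
    median: pd.Series

    def usage_of(self, name: AlleleName | str) -> float:
        """Median usage of one allele/gene; absent names have usage 0."""
        key = str(name)
        if key not in self.median.index:
            warnings.warn(f"{key} absent from {self.level} usage table; usage 0", stacklevel=2)
            return 0.0
        return float(self.median.loc[key])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.median.index,
                "chain": self.chain,
                "segment": self.segment,
                "level": self.level,
                "median_usage": self.median.values,
                "n_subjects": self.per_subject.shape[1],
            }
        )


def usage_table(
    samples: Sequence[RepertoireSample],
    level: str = "allele",
    segment: str = "V",
    chain: str = "heavy",
    reference: GermlineReference | None = None,
) -> UsageTable:
    """Usage fractions per subject and their median across subjects.

    The denominator is the subject's same-chain read count.  Names seen
    in no subject appear (with zero usage) only when a reference is
    supplied.
    """
    if not samples:
        raise ValueError("no samples")
    columns = {}
    for sample in samples:
        total = sample.total_reads(chain)
        counts = sample.counts(chain, segment, level)
        columns[sample.subject_id] = {
            str(name): n / total for name, n in counts.items()
        } if total else {}
    frame = pd.DataFrame(columns).fillna(0.0)
    if reference is not None:
        loci = ("IGH",) if chain == "heavy" else ("IGK", "IGL")
        names = {
            str(a.name.gene_name() if level == "gene" else a.name)
            for a in reference.alleles_for(loci, segment)
        }
        frame = frame.reindex(sorted(names | set(frame.index)), fill_value=0.0)
    frame = frame.sort_index()
    median = frame.median(axis=1)
    return UsageTable(level=level, segment=segment, chain=chain,
                      per_subject=frame, median=median)


def usage_for_segment(seg_assignment, table: UsageTable) -> float:
    """Usage score of one segment assignment: median usages summed over ties.

    At gene level, tied alleles of the same gene count that gene once.
    """
    if table.segment != seg_assignment.segment:
        raise ValueError(
            f"table is for segment {table.segment}, assignment for {seg_assignment.segment}"
        )
    if table.level == "gene":
        names = {a.gene_name() for a in seg_assignment.closest}
    else:
        names = set(seg_assignment.closest)
    return float(sum(table.usage_of(n) for n in sorted(names, key=str)))


def antibody_usage(assignment, heavy_table: UsageTable, light_table: UsageTable):
    """Per-chain V usage of one antibody and the heavy x light product.

    Ties are summed (each tied allele's median usage contributes), and
    the product of the heavy- and light-chain scores is the antibody's
    overall usage predictor.
    """
    if heavy_table.chain != "heavy" or light_table.chain != "light":
        raise ValueError("pass a heavy-chain table and a light-chain table, in that order")
    segment = heavy_table.segment
    heavy = usage_for_segment(assignment[("heavy", segment)], heavy_table)
    light = usage_for_segment(assignment[("light", segment)], light_table)
    return heavy, light, heavy * light


def cohort_usage_correlation(
    samples: Sequence[RepertoireSample],
    cohort_a: str,
    cohort_b: str,
    level: str = "allele",
    segment: str = "V",
    chain: str = "heavy",
) -> tuple[float, float]:
    """Spearman correlation of median usage between two cohorts.

    Returns (rho, p) over the union of names observed in either cohort
    (zero-filled where absent).
    """
    group_a = [s for s in samples if s.cohort == cohort_a]
    group_b = [s for s in samples if s.cohort == cohort_b]
    if not group_a or not group_b:
        raise ValueError(f"empty cohort: {cohort_a if not group_a else cohort_b}")
    table_a = usage_table(group_a, level, segment, chain).median
    table_b = usage_table(group_b, level, segment, chain).median
    names = sorted(set(table_a.index) | set(table_b.index))
    if len(names) < 3:
        raise ValueError(f"only {len(names)} shared names; need at least 3")
    a = table_a.reindex(names, fill_value=0.0).to_numpy()
    b = table_b.reindex(names, fill_value=0.0).to_numpy()
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
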