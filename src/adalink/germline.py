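"""Germline V/J allele reference handling.

Immunoglobulin germline segments follow IMGT nomenclature: a locus (IGH,
IGK, IGL), a segment letter (V or J), a gene label such as ``IGHV4-34``
and an allele number suffix such as ``*10``.  This module parses those
names, loads amino-acid germline references from FASTA (plain headers or
the IMGT ``|``-delimited dialect), and computes pairwise amino-acid
divergence between alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "AlleleName",
    "GermlineAllele",
    "GermlineReference",
    "AlleleNameError",
    "parse_allele_name",
    "load_germline_fasta",
    "pairwise_mismatch",
]

LOCI = ("IGH", "IGK", "IGL")
SEGMENTS = ("V", "J")

# 20 canonical amino acids plus X (unknown); gaps are stripped before validation
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP_CHARS = ".-"

_NAME_RE = re.compile(
    r"^(?P<locus>IGH|IGK|IGL)(?P<segment>[VJ])"
    r"(?P<rest>[0-9][0-9A-Za-z./()-]*)"
    r"(?:\*(?P<allele>[0-9]+))?$"
)


class AlleleNameError(ValueError):
    """Raised when an immunogenetics allele/gene name cannot be parsed."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Structured IMGT-style name for a germline gene or allele.

    ``allele_num is None`` denotes a gene-level reference (no ``*NN``
    suffix), e.g. ``IGHV2-70D``; such names are never matched against
    allele-level entries.
    """

    locus: str
    segment: str
    gene: str
    allele_num: int | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleNameError(f"unknown locus {self.locus!r}")
        if self.segment not in SEGMENTS:
            raise AlleleNameError(f"unknown segment {self.segment!r}")
        if not self.gene.startswith(self.locus + self.segment):
            raise AlleleNameError(
                f"gene {self.gene!r} does not start with {self.locus + self.segment!r}"
            )
        if self.allele_num is not None and self.allele_num <= 0:
            raise AlleleNameError(f"allele number must be positive, got {self.allele_num}")

    @property
    def is_gene_level(self) -> bool:
        return self.allele_num is None

    def gene_name(self) -> "AlleleName":
        """The gene-level name obtained by dropping the allele suffix."""
        return AlleleName(self.locus, self.segment, self.gene)

    def __str__(self) -> str:
        if self.allele_num is None:
            return self.gene
        return f"{self.gene}*{self.allele_num:02d}"


def parse_allele_name(raw: str) -> AlleleName:
    """Parse an IMGT-style allele or gene name.

    >>> parse_allele_name("IGHV4-34*10")
    AlleleName(locus='IGH', segment='V', gene='IGHV4-34', allele_num=10)

    A missing ``*NN`` suffix yields a gene-level name (``allele_num`` of
    ``None``), as for the duplicated-gene label ``IGHV2-70D``.
    """
    token = raw.strip()
    m = _NAME_RE.match(token)
    if m is None:
        raise AlleleNameError(f"cannot parse allele name {token!r}")
    locus = m.group("locus")
    segment = m.group("segment")
    gene = locus + segment + m.group("rest")
    allele = m.group("allele")
    return AlleleName(locus, segment, gene, int(allele) if allele is not None else None)


@dataclass(frozen=True)
class GermlineAllele:
    """One germline V or J allele as an ungapped amino-acid sequence."""

    name: AlleleName
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class GermlineReference:
    """Indexed collection of germline alleles.

    Indexes by full name, by gene, and by (locus, segment); duplicate
    full names are rejected.
    """

    def __init__(self, alleles: Iterable[GermlineAllele] = ()) -> None:
        self._by_name: dict[AlleleName, GermlineAllele] = {}
        self._by_gene: dict[AlleleName, list[GermlineAllele]] = {}
        self._by_locus_segment: dict[tuple[str, str], list[GermlineAllele]] = {}
        for allele in alleles:
            self.add(allele)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name.is_gene_level:
            raise ValueError(f"reference entries need an allele number: {allele.name}")
        if allele.name in self._by_name:
            raise ValueError(f"duplicate allele name {allele.name}")
        self._by_name[allele.name] = allele
        self._by_gene.setdefault(allele.name.gene_name(), []).append(allele)
        key = (allele.name.locus, allele.name.segment)
        self._by_locus_segment.setdefault(key, []).append(allele)

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self._by_name.values())

    def __contains__(self, name: AlleleName) -> bool:
        return name in self._by_name

    def get(self, name: AlleleName) -> GermlineAllele:
        return self._by_name[name]

    @property
    def genes(self) -> list[AlleleName]:
        return sorted(self._by_gene)

    def alleles_of_gene(self, gene: AlleleName | str) -> list[GermlineAllele]:
        if isinstance(gene, str):
            gene = parse_allele_name(gene)
        return list(self._by_gene[gene.gene_name()])

    def alleles_for(self, loci: Iterable[str], segment: str) -> list[GermlineAllele]:
        """All alleles of the given segment across one or more loci."""
        out: list[GermlineAllele] = []
        for locus in loci:
            out.extend(self._by_locus_segment.get((locus, segment), []))
        return out

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for allele in sorted(self, key=lambda a: str(a.name)):
                fh.write(f">{allele.name}\n{allele.sequence}\n")


def _name_from_header(header: str) -> AlleleName:
    # IMGT GENE-DB dialect: accession|allele|species|functionality|...
    if "|" in header:
        fields = header.split("|")
        if len(fields) < 2 or not fields[1].strip():
            raise AlleleNameError(f"IMGT-style header lacks an allele field: {header!r}")
        return parse_allele_name(fields[1])
    return parse_allele_name(header.split()[0])


def load_germline_fasta(path: str | Path) -> GermlineReference:
    """Load a germline amino-acid FASTA into an indexed reference.

    IMGT alignment gaps (``.`` and ``-``) are stripped; the header's
    second ``|``-field (IMGT dialect) or the whole first word is taken
    as the allele name.  Gene-level headers (no ``*NN``) are rejected:
    a reference must be allele-resolved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    reference = GermlineReference()
    for rec in records:
        name = _name_from_header(rec.description)
        seq = str(rec.seq).upper()
        for gap in GAP_CHARS:
            seq = seq.replace(gap, "")
        reference.add(GermlineAllele(name, seq))
    return reference


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_GLOBAL = _global_aligner()


def count_alignment_mismatches(alignment) -> tuple[int, int]:
    """(mismatch columns, total columns) of a pairwise alignment.

    A mismatch column is either a substitution or a gap in either
    sequence.
    """
    a_blocks, b_blocks = alignment.aligned
    seq_a, seq_b = alignment.target, alignment.query
    matches = 0
    subs = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if x == y:
                matches += 1
            else:
                subs += 1
    aligned_a = sum(a1 - a0 for a0, a1 in a_blocks)
    aligned_b = sum(b1 - b0 for b0, b1 in b_blocks)
    gap_cols = (len(seq_a) - aligned_a) + (len(seq_b) - aligned_b)
    return subs + gap_cols, matches + subs + gap_cols


def pairwise_mismatch(a: GermlineAllele | str, b: GermlineAllele | str) -> tuple[int, float]:
    """Amino-acid divergence between two germline alleles.

    Global alignment; mismatches = substituted columns + gap columns;
    the percent difference uses the alignment length (gap columns
    included) as denominator, returned as a fraction.
    """
    seq_a = a.sequence if isinstance(a, GermlineAllele) else a
    seq_b = b.sequence if isinstance(b, GermlineAllele) else b
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return 0, 0.0
    alignment = _GLOBAL.align(seq_a, seq_b)[0]
    mism, ncols = count_alignment_mismatches(alignment)
    return int(mism), float(mism / ncols)
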