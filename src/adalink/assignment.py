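"""Closest-germline V/J assignment for therapeutic-antibody chains.

Each antibody chain (amino-acid sequence of the variable domain,
optionally with trailing constant region) is scored against every
candidate germline allele with a semi-global alignment: the germline is
aligned end-to-end while chain overhangs on either side are free.  The
allele(s) with the fewest mismatches are the assignment; ties (which
may span genes and, for light chains, loci) are all kept, mirroring how
repertoire annotation tools report multi-allele calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from .germline import AlleleName, GermlineAllele, GermlineReference

__all__ = [
    "ChainRecord",
    "SegmentAssignment",
    "AntibodyAssignment",
    "align_germline_to_chain",
    "assign_segment",
    "assign_antibody",
    "assign_panel",
    "read_drug_panel",
    "assignments_to_frame",
]

MIN_CHAIN_LENGTH = 90

HEAVY_LOCI = ("IGH",)
LIGHT_LOCI = ("IGK", "IGL")


@dataclass(frozen=True)
class ChainRecord:
    """One antibody chain: drug identifier, heavy/light, AA sequence."""

    drug_id: str
    chain: str  # "heavy" | "light"
    sequence: str

    def __post_init__(self) -> None:
        if self.chain not in ("heavy", "light"):
            raise ValueError(f"chain must be 'heavy' or 'light', got {self.chain!r}")
        if not self.sequence:
            raise ValueError(f"{self.drug_id}/{self.chain}: empty sequence")
        if len(self.sequence) < MIN_CHAIN_LENGTH:
            warnings.warn(
                f"{self.drug_id}/{self.chain}: sequence shorter than "
                f"{MIN_CHAIN_LENGTH} residues; V assignment may be unreliable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SegmentAssignment:
    """Tied set of closest germline alleles for one segment of one chain."""

    segment: str  # "V" | "J"
    closest: frozenset[AlleleName]
    mismatches: int

    def __post_init__(self) -> None:
        if not self.closest:
            raise ValueError("assignment needs at least one allele")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")

    @property
    def sorted_alleles(self) -> list[AlleleName]:
        return sorted(self.closest, key=str)


@dataclass(frozen=True)
class AntibodyAssignment:
    """Per-drug V/J assignments for both chains plus total mismatch load."""

    drug_id: str
    segments: Mapping[tuple[str, str], SegmentAssignment]  # (chain, segment) -> assignment

    @property
    def total_mismatches(self) -> int:
        return sum(s.mismatches for s in self.segments.values())

    def __getitem__(self, key: tuple[str, str]) -> SegmentAssignment:
        return self.segments[key]


def _semiglobal_aligner() -> PairwiseAligner:
    # target = chain (free end gaps), query = germline (end-to-end; end
    # gaps cost like internal ones so overhangs register as mismatches)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_internal_deletion_score = -10.0
    aligner.extend_internal_deletion_score = -1.0
    aligner.open_internal_insertion_score = -10.0
    aligner.extend_internal_insertion_score = -1.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aligner.open_end_insertion_score = -10.0
    aligner.extend_end_insertion_score = -1.0
    return aligner


_SEMIGLOBAL = _semiglobal_aligner()


def align_germline_to_chain(
    germline: GermlineAllele | str, chain_seq: str, count_gaps: bool = True
) -> int:
    """Mismatches between a germline allele and its best placement in a chain.

    Semi-global alignment: the germline spans end-to-end, chain residues
    before/after the germline span are free.  Mismatches are substituted
    columns plus (if ``count_gaps``) gap columns internal to the germline
    span, including germline overhang beyond the chain ends.
    """
    gseq = germline.sequence if isinstance(germline, GermlineAllele) else germline
    if not gseq or not chain_seq:
        raise ValueError("sequences must be non-empty")
    alignment = _SEMIGLOBAL.align(chain_seq, gseq)[0]
    chain_blocks, germ_blocks = alignment.aligned
    subs = 0
    for (c0, c1), (g0, g1) in zip(chain_blocks, germ_blocks):
        for x, y in zip(chain_seq[c0:c1], gseq[g0:g1]):
            if x != y:
                subs += 1
    if not count_gaps:
        return subs
    aligned_germ = sum(g1 - g0 for g0, g1 in germ_blocks)
    germ_gap_cols = len(gseq) - aligned_germ  # germline residues opposite chain gaps
    # chain residues between aligned blocks are insertions internal to the
    # germline span; chain overhangs outside the span stay free
    chain_insertions = 0
    for i in range(len(chain_blocks) - 1):
        chain_insertions += chain_blocks[i + 1][0] - chain_blocks[i][1]
    return subs + germ_gap_cols + chain_insertions


def assign_segment(
    chain_seq: str,
    reference: GermlineReference,
    loci: Sequence[str],
    segment: str,
    count_gaps: bool = True,
) -> SegmentAssignment:
    """Closest germline allele(s) of one segment for a chain sequence.

    All alleles attaining the minimum mismatch count are returned as a
    tie set; ties may span genes and loci.
    """
    candidates = reference.alleles_for(loci, segment)
    if not candidates:
        raise ValueError(f"no {segment} alleles for loci {list(loci)} in reference")
    scores = {
        allele.name: align_germline_to_chain(allele, chain_seq, count_gaps=count_gaps)
        for allele in candidates
    }
    best = min(scores.values())
    tied = frozenset(name for name, s in scores.items() if s == best)
    return SegmentAssignment(segment=segment, closest=tied, mismatches=best)


def assign_antibody(
    heavy: ChainRecord,
    light: ChainRecord,
    reference: GermlineReference,
    count_gaps: bool = True,
) -> AntibodyAssignment:
    """Assign V and J germline alleles to both chains of one antibody.

    V and J are scored independently against the whole chain; the total
    mismatch load is the sum of the four per-segment minima.
    """
    if heavy.chain != "heavy":
        warnings.warn(
            f"{heavy.drug_id}: record labelled {heavy.chain!r} passed as heavy chain; "
            "assigning against IGH anyway",
            stacklevel=2,
        )
    if light.chain != "light":
        warnings.warn(
            f"{light.drug_id}: record labelled {light.chain!r} passed as light chain; "
            "assigning against IGK/IGL anyway",
            stacklevel=2,
        )
    segments: dict[tuple[str, str], SegmentAssignment] = {}
    for chain_name, record, loci in (
        ("heavy", heavy, HEAVY_LOCI),
        ("light", light, LIGHT_LOCI),
    ):
        for segment in ("V", "J"):
            segments[(chain_name, segment)] = assign_segment(
                record.sequence, reference, loci, segment, count_gaps=count_gaps
            )
    return AntibodyAssignment(drug_id=heavy.drug_id, segments=segments)


PANEL_COLUMNS = [
    "drug_id",
    "origin",
    "heavy_seq",
    "light_seq",
    "ada_rate",
    "target_class",
    "disease_category",
    "approval_year",
]


def read_drug_panel(path: str | Path) -> pd.DataFrame:
    """Read a drug panel CSV (one therapeutic antibody per row)."""
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"drug panel missing columns: {missing}")
    bad_origin = set(panel["origin"]) - {"human", "humanized"}
    if bad_origin:
        raise ValueError(f"origin must be 'human' or 'humanized', found {sorted(bad_origin)}")
    if ((panel["ada_rate"] < 0) | (panel["ada_rate"] > 100)).any():
        raise ValueError("ada_rate must lie in [0, 100] (percent scale)")
    return panel


def assign_panel(
    panel: pd.DataFrame, reference: GermlineReference, count_gaps: bool = True
) -> dict[str, AntibodyAssignment]:
    """Assign germline alleles to every antibody of a drug panel."""
    out: dict[str, AntibodyAssignment] = {}
    for row in panel.itertuples(index=False):
        heavy = ChainRecord(row.drug_id, "heavy", row.heavy_seq)
        light = ChainRecord(row.drug_id, "light", row.light_seq)
        out[row.drug_id] = assign_antibody(heavy, light, reference, count_gaps=count_gaps)
    return out


def assignments_to_frame(assignments: Iterable[AntibodyAssignment]) -> pd.DataFrame:
    """Long-format table: one row per drug x chain x segment, ties ';'-joined."""
    rows = []
    for asg in assignments:
        for (chain, segment), seg in sorted(asg.segments.items()):
            rows.append(
                {
                    "drug_id": asg.drug_id,
                    "chain": chain,
                    "segment": segment,
                    "closest_alleles": ";".join(str(n) for n in seg.sorted_alleles),
                    "mismatches": seg.mismatches,
                    "total_mismatches": asg.total_mismatches,
                }
            )
    return pd.DataFrame(rows)
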