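"""End-to-end orchestration: panel decoration and the association suite.

Glues the stages together: germline assignment of each drug, repertoire
usage tables, genotype inference, and the derived per-drug predictors
(mismatch load, heavy x light V usage products, population allele
frequency and gene non-deletion products), followed by the association
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .assignment import AntibodyAssignment, assign_panel
from .associations import (
    AssociationResult,
    OriginComparison,
    compare_origins,
    correlate,
    multivariable_regression,
)
from .genotype import (
    allele_population_frequency,
    antibody_genomic_scores,
    detect_deletions,
    genotype_population,
)
from .germline import GermlineReference
from .usage import RepertoireSample, antibody_usage, usage_table

__all__ = ["PipelineResult", "decorate_panel", "run_associations", "run_pipeline"]

PREDICTORS = [
    "total_mismatches",
    "usage_product",
    "gene_usage_product",
    "allele_freq_product",
    "gene_nondeletion_product",
]


@dataclass
class PipelineResult:
    records: pd.DataFrame
    assignments: dict[str, AntibodyAssignment]
    associations: list[AssociationResult]
    origin_comparison: OriginComparison | None
    regression: pd.DataFrame | None


def decorate_panel(
    panel: pd.DataFrame,
    reference: GermlineReference,
    samples: Sequence[RepertoireSample],
    candidate_threshold: float = 0.001,
    fdr_threshold: float = 0.01,
    abundance_threshold: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, AntibodyAssignment]]:
    """Attach every derived predictor to the drug panel.

    Adds: total mismatch load, heavy/light allele-level V usages and
    their product, and the three genomic decomposition products (allele
    frequency, gene non-deletion, gene usage).
    """
    assignments = assign_panel(panel, reference)
    tables = {
        (level, chain): usage_table(samples, level, "V", chain, reference)
        for level in ("allele", "gene")
        for chain in ("heavy", "light")
    }
    deletion_calls = detect_deletions(
        samples, candidate_threshold=candidate_threshold, fdr_threshold=fdr_threshold
    )
    genotype_calls = genotype_population(
        samples, deletion_calls, abundance_threshold=abundance_threshold
    )
    freqs = allele_population_frequency(genotype_calls)
    records = panel.copy()
    extra: dict[str, list[float]] = {
        "total_mismatches": [],
        "heavy_v_usage": [],
        "light_v_usage": [],
        "usage_product": [],
        "gene_usage_product": [],
        "allele_freq_product": [],
        "gene_nondeletion_product": [],
    }
    for drug_id in records["drug_id"]:
        asg = assignments[drug_id]
        heavy_u, light_u, product = antibody_usage(
            asg, tables[("allele", "heavy")], tables[("allele", "light")]
        )
        scores = antibody_genomic_scores(
            asg, freqs, tables[("gene", "heavy")], tables[("gene", "light")]
        )
        extra["total_mismatches"].append(asg.total_mismatches)
        extra["heavy_v_usage"].append(heavy_u)
        extra["light_v_usage"].append(light_u)
        extra["usage_product"].append(product)
        extra["gene_usage_product"].append(scores["gene_usage_product"])
        extra["allele_freq_product"].append(scores["allele_freq_product"])
        extra["gene_nondeletion_product"].append(scores["gene_nondeletion_product"])
    for col, values in extra.items():
        records[col] = values
    return records, assignments


def run_associations(records: pd.DataFrame) -> tuple[
    list[AssociationResult], OriginComparison | None, pd.DataFrame | None
]:
    """The full association battery over a decorated panel."""
    results: list[AssociationResult] = []
    for predictor in PREDICTORS:
        if predictor not in records.columns:
            continue
        for subset in ("all", "human", "humanized"):
            try:
                results.append(correlate(records, predictor, subset))
            except ValueError as exc:
                warnings.warn(f"{predictor}/{subset}: {exc}", stacklevel=2)
    try:
        origin = compare_origins(records)
    except ValueError as exc:
        warnings.warn(f"origin comparison skipped: {exc}", stacklevel=2)
        origin = None
    try:
        regression = multivariable_regression(records)
    except ValueError as exc:
        warnings.warn(f"regression skipped: {exc}", stacklevel=2)
        regression = None
    return results, origin, regression


def run_pipeline(
    panel: pd.DataFrame,
    reference: GermlineReference,
    samples: Sequence[RepertoireSample],
    **thresholds,
) -> PipelineResult:
    records, assignments = decorate_panel(panel, reference, samples, **thresholds)
    associations, origin, regression = run_associations(records)
    return PipelineResult(
        records=records,
        assignments=assignments,
        associations=associations,
        origin_comparison=origin,
        regression=regression,
    )
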