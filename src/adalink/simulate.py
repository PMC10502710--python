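"""Synthetic BCR-repertoire and drug-panel generator with known ground truth.

Generates every input of the pipeline so each stage can be validated
against generating parameters:

* a germline amino-acid reference (random V/J alleles, alleles of one
  gene separated by a configurable number of substitutions);
* a population of subject genotypes: per V gene, homozygous deletion
  with a gene-specific probability, otherwise two independent allele
  draws from the gene's allele-frequency simplex (Hardy-Weinberg-style);
* per-subject repertoires: reads distributed over genes according to
  per-subject propensities drawn around a shared, skewed (log-normal)
  base usage — so some genes dominate repertoires while others are
  rare, as in real bulk BCR data — with a configurable read-level
  within-gene allele misassignment rate emulating mutation-driven
  miscalls;
* a therapeutic-antibody panel: germline V + random junction + germline
  J chains with an origin-specific number of injected substitutions
  (human-origin antibodies carry few mutations, humanized ones many,
  giving the characteristic bimodal mismatch distribution), and
  clinical ADA rates generated for human-origin drugs as a noisy
  decreasing function of the log2 heavy x light V-usage product.

All randomness derives from one integer seed through independent
spawned streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .germline import AlleleName, GermlineAllele, GermlineReference, parse_allele_name
from .usage import RepertoireSample, UsageTable, usage_table, write_airr

__all__ = [
    "PanelConfig",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_reference",
    "simulate_population",
    "simulate_repertoire",
    "simulate_drug_panel",
    "simulate_study",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PanelConfig:
    """Therapeutic-antibody panel generator settings.

    Mutation-count ranges are inclusive uniform bounds per origin; the
    defaults separate the two origins cleanly, reproducing the bimodal
    total-mismatch pattern seen across real human/humanized panels.
    The ADA model applies to human-origin drugs: percent-scale rate =
    intercept + slope * log2(usage product + pseudocount) + noise,
    clamped to [0, 100].  Humanized drugs draw their ADA rate from an
    origin-level normal independent of usage.
    """

    n_human: int = 43
    n_humanized: int = 50
    human_mutations: tuple[int, int] = (0, 15)
    humanized_mutations: tuple[int, int] = (18, 35)
    ada_intercept: float = -5.0
    ada_slope: float = -1.5
    ada_noise_sd: float = 5.0
    ada_pseudocount: float = 1e-6
    humanized_ada_mean: float = 25.0
    humanized_ada_sd: float = 8.0
    junction_length: int = 10
    constant_stub_length: int = 20
    target_classes: tuple[str, ...] = ("cytokine", "receptor", "checkpoint", "other")
    disease_categories: tuple[str, ...] = ("oncology", "autoimmune", "infectious", "other")
    approval_years: tuple[int, int] = (1998, 2023)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings.

    Defaults emulate a bulk-repertoire cohort: 200 subjects at 5000
    reads each (heavy fraction ~0.37, matching the heavy/light balance
    of public bulk BCR collections), two alleles per gene three
    substitutions apart, 2% within-gene misassignment, and two
    heavy-chain genes with population deletion frequencies 0.57 and
    0.17 — the magnitudes reported for the most commonly deleted human
    IGHV genes — all others never deleted.
    """

    seed: int = 0
    n_subjects: int = 200
    reads_per_subject: int = 5000
    heavy_fraction: float = 0.37
    n_v_genes: Mapping[str, int] = field(
        default_factory=lambda: {"IGH": 20, "IGK": 12, "IGL": 8}
    )
    n_j_genes: Mapping[str, int] = field(
        default_factory=lambda: {"IGH": 4, "IGK": 3, "IGL": 3}
    )
    alleles_per_gene: int = 2
    allele_divergence: int = 3
    v_length: int = 98
    j_length: int = 15
    gene_usage_sigma: float = 1.0
    gene_usage_concentration: float = 500.0
    misassignment_rate: float = 0.02
    # gene name -> population deletion probability; unlisted genes: 0
    deletion_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"IGHV1-1": 0.57, "IGHV1-2": 0.17}
    )
    major_allele_range: tuple[float, float] = (0.55, 0.9)
    panel: PanelConfig = field(default_factory=PanelConfig)


@dataclass
class GroundTruth:
    """Generating parameters paired with the emitted data."""

    deletion_frequencies: dict[str, float]
    allele_frequencies: dict[str, dict[str, float]]  # gene -> allele -> freq
    genotypes: dict[str, dict[str, tuple[str, ...]]]  # subject -> gene -> alleles (() = deleted)
    panel: pd.DataFrame | None = None  # per-drug generating alleles / mutations / expected ADA

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deletion_frequencies": self.deletion_frequencies,
            "allele_frequencies": self.allele_frequencies,
            "genotypes": {
                s: {g: list(a) for g, a in genes.items()} for s, genes in self.genotypes.items()
            },
            "panel": None if self.panel is None else self.panel.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    reference: GermlineReference
    samples: list[RepertoireSample]
    panel: pd.DataFrame
    truth: GroundTruth


def _gene_names(locus: str, segment: str, n: int) -> list[str]:
    # family-style names, e.g. IGHV1-1 .. IGHV4-5 (5 genes per family)
    if segment == "J":
        return [f"{locus}J{i + 1}" for i in range(n)]
    return [f"{locus}V{i // 5 + 1}-{i % 5 + 1}" for i in range(n)]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _diverge(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Copy of ``seq`` with ``n_subs`` substitutions at distinct positions."""
    positions = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    out = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GermlineReference:
    """Random germline reference: per gene, allele *01 plus diverged copies."""
    if config.alleles_per_gene < 1:
        raise ValueError("alleles_per_gene must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    reference = GermlineReference()
    for segment, sizes, length in (
        ("V", config.n_v_genes, config.v_length),
        ("J", config.n_j_genes, config.j_length),
    ):
        for locus, n_genes in sizes.items():
            for gene in _gene_names(locus, segment, n_genes):
                base = _random_sequence(rng, length)
                for k in range(config.alleles_per_gene):
                    seq = base if k == 0 else _diverge(rng, base, config.allele_divergence)
                    name = parse_allele_name(f"{gene}*{k + 1:02d}")
                    reference.add(GermlineAllele(name, seq))
    return reference


def _allele_simplex(
    config: SimulationConfig, reference: GermlineReference, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Generating allele frequencies per gene (major allele dominant)."""
    freqs: dict[str, dict[str, float]] = {}
    for gene in reference.genes:
        alleles = sorted(str(a.name) for a in reference.alleles_of_gene(gene))
        if len(alleles) == 1:
            freqs[str(gene)] = {alleles[0]: 1.0}
            continue
        lo, hi = config.major_allele_range
        major = float(rng.uniform(lo, hi))
        rest = rng.dirichlet(np.ones(len(alleles) - 1)) * (1 - major)
        freqs[str(gene)] = {alleles[0]: major}
        freqs[str(gene)].update({a: float(f) for a, f in zip(alleles[1:], rest)})
    return freqs


def simulate_population(
    config: SimulationConfig,
    reference: GermlineReference,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw per-subject genotypes for every gene.

    V genes listed in ``deletion_frequencies`` are homozygously deleted
    with that probability; carried genes get two independent allele
    draws from the gene's frequency simplex (unordered pair).  J genes
    are never deleted.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    allele_freqs = _allele_simplex(config, reference, rng)
    genotypes: dict[str, dict[str, tuple[str, ...]]] = {}
    genes = [str(g) for g in reference.genes]
    for i in range(config.n_subjects):
        subject = f"S{i + 1:04d}"
        genotypes[subject] = {}
        for gene in genes:
            d = config.deletion_frequencies.get(gene, 0.0)
            if d and rng.random() < d:
                genotypes[subject][gene] = ()
                continue
            alleles = sorted(allele_freqs[gene])
            probs = np.array([allele_freqs[gene][a] for a in alleles])
            pair = rng.choice(len(alleles), size=2, p=probs)
            genotypes[subject][gene] = tuple(sorted({alleles[j] for j in pair}))
    truth = GroundTruth(
        deletion_frequencies={g: config.deletion_frequencies.get(g, 0.0) for g in genes},
        allele_frequencies=allele_freqs,
        genotypes=genotypes,
    )
    return truth


def _base_weights(
    names: Sequence[str], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(names))
    return w / w.sum()


def _allele_call_probs(
    carried: Sequence[str], all_alleles: Sequence[str], misassignment: float
) -> np.ndarray:
    """Read-level allele call distribution for one gene in one subject."""
    probs = np.zeros(len(all_alleles))
    carried_idx = [i for i, a in enumerate(all_alleles) if a in carried]
    non_carried = [i for i in range(len(all_alleles)) if i not in carried_idx]
    for i in carried_idx:
        probs[i] = 1.0 / len(carried_idx)
    if non_carried and misassignment > 0:
        probs *= 1.0 - misassignment
        for i in non_carried:
            probs[i] = misassignment / len(non_carried)
    return probs


def simulate_repertoire(
    config: SimulationConfig,
    reference: GermlineReference,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    outdir: str | Path | None = None,
) -> list[RepertoireSample]:
    """Per-subject repertoires as aggregated V/J call counts.

    Reads split heavy/light binomially, then over a chain's V genes by
    the subject's propensities (zero for deleted genes), then over
    alleles by genotype with within-gene misassignment noise; the J
    call is drawn from the same locus.  With ``outdir`` set, one AIRR
    Rearrangement TSV per subject is also written.
    """
    if config.reads_per_subject < 1:
        raise ValueError("reads_per_subject must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    v_genes = {
        locus: _gene_names(locus, "V", n) for locus, n in config.n_v_genes.items()
    }
    j_genes = {
        locus: _gene_names(locus, "J", n) for locus, n in config.n_j_genes.items()
    }
    alleles_of = {
        str(g): sorted(str(a.name) for a in reference.alleles_of_gene(g))
        for g in reference.genes
    }
    base = {
        locus: _base_weights(v_genes[locus], config.gene_usage_sigma, rng)
        for locus in v_genes
    }
    base_j = {
        locus: _base_weights(j_genes[locus], config.gene_usage_sigma / 2, rng)
        for locus in j_genes
    }
    light_loci = [l for l in v_genes if l != "IGH"]
    samples: list[RepertoireSample] = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for subject, genotype in truth.genotypes.items():
        sample = RepertoireSample(subject_id=subject)
        conc = config.gene_usage_concentration
        propensity = {
            locus: rng.dirichlet(conc * base[locus]) for locus in v_genes
        }
        j_propensity = {
            locus: rng.dirichlet(conc * base_j[locus]) for locus in j_genes
        }
        # deleted genes emit nothing; renormalize within chain
        for locus in propensity:
            mask = np.array([len(genotype[g]) > 0 for g in v_genes[locus]], dtype=float)
            weights = propensity[locus] * mask
            if weights.sum() == 0:
                raise ValueError(f"{subject}: all {locus} V genes deleted; degenerate config")
            propensity[locus] = weights / weights.sum()
        n_heavy = int(rng.binomial(config.reads_per_subject, config.heavy_fraction))
        n_light = config.reads_per_subject - n_heavy
        # light reads split between IGK/IGL by total propensity-weighted size
        light_weights = np.array(
            [len(v_genes[l]) for l in light_loci], dtype=float
        )
        light_weights /= light_weights.sum()
        light_counts = rng.multinomial(n_light, light_weights)
        rows: list[dict] = []
        for locus, n_reads in [("IGH", n_heavy)] + list(zip(light_loci, light_counts)):
            if n_reads == 0:
                continue
            chain = "heavy" if locus == "IGH" else "light"
            gene_counts = rng.multinomial(n_reads, propensity[locus])
            for gene, n_gene in zip(v_genes[locus], gene_counts):
                if n_gene == 0:
                    continue
                carried = genotype[gene]
                call_probs = _allele_call_probs(
                    carried, alleles_of[gene], config.misassignment_rate
                )
                v_counts = rng.multinomial(n_gene, call_probs)
                j_gene_counts = rng.multinomial(n_gene, j_propensity[locus])
                j_calls: list[str] = []
                for jg, n_jg in zip(j_genes[locus], j_gene_counts):
                    if n_jg == 0:
                        continue
                    j_carried = genotype[jg]
                    j_probs = _allele_call_probs(
                        j_carried, alleles_of[jg], config.misassignment_rate
                    )
                    j_allele_counts = rng.multinomial(n_jg, j_probs)
                    for ja, n_ja in zip(alleles_of[jg], j_allele_counts):
                        j_calls.extend([ja] * int(n_ja))
                # pair V and J calls positionally: only marginals matter downstream
                v_calls: list[str] = []
                for va, n_va in zip(alleles_of[gene], v_counts):
                    v_calls.extend([va] * int(n_va))
                pair_counts: dict[tuple[str, str], int] = {}
                for va, ja in zip(v_calls, j_calls):
                    pair_counts[(va, ja)] = pair_counts.get((va, ja), 0) + 1
                for (va, ja), n_pair in sorted(pair_counts.items()):
                    sample.add_reads(
                        chain,
                        (parse_allele_name(va),),
                        (parse_allele_name(ja),),
                        count=n_pair,
                    )
                    if outdir is not None:
                        rows.append(
                            {"v_call": va, "j_call": ja, "locus": locus, "count": n_pair}
                        )
        samples.append(sample)
        if outdir is not None:
            expanded = []
            seq_id = 0
            for row in rows:
                for _ in range(row["count"]):
                    seq_id += 1
                    expanded.append(
                        {
                            "sequence_id": f"{subject}_{seq_id}",
                            "v_call": row["v_call"],
                            "j_call": row["j_call"],
                            "locus": row["locus"],
                            "subject": subject,
                        }
                    )
            write_airr(pd.DataFrame(expanded), outdir / f"{subject}.tsv")
    return samples


def simulate_drug_panel(
    config: SimulationConfig,
    reference: GermlineReference,
    heavy_usage: UsageTable,
    light_usage: UsageTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic therapeutic-antibody panel with generating ground truth.

    Returns (panel, truth): the panel in the drug-panel CSV schema and
    a per-drug table of generating alleles, injected mutation counts
    and the pre-noise expected ADA rate.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    pc = config.panel
    heavy_v = sorted(
        str(a.name) for a in reference.alleles_for(("IGH",), "V")
    )
    heavy_j = sorted(str(a.name) for a in reference.alleles_for(("IGH",), "J"))
    light_v = sorted(
        str(a.name) for a in reference.alleles_for(("IGK", "IGL"), "V")
    )
    j_by_locus = {
        locus: sorted(str(a.name) for a in reference.alleles_for((locus,), "J"))
        for locus in ("IGK", "IGL")
    }
    origins = ["human"] * pc.n_human + ["humanized"] * pc.n_humanized
    panel_rows = []
    truth_rows = []
    for i, origin in enumerate(origins):
        drug = f"drug{i + 1:03d}"
        hv = str(rng.choice(heavy_v))
        hj = str(rng.choice(heavy_j))
        lv = str(rng.choice(light_v))
        lj = str(rng.choice(j_by_locus[parse_allele_name(lv).locus]))
        chains = {}
        spans = []  # (chain, start, end) of germline spans for mutation placement
        for chain, v_name, j_name in (("heavy", hv, hj), ("light", lv, lj)):
            v_seq = reference.get(parse_allele_name(v_name)).sequence
            j_seq = reference.get(parse_allele_name(j_name)).sequence
            junction = _random_sequence(rng, pc.junction_length)
            constant = _random_sequence(rng, pc.constant_stub_length)
            chains[chain] = v_seq + junction + j_seq + constant
            spans.append((chain, 0, len(v_seq)))
            j_start = len(v_seq) + len(junction)
            spans.append((chain, j_start, j_start + len(j_seq)))
        lo, hi = pc.human_mutations if origin == "human" else pc.humanized_mutations
        n_mut = int(rng.integers(lo, hi + 1))
        positions = [(c, p) for c, s, e in spans for p in range(s, e)]
        chosen = rng.choice(len(positions), size=n_mut, replace=False)
        mutable = {c: list(seq) for c, seq in chains.items()}
        for idx in chosen:
            c, p = positions[int(idx)]
            current = mutable[c][p]
            mutable[c][p] = str(rng.choice([a for a in AMINO_ACIDS if a != current]))
        chains = {c: "".join(s) for c, s in mutable.items()}
        usage_product = heavy_usage.usage_of(hv) * light_usage.usage_of(lv)
        if origin == "human":
            expected = pc.ada_intercept + pc.ada_slope * np.log2(
                usage_product + pc.ada_pseudocount
            )
            ada = expected + rng.normal(0.0, pc.ada_noise_sd)
        else:
            expected = pc.humanized_ada_mean
            ada = rng.normal(pc.humanized_ada_mean, pc.humanized_ada_sd)
        ada = float(np.clip(ada, 0.0, 100.0))
        panel_rows.append(
            {
                "drug_id": drug,
                "origin": origin,
                "heavy_seq": chains["heavy"],
                "light_seq": chains["light"],
                "ada_rate": round(ada, 3),
                "target_class": str(rng.choice(pc.target_classes)),
                "disease_category": str(rng.choice(pc.disease_categories)),
                "approval_year": int(rng.integers(*pc.approval_years)),
            }
        )
        truth_rows.append(
            {
                "drug_id": drug,
                "origin": origin,
                "heavy_v": hv,
                "heavy_j": hj,
                "light_v": lv,
                "light_j": lj,
                "n_mutations": n_mut,
                "usage_product": usage_product,
                "expected_ada": float(expected),
            }
        )
    return pd.DataFrame(panel_rows), pd.DataFrame(truth_rows)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the whole generator: reference, genotypes, repertoires, panel."""
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]
    reference = simulate_reference(config, rngs[0])
    truth = simulate_population(config, reference, rngs[1])
    samples = simulate_repertoire(config, reference, truth, rngs[2])
    heavy_usage = usage_table(samples, "allele", "V", "heavy", reference)
    light_usage = usage_table(samples, "allele", "V", "light", reference)
    panel, panel_truth = simulate_drug_panel(
        config, reference, heavy_usage, light_usage, rngs[3]
    )
    truth.panel = panel_truth
    return SimulatedStudy(
        config=config, reference=reference, samples=samples, panel=panel, truth=truth
    )
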