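# adalink

Sequence-level immunogenicity analysis for therapeutic antibodies:
linking clinical anti-drug-antibody (ADA) rates to germline V/J allele
choice, population immunoglobulin genotype, and mutation load.

## The problem

A patient can mount an immune response against a therapeutic antibody
(ADA), degrading its pharmacokinetics, efficacy and safety. Two
sequence-level properties of the drug predict this risk:

* **mutation load** — the number of amino-acid mismatches between the
  drug's heavy/light chains and their closest germline V and J alleles
  (engineered and somatic mutations create non-self epitopes);
* **germline rarity** — how rare the drug's V alleles are in the
  treated population. An antibody built on a rare allele looks foreign
  to the many patients who do not carry it. Rarity decomposes into
  repertoire **gene usage**, population **allele frequency**, and
  **gene deletion** (some V genes are absent from many genomes).

`adalink` computes all of these from standard inputs — a germline
amino-acid FASTA (IMGT-style headers supported), BCR repertoires as
AIRR Rearrangement TSVs of per-read V/J calls, and a drug panel CSV —
and runs the association statistics:

* closest-germline assignment per chain and segment (semi-global
  alignment, germline end-to-end, ties kept and summed downstream);
* per-subject and population-median allele/gene usage
  (`usage = median_subjects(reads with allele / same-chain reads)`);
* per-subject genotype inference: gene deletions (usage < 0.1% →
  binomial test against the pooled carrier null, BH-corrected per gene,
  FDR < 0.01) and zygosity (allele abundance > 20% within the gene;
  one candidate → homozygous, two+ → heterozygous of the top two);
* Spearman correlations of ADA rate vs every predictor (overall and by
  origin), a Welch t-test of mismatch load between human-origin and
  humanized drugs, and a multivariable OLS of ADA rate on
  `log2(heavy V usage x light V usage)` controlling for target class,
  disease category and approval year.

A fully seeded synthetic-data generator produces germline references,
population genotypes, repertoires and drug panels with known ground
truth, so every stage is testable end-to-end without any downloads.

## Worked example

```python
import warnings
import adalink as A

config = A.SimulationConfig(seed=1, n_subjects=50, reads_per_subject=3000)
study = A.simulate_study(config)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    samples = A.filter_samples(study.samples, min_reads=2000)
    result = A.run_pipeline(study.panel, study.reference, samples)

usage = next(r for r in result.associations
             if r.predictor == "usage_product" and r.subset == "human")
print(f"human-origin drugs: n={usage.n}, "
      f"Spearman rho={usage.spearman_rho:.3f}, p={usage.p_value:.2g}")
origin = result.origin_comparison
print(f"mismatch load: human {origin.mean_human:.1f} vs "
      f"humanized {origin.mean_humanized:.1f} (Welch p={origin.p_value:.2g})")
slope = result.regression.set_index("term").loc["log2_usage_product"]
print(f"regression: log2 usage product slope {slope['estimate']:.2f} "
      f"(se {slope['se']:.2f}, p={slope['p']:.2g})")
```

prints

```
human-origin drugs: n=43, Spearman rho=-0.471, p=0.0014
mismatch load: human 6.2 vs humanized 27.6 (Welch p=8.3e-38)
regression: log2 usage product slope -0.79 (se 0.22, p=0.0011)
```

Read: among the 43 human-origin drugs of the simulated panel, drugs
using rarer V alleles (smaller heavy x light usage product) have higher
ADA rates (negative rank correlation, significant after covariate
control), and humanized drugs carry ~4x the germline mismatch load of
human-origin drugs — the generator's planted structure, recovered by
the pipeline from raw reads and sequences.

The same pipeline is available from the shell:

```bash
adalink all --seed 7 --outdir out/          # simulate + assign + usage +
                                            # genotype + associate + report
adalink simulate --seed 7 --outdir sim/     # write FASTA / AIRR TSVs / panel
adalink usage --airr-dir sim/airr --out usage.csv --min-reads 2000
adalink genotype --airr-dir sim/airr --outdir geno/
```

Each run writes a `run_manifest.json` with the config snapshot, output
checksums and collected warnings; outputs are byte-identical for a
given seed.

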