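# Methods

## Problem and model

Therapeutic antibodies can provoke anti-drug antibodies (ADA) in
patients. Two sequence-level risk factors are quantified here:

1. **Mutation load** — the number of amino-acid mismatches between an
   antibody's chains and their closest germline V and J alleles.
2. **Germline rarity** — how rare the antibody's V alleles are in the
   treated population, both in repertoire usage (fraction of BCR reads
   carrying the allele) and genomically (population allele frequency and
   gene-deletion frequency).

The pipeline takes (a) a germline V/J amino-acid reference, (b) a cohort
of BCR repertoires as per-read V/J allele calls (AIRR Rearrangement
TSV), and (c) a drug panel (sequences, origin, clinical ADA rate,
covariates), and produces per-drug predictors plus the association
statistics linking them to ADA rate.

## Germline assignment

Each chain is scored against every candidate allele (heavy: IGH; light:
IGK ∪ IGL) with a semi-global alignment: the germline must span
end-to-end, chain residues outside the germline span are free. Scoring
is match +1 / mismatch 0 with gap open −10 / extend −1; mismatches are
then recounted on the traceback as substituted columns plus gap columns
internal to the germline span (germline overhang beyond a short chain
also counts; counting gap columns at all is switchable via
`count_gaps`, default on). All alleles attaining the minimal mismatch
count form the assignment — ties may span genes and, for light chains,
loci — and downstream usage scores sum over the tie set. The steep gap
penalty makes the result equal to exhaustive ungapped placement
minimization in the no-indel regime, which the test suite verifies
against an independent sliding-window oracle.

The percent difference between two germline alleles uses a global
alignment with the alignment length (gap columns included) as
denominator. For a 97-residue V pair differing at 14 positions this
yields 14/97 = 14.4%, the divergence scale of the most distinct human
IGHV4-34 alleles; that pair is a regression test for the denominator
choice.

## Usage quantification

Usage of an allele is the fraction of a subject's *same-chain* reads
whose call includes the allele; the population statistic is the median
over subjects, with subjects lacking the allele contributing zero
(omitting them would bias rare-allele medians upward). Multi-allele
read calls credit every listed allele (so allele-level fractions can sum
above 1); gene-level usage credits a read to a gene once. Samples with
fewer than 2000 total reads are excluded by default. Fractions are kept
on the 0–1 scale internally and rendered ×100 only at I/O. A drug's
usage predictor is the product of its heavy- and light-chain V scores.

## Genotype inference

**Deletion.** Per gene, subjects with usage below 0.1% of same-chain
reads are deletion candidates. The null usage is the *pooled* fraction
over non-candidate subjects (total gene reads / total chain reads —
pooling is more stable than averaging per-subject percents at small
cohort sizes). Each candidate gets a one-sided lower-tail binomial test;
Benjamini–Hochberg is applied within each gene's candidate set and
deletion is declared at FDR < 0.01. A gene whose every subject is a
candidate has no null and its candidates stay untested (not deleted),
with a warning.

**Zygosity.** Within a carried gene, allele abundances are fractions of
the gene's reads. Alleles strictly above 20% abundance are genotype
candidates: one → homozygous; two or more → heterozygous for the top
two (ties broken by abundance descending, then allele name — full
determinism). A subject with no allele above 20% is *unresolved* and is
excluded from both numerator and denominator of population allele
frequencies. Deleted subjects are likewise excluded ("individuals who
carry the gene").

**Population summaries.** Deletion frequency = deleted subjects / all
subjects. Allele carrier frequency = carriers of the allele / resolved
carriers of its gene; heterozygotes count for both alleles, so a gene's
carrier frequencies may sum above 1.

## Association statistics

Spearman correlations (ADA rate vs each predictor, overall and within
origin strata) are computed on untransformed values; rank statistics are
invariant to the monotone log transforms used for display. P-values use
the t-approximation, except at n ≤ 8 where the permutation distribution
is enumerated exactly (8! = 40 320 is instant; the t-approximation is
already adequate well before n = 10). The origin comparison of mismatch
loads is a Welch (unequal-variance) two-sample t-test.

The multivariable model is OLS of ADA rate (percent scale) on
log2(usage product + pseudocount) plus dummy-coded target class and
disease category (reference = most frequent level, for run-to-run
determinism) and approval year, restricted to human-origin antibodies.
The automatic pseudocount is half the smallest positive value and 0 when
no zeros are present. Rows without an approval year are dropped with a
warning; a rank-deficient design raises an error naming the aliased
terms.

## Synthetic-data generator

The generator emulates the statistical structure of a bulk-repertoire
cohort plus a therapeutic panel, with full ground truth:

* **Reference** — per gene, allele \*01 is a random sequence (V: 98
  residues, J: 15); further alleles differ by 3 substitutions (the
  typical within-gene allele divergence; configurable).
* **Genotypes** — per V gene, homozygous deletion with a gene-specific
  probability (defaults: one gene at 0.57 and one at 0.17, the
  magnitudes reported for the most commonly deleted human IGHV genes;
  all others 0), otherwise two independent draws from the gene's
  allele-frequency simplex (major allele 0.55–0.9).
* **Repertoires** — 200 subjects × 5000 reads (heavy fraction 0.37,
  matching the heavy/light balance of public bulk BCR collections).
  Gene propensities per subject are Dirichlet draws around shared
  log-normal base weights (σ = 1), giving the skewed usage pattern of
  real repertoires (some genes >10% of reads, others rare). The
  Dirichlet concentration is 500, i.e. ≈30% between-subject coefficient
  of variation for a mid-usage gene — tight enough that carriers of a
  gene essentially never drop to deletion-candidate usage by propensity
  alone, which matches observed repertoire variability. Read-level
  allele misassignment (2%) swaps a read's call to a non-carried allele
  of the same gene, emulating mutation-driven miscalls; cross-gene
  miscalls are not modeled.
* **Drug panel** — 43 human-origin + 50 humanized drugs; chains are
  germline V + 10-residue random junction + germline J + constant-region
  stub, with an origin-specific number of injected substitutions inside
  the germline spans (human U{0..15}, humanized U{18..35} — cleanly
  bimodal). Human-origin ADA rate = −5 − 1.5·log2(usage product + 1e−6)
  + N(0, 5), clamped to [0, 100] — a noisy decreasing function of usage,
  putting common-allele drugs near 5–10% ADA and rare-allele drugs near
  25%. Humanized ADA ~ N(25, 8) independent of usage: their heavy
  mutation load both dominates their immunogenicity and obscures the
  originating allele, so no usage association is expected or generated;
  their higher mean also reproduces the positive panel-wide
  mismatch–ADA relation.

What the generator does *not* model: somatic hypermutation hotspots,
clonal structure, isotypes, realistic CDR3 length/composition, and
cross-gene call noise. Passing tests therefore demonstrate correctness
of the inference machinery under the stated statistical model, not
robustness to every artifact of real repertoire data.

All randomness flows from one integer seed through four spawned
streams (reference / population / repertoire / panel), so every output
is bit-reproducible.

## Numerical and degenerate-input choices

* Zygosity candidate rule is *strictly* above threshold; exact-20%
  abundances are not candidates.
* A subject with exactly the minimum read count passes the depth filter
  ("fewer than" excludes).
* Deletion p-values for non-candidates are NaN by construction; BH is
  computed only over a gene's candidates.
* Usage of a name absent from a table is 0 with a warning, never an
  error, so panel scoring is total.
* The read-depth filter, candidate threshold (0.1%), FDR (0.01),
  abundance threshold (20%) and pseudocount are all config keys
  defaulting to the standard values above.

## Problem sizes used in validation

The validation suite runs the cohort at its default scale (200 subjects
× 5000 reads) for genotype recovery, 1000 replicates for zygosity
calibration, 100 replicates (n = 43) for correlation power and 200 for
regression recovery, and a reduced cohort (20–30 subjects) where only
plumbing, not statistical power, is under test.

## Known limitations

* Allele misassignment is within-gene only; heavily mutated chains in
  real data can cross gene boundaries at the calling stage.
* The deletion test inherits the standard assumption that carriers'
  usage is exchangeable around the pooled null; strong per-subject
  usage heterogeneity would inflate false positives.
* Measured usage products for mutated drugs suffer errors-in-variables
  attenuation: the regression slope on measured predictors is biased
  toward zero relative to the generating slope (visible in the
  end-to-end run; the recovery tests use the generating predictor).
* J-segment assignment scores the whole chain; no junction-proximal
  trimming is attempted.
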