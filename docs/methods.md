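# Methods

This note documents the models, rules and numerical choices behind
`twohitscan`, and what the synthetic cohorts do and do not establish.

## Germline triage

A variant survives triage when it passes the quality, rarity and
deleteriousness predicates *and* lies in the configured gene panel.

* **Quality.** The filter string mixes two callers' vocabularies (GATK
  emits FS/MQ/DP; Mutect2 adds TLOD/SEQQ/STRANDQ). One threshold set is
  applied to both call types, so the conjunction runs over the metrics
  *present* on a record and absent metrics never fail it. Comparison
  directions are exactly TLOD > 12, FS < 10, SEQQ > 60, MQ ≥ 60,
  STRANDQ > 40, DP > 10 — MQ is deliberately the only non-strict bound.
* **Rarity.** East-Asian reference allele fraction strictly below 0.01; a
  variant absent from the reference panel counts as frequency zero.
* **Deleteriousness.** Non-synonymous exonic/splicing consequence with
  CADD strictly above 20. `splice_region` counts as splicing here but is
  never LoF-type. Unscored variants are not called damaging.
* **LoF confidence.** Full LOFTEE logic (ancestral alleles, NAGNAG sites,
  …) is out of scope; the two dominant demotion flags are implemented with
  testable semantics: a truncation in the terminal 5% of the coding
  sequence, or a splice variant not at a canonical dinucleotide, is
  low-confidence; other truncations are high-confidence. Both thresholds
  are configurable.

Note the term "candidate LoF variant" covers every triage survivor — a
rare damaging missense stays a candidate (category `not_lof`); only the
truncating classes receive an LoF confidence grade.

## ACMG combination

The engine implements the standard ACMG/AMP combining rules over the 28
unmodified codes (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7). Strength
modifiers are not supported because the clinical reports the fixture
encodes use only default strengths. PP5/BP6 are accepted despite their
later deprecation, again for fixture fidelity. Conflicting evidence
(pathogenic-side and benign-side rules both firing) and the empty rule set
both yield VUS; the function is total over arbitrary code subsets and is
monotone under addition of pathogenic-side evidence (property-tested).
A structural variant (multi-exon deletion) enters as an `exon_loss`
consequence with its assigned criteria — the engine consumes criteria
codes, not molecules.

## Phenotype rules

* MSI integration is a logical OR over assays: ≥2 of the 5 Bethesda
  markers unstable (the consensus cutoff; configurable), any MMR-protein
  loss by IHC, or MSIsensor score strictly above 3.5. All assays absent ⇒
  unknown; assays present but all negative ⇒ MSS. The OR makes the status
  monotone: adding a positive assay can only move MSS → MSI-H.
* Early onset: age at the chronologically second diagnosis ≤ 55
  (non-strict, "55 or younger").
* Synchronous: interval between first and second diagnoses < 365 days
  (strict). Diagnosis dates, not treatment dates, define the interval;
  synthetic dates are day offsets so the boundary is exact.
* Strong family history: ≥2 first-degree relatives with cancer; unknown
  history propagates as unknown and is excluded from downstream
  contingency denominators (56 of 71 on the fixture margins).

## Allelic-imbalance HMM

Two states over phased heterozygous sites: balanced emits
Binomial(depth, ½) on the haplotype-A count; imbalanced emits the mixture
(1−ε)·Binomial(depth, ½+δ) + ε·Binomial(depth, ½−δ), where ε absorbs
phase-switch errors. The imbalanced self-transition is 1 − 1/L with L the
expected event length in sites; the balanced self-transition is chosen so
the stationary distribution equals (1−π, π), and the chain is initialized
at stationarity. Defaults: π = 0.1 and posterior cutoff 0.9 (the fixed
study parameters); δ = 0.10, ε = 0.02, L = 100 sites are not fixed by the
study and are exposed as configuration. Posteriors come from a scaled
forward–backward pass (log-shifted emissions), verified against exhaustive
path enumeration on ≤12 sites to 1e-8 and against the forward/backward
likelihood identity to 1e-9 relative. Events are maximal runs of sites
with posterior strictly above the cutoff; the chain runs independently per
(chromosome, phase block) because phase is not comparable across blocks,
so events never span blocks. Detection is deliberately tolerant of model
mismatch: tracks simulated at δ = 0.15 are recovered by the δ = 0.10
default configuration.

## Gene-level copy number

The gene ratio is the bin-length-weighted mean of *all* bins belonging to
any segment overlapping the gene span — the whole segment contributes, not
only its in-gene portion. Deletion requires the mean strictly below −0.3.
The "≥3 segments of copy-number change" requirement is read as a
sample-level QC (≥3 segments with |log₂| ≥ 0.3 anywhere in the genome)
rather than a per-gene requirement, which would exclude nearly every gene;
the sample-level reading matches a noise-screening intent. A gene
overlapping no segment yields an absent mean and a failed QC. Intervals
are 1-based inclusive externally with half-open arithmetic internally;
strand is ignored throughout.

## Bi-allelic integration

For each (patient, tumor, candidate gene): somatic damaging mutation in
the gene ⇒ `somatic_lof_mutation`; AI event overlapping the gene body
(exact gene-body overlap, no flanking window) ⇒ `allelic_imbalance`;
gene-level deletion ⇒ `deletion`. All applicable mechanisms are reported —
AI and deletion are computed independently, so copy-neutral LOH surfaces
as AI without deletion. The somatic rarity filter is not applied (a
somatic event's population frequency is meaningless). Two or more somatic
damaging MMR-gene mutations in one tumor raise a separate double-somatic
flag, a known mismatch-repair phenocopy.

## Exact 2×2 inference

Two-sided Fisher p sums central hypergeometric point probabilities not
exceeding the observed one, with a 1e-7 relative tolerance absorbing
floating-point ties (integer-exact enumeration confirms agreement to
1e-10 over every margin with N ≤ 60). The odds-ratio estimate is the
conditional MLE: the ψ solving E_ψ[a] = a_obs under Fisher's noncentral
hypergeometric distribution, found by Brent root-finding on log ψ with an
expanding bracket; observed cells at the boundary of their attainable
range map to 0 / +∞. Confidence bounds invert the one-sided exact tails at
α/2. These are the `fisher.test` conventions — the printed estimate 31.66
differs from the cross-product ratio 34.5 precisely because it is the
conditional MLE. One caveat: `fisher.test` computes its CI bounds by
root-finding on the reciprocal-ψ scale at a loose default tolerance, which
misplaces very large bounds (e.g. 1700.6 where the exact bound is 1721.5);
this package inverts the tails to 1e-12, so extreme CI bounds can differ
from legacy reports in that direction while p-values and estimates agree.

The burden scan reports genes with ≥2 total case carriers, ordered by the
non-LS p-value, flags p < 0.01 (the report convention), and offers
optional Benjamini–Hochberg columns (off by default, for fidelity to the
unadjusted-report convention). Rank-sum comparisons use exact enumeration
for tie-free samples of ≤20 and the tie-corrected normal approximation
otherwise.

## Synthetic cohorts

The generator's defaults are the study conditions: 71 MPC patients, 15 LS
carriers (gene pattern MLH1×10, MSH6×2, PMS2×2, MSH2×1; criteria patterns
drawn from the printed classifications), 42% early-onset overall with
13/15 among carriers, family history known for 56/71, a 70-patient
reference cohort, and planted candidate-gene carrier rates emulating the
printed burden table (RECQL5 4/12 vs 1/70, etc.). Each carrier's second
hit is planted in one MSI-H tumor with mechanism probabilities 0.6 AI /
0.2 deletion / 0.2 somatic mutation — not study-fixed; chosen to match the
printed predominance of LOH mechanisms. Per-tumor phased-BAF tracks place
240 evenly spaced het sites in a ±0.7 Mb window around each candidate
gene (≈100 in-gene sites at the synthetic 1 Mb gene size, matching the
HMM's expected event length) with Poisson(60) depths and AI shift
δ = 0.2. Genes live on a synthetic deterministic gene model (1 Mb spans
laid out across 22 autosomes), so coordinates are self-consistent but not
genomic.

One global seed keys independent per-patient substreams
(`default_rng([seed, patient_index])`), so adding a patient never perturbs
the others and identical seeds give bit-identical cohorts.

What the generator does **not** emulate: read-level error profiles,
mapping artifacts, FFPE damage, tumor purity/subclonality, LD structure,
segmentation noise beyond Gaussian bin jitter, and real gene sizes or
positions. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated generative model, not calibrated
performance on real sequencing data. Cohort-scale raw-variant tallies from
the original whole-exome analysis are similarly not reproducible from
printed material and are covered by these synthetic recovery suites
instead.

## Fixtures

The printed summary tables ship as commented TSVs inside the package: the
16 germline P/LP variants with criteria codes, the per-gene carrier
counts, the per-patient candidate-gene lists with high-confidence flags
and bi-allelic outcomes, and the cohort margins. Ages appear only as range
labels ("<55"/">55"), as printed. High-confidence flags garbled by the
source's formatting were resolved from the running text (five of the seven
LS MLH1 variants; BRCA1; FANCG and CASP8 among non-LS candidates); MSI
labels for patients outside the printed tables are synthetic and marked as
such. Per-tumor bi-allelic multiplicities are not carried.

## Problem sizes and determinism

The test suite runs the exhaustive Fisher oracle over all canonical
margins with N ≤ 60 (the rest follow from tested symmetries), 500
simulated tables for CI coverage, 50 seeded AI tracks of 500 sites for
event recovery, and one full-size (71 + 70) synthetic cohort for
end-to-end parameter recovery; everything is seeded or derandomized, and
the whole suite completes in about a minute on one CPU.
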