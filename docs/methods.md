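# Methods

This note records what `castriage` computes, the assumptions behind it,
the defaults and why they were chosen, and what the synthetic-data
generators do and do not establish about real data.

## Variant triage

The triage model treats candidate discovery in trio genome data as a
sequence of hard filters followed by rule classifiers. Filters are applied
in a fixed order — site QC, genotype QC, population rarity, cohort
recurrence, inheritance — and the attrition log records the *first* stage
each variant fails, so input count always equals survivors plus per-stage
drops.

Thresholds (all configurable through `FilterConfig`, all strict
inequalities exactly as written):

| filter | SNV | indel |
| --- | --- | --- |
| quality by depth (QD), min | 2 | 2 |
| Fisher strand (FS), max | 60 | 200 |
| strand odds ratio (SOR), max | 3 | 10 |
| MQ rank sum, min | −12.6 | not applied |
| read position rank sum, min | −8 | −20 |
| excess heterozygosity Z, max | 4.5 | 4.5 |
| per-sample depth / genotype quality | DP > 10, GQ > 20 | same |
| gnomAD allele count (dominant/de novo), max | 2 | 2 |
| gnomAD allele frequency (compound het), max | < 0.05% | same |
| SV: cohort families with an overlapping call, max | 2 | — |
| SV: population frequency | kept unless > 0.05% | — |

Design choices where the rules leave room:

* **Missing site metrics never drop a variant.** Only explicit threshold
  violations and explicit recalibration-failure flags do. Penalizing
  missingness would silently discard records whose annotations were simply
  not computed.
* **The MQ rank-sum cutoff applies to SNVs only**; the indel filter set
  replaces the strand and position cutoffs and does not include it.
* **Cohort recurrence is cross-family.** The identical allele
  (chromosome, position, ref, alt — no fuzzy indel matching) carried by an
  unaffected member of *another* family removes a variant. Carriage within
  the proband's own family is the business of the inheritance model, which
  must be able to see variants transmitted by an unaffected parent in
  order to report them (e.g. as uncertain findings) or pair them as
  compound heterozygotes.
* **Inheritance eligibility.** De novo (both sequenced parents homozygous
  reference), homozygous recessive, and compound heterozygous calls are
  always candidate-eligible. Inherited dominant calls are eligible only
  when the transmitting parent is affected, with one exemption: maternal
  transmission on X to a male proband, where unaffected carrier females
  are expected. Duos and singletons where transmission cannot be resolved
  are `unknown` and stay in the pool.
* **Compound heterozygotes** require one maternally and one paternally
  transmitted heterozygote in the same gene; phase is inferred from
  parental genotypes only. A variant too common for the dominant
  allele-count rule survives only if its frequency admits the
  compound-het rule *and* it actually pairs.
* **Monozygotic twins** are collapsed to a single analysis proband via a
  PED twin annotation column.

## Deleteriousness classification

Predicted LoF: LoF consequence ∧ (pLI ≥ 0.9 ∨ LoFtool < 0.1) ∧
(frameshift ∨ CADD ≥ 20 ∨ splice AdaBoost ≥ 0.6 ∨ splice random forest
≥ 0.6). Predicted damaging missense: at least 3 of {PolyPhen-2
probably/possibly damaging, SIFT deleterious (incl. low confidence), CADD
≥ 20, MTR FDR < 0.05}. A missing annotation never counts toward a
criterion (classification fails closed). The "at least three" rule is a
counting rule over the four criteria; the implementation and its tests
enumerate all 16 subsets to pin the boundary at three.

Transcript handling follows a most-severe-transcript rule: an allele
qualifies if any transcript's annotation qualifies, and the qualifying
transcript is the one reported.

Shortlisting is two-stage per family: candidates in the collated
genes-of-interest union first; the genome-wide, gene-agnostic pass runs
only when the panel stage yields no reviewable candidate, with identical
classifier rules in both stages. ACMG classes and phenotype-consistency
are operator-supplied review inputs; candidates without a review row
default to class 3 (uncertain), so an unreviewed variant can never become
a high-confidence finding. Class 4/5 with phenotype fit is high
confidence; class 3, or class 4 without fit, is low confidence; everything
else (including class 5 without phenotype fit) is excluded from reporting
tiers.

## Co-expression model

All correlation is Spearman's ρ with average-rank ties, computed on a
genes × samples expression matrix; every downstream statistic is therefore
invariant under strictly monotone transforms of the expression values
(this is asserted bit-for-bit in the tests). Pairs involving a constant
expression vector have undefined ρ; they are excluded from medians and
thresholds and counted in the outputs.

* **Set statistic:** median |ρ| over the set's unordered pairs.
* **Genome-wide threshold:** the top-5% cutoff (quantile 0.95,
  configurable) on |ρ| over gene pairs. Exact (sorted-value lookup) when
  the pair count is at most `max_pairs` (default 2 × 10⁶); otherwise
  estimated over `max_pairs` pairs sampled uniformly without replacement,
  with the method recorded. The threshold is always computed from the
  data, never hard-coded.
* **Monte-Carlo test:** `n_iter` (default 5000) same-size sets drawn
  uniformly without replacement within a draw from the eligible universe.
  The observed genes remain drawable (overlapping draws are legitimate
  null samples); only a draw identical to the whole observed set is
  rejected. The add-one estimator (1 + r)/(n_iter + 1) keeps p strictly
  positive with resolution floor 1/(n_iter + 1) — 2 × 10⁻⁴ at 4999 draws.
* **Eligible universe:** genes detected (expression above a configurable
  floor, default 0) in at least half the samples. Real atlas preprocessing
  (normalization, sample selection) is upstream of this package; the
  eligibility rule is deliberately exposed as configuration.
* **Network:** an edge wherever |ρ| reaches the threshold, with the
  correlation sign as an attribute and gene-set provenance labels on
  nodes.
* **Display order:** agglomerative clustering with median linkage on the
  distance 1 − ρ, via scipy's linkage; undefined correlations are treated
  as distance 1.

## Connectivity prioritization

The connectivity of a candidate gene to the implicated seed set is the sum
of |ρ(gene, seed)| over the seeds, self-pairs excluded, so scores lie in
[0, |seeds|] and decompose additively over disjoint seed subsets.
Undefined terms contribute zero and are counted. This sum-of-|ρ| form is
the package's definition of the continuous connectivity score: against a
~34-gene seed set with typical pairwise |ρ| around 0.4 it produces scores
on the single-digit-to-low-teens scale, and it is implemented as a single
swappable function should a different aggregation be preferred.

Significance is empirical: `n_iter` single genes drawn uniformly from the
eligible universe (seed genes excluded from the null pool) give the null
score distribution; candidates get (1 + #{null ≥ score})/(n_iter + 1) and
Benjamini–Hochberg adjustment *within their batch* — the low-confidence
candidate list is one batch, each CNV region another. Null draws are
shared across regions, so a gene spanning two overlapping regions receives
identical score and p in both. Region nulls come from the full universe,
not from within the region, since small regions would give degenerate
nulls. `q < 0.1` (configurable) marks a gene as prioritized.

## Synthetic data

The generators produce inputs with exactly the structure the analysis
assumes, plus a truth table naming each variant's expected disposition.

* **Cohort:** trio families (duos/singletons on request). Planted causal
  variants satisfy every filter and their classifier; genotypes are drawn
  safely above the DP/GQ thresholds; de novo, inherited (from a parent
  marked affected), X-linked de novo (in a female proband) and
  compound-heterozygous configurations are supported. Benign background
  variants — Poisson per family, default rate 20 — are each constructed to
  fail exactly one stage, sampled uniformly over {site QC, genotype QC,
  frequency, recurrence, inheritance, classifier}, so every filter is
  exercised and the expected failure is recorded. Each background variant
  gets its own synthetic gene so that no spurious compound-het pair can
  arise by gene collision.
* **Expression:** log-normal values. On the log scale, genes in block
  b > 0 share a per-sample latent factor giving equicorrelation c within
  the block (positive-definite for 0 ≤ c < 1); block 0 is independent
  noise. The exponential link yields positive RPKM-like values without
  touching any rank statistic. The default shape — 280 samples from 24
  donors spanning early prenatal to infant stages — mirrors a
  developmental brain atlas subset; donor identity is recorded in the
  metadata but samples are generated independently (no donor random
  effect). At the default within-block correlation 0.65 the realized mean
  within-block Spearman |ρ| lands within ±0.1 of target for blocks of ≥ 5
  genes and ≥ 100 samples (the rank correlation of a bivariate normal is
  slightly below its Pearson parameter).
* **Panels:** named panels with exact sizes and an exact number of
  redundant memberships, so union = Σ sizes − overlaps; the default
  acceptance configuration uses the five clinical panel sizes 81, 1399,
  611, 131, 156 with 233 overlaps, a 2145-gene union.

Identical specification and seed give byte-identical outputs everywhere.

What passing on synthetic data does **not** show: recovery under realistic
LD, mutation-rate or annotation-error structure (no sequence context is
simulated); robustness to donor-level pseudoreplication in expression
(samples are independent here); or agreement with any specific real
cohort's numbers, which depend on the private genomes and the exact atlas
preprocessing.

## Problem sizes and numerical choices

The test suite and the acceptance script run at these scales, chosen so
that the distributional checks are well-powered while a full run stays in
the minutes range on a single CPU:

* filter-oracle equivalence: 100 seeded cohorts of ~200 variants each,
  compared exactly against an independent rule re-evaluation;
* null calibration: 200 independent 1000-gene × 100-sample universes,
  18-gene sets, 399 Monte-Carlo draws each (resolution 1/400); empirical
  type-I error at α = 0.05 must lie in [0.02, 0.09];
* planted-block power: 100 runs of an 18-gene block at c = 0.65 in a
  5000-gene × 280-sample universe, 2000 draws; detection means
  p ≤ 0.01;
* prioritization recovery: 50 runs, 6 block-member and 14 background
  candidates against an 18-gene seed block in a 2000-gene universe,
  999 draws, aggregate sensitivity ≥ 90% and false-positive rate ≤ 10%
  at q < 0.1.

Ties and determinism: Spearman uses average ranks; the quantile threshold
is a sorted-value lookup (smallest value covering the requested mass, the
minimum at quantile 0); hierarchical clustering inherits scipy's
deterministic merge order; all Monte-Carlo randomness flows from a single
`numpy` Generator seed per call; pipeline outputs carry no timestamps, so
re-running a configuration reproduces files byte for byte.

## Known limitations

* ACMG classification, annotation (VEP), variant calling and CNV calling
  are consumed, never recomputed; the package starts from annotated calls.
* The genome-wide threshold on a sampled pair set is an estimate; its
  sampling error is not propagated (at the default 2 × 10⁶ pairs it is
  negligible for the decision it feeds).
* Gene-set enrichment against external pathway databases is out of scope,
  as are polygenic scores, STR expansions and mitochondrial abundance.
* The compound-het frequency rule uses the annotated mean population
  frequency; no population-specific frequencies are modelled.
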