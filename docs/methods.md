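# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that a maintainer would otherwise have to
reverse-engineer.

## Data model and conventions

Genotypes are biallelic calls coded `hom_a = 0`, `het = 1`, `hom_b = 2`,
`missing = -1` in an `n_samples × n_snps` int8 matrix.  After loading a
PED/MAP fileset (and after simulation), **allele A is re-labelled to the
minor allele among controls**, with ties broken to the lexicographically
smaller letter.  This makes odds-ratio directions deterministic across files
and machines.  Positions are 1-based base pairs as in MAP files; intervals
are closed.  Sex and phenotype use the PLINK 1/2 codes; any other value is
an error because the covariate-adjusted analyses need complete data.  Ages
travel in a small sidecar TSV (PED has no age column).

## Marker QC

Three screens, reported for every SNP and applied jointly:

* call rate — analysis-stage missingness cutoff 50% (markers with worse
  missingness are uninformative rather than merely noisy; panel-design
  screens are stricter but happen before data reach this package);
* minor allele frequency ≥ 0.01 over all samples;
* Hardy–Weinberg exact test p ≥ 0.001 **in controls**.  Cases may deviate
  from HWE under true association (and under allelic imbalance — that is
  the LOH signal), so filtering on cases would remove exactly the loci of
  interest.  Case-group p-values are still reported.

The HWE test is the conditional exact test: conditional on observed allele
counts, heterozygote counts follow
P(n_het) ∝ n! 2^{n_het} / (n_AA! n_het! n_BB!) · n_A! n_B! / (2n)!,
and the two-sided p sums all outcomes no more probable than the observed
one.  It is computed with a ratio recurrence outward from the modal
heterozygote count, which is numerically stable at any sample size; a
brute-force exact-rational enumeration serves as the test oracle.

## Single-SNP association

The allelic test treats each individual as two independent alleles (the
convention of the tool family this reproduces; an approximation when HWE
fails) and uses the Pearson χ² without continuity correction on the 2×2
allele × status table.  OR = ad/bc with the Woolf logit 95% CI; a zero cell
switches OR/CI (not the χ²) to the Haldane–Anscombe +0.5 correction and
flags the result.  The genotypic test is the 2×3 Pearson χ² with empty
columns dropped (df reduced accordingly).  Bonferroni is textbook
min(1, m·p).

Logistic regression codes the genotype additively as copies of allele A
(the control-minor allele) with age and sex as covariates, fit by
maximum likelihood (Newton, tolerance 1e-8, ≤ 100 iterations) via
statsmodels; separation is reported as a non-convergence flag rather than an
exception.

Permutation correction shuffles case/control labels only and offers both
the family-wise max-T adjusted p (default) and the pointwise per-SNP
permutation p, both with the add-one estimator (1 + #{exceedances}) /
(n_perm + 1).  Under the null the permutation p is *valid* but
super-uniform: the genotype-count statistic is discrete, so ties make it
conservative.  Tests therefore check P(p ≤ α) ≤ α rather than exact
uniformity.

## Haplotypes and LD

Haplotype frequencies for 2–8 SNP windows come from the standard EM over
unphased multilocus genotypes: the E-step weights every compatible ordered
haplotype pair by the product of current frequencies (random mating), the
M-step re-estimates frequencies from expected counts.  Initialisation is
uniform over compatible haplotypes — the likelihood for windows this small
is well-behaved, so restarts are unnecessary and the fit is deterministic.
Convergence is declared when the largest frequency change drops below 1e-6
(≤ 1000 iterations); the log-likelihood is asserted non-decreasing at every
iteration.  Individuals with any missing call inside a window are dropped
from that window (simpler than summing over missing states; at the ~2%
missingness this package targets the efficiency loss is negligible).

The EM never sees phenotype labels.  Case/control haplotype frequencies are
posterior-expected haplotype counts within each stratum, which has two
consequences: stratum frequencies remain consistent with the pooled fit,
and label permutation is exact without re-running the EM (per-sample
haplotype dosages are fixed).  Per-haplotype association is the 2×2 χ² of
EM-expected fractional counts (haplotype vs all others × case vs control);
fractional counts are never rounded inside the statistic.  Haplotypes rarer
than 0.01 overall are pooled; window results are reported in haplotype
lexicographic order.

Pairwise LD: D' = |D|/D_max and r² from the two-locus EM frequencies.  The
D' confidence interval profiles the two-locus genotype likelihood over a
101-point D' grid (allele frequencies fixed at their sample estimates, sign
fixed at the point estimate) and reads the 5th/95th percentiles of the
normalised profile.  Blocks use the confidence-interval rule: a pair is
"strong LD" if its CI is (≥ 0.70, ≥ 0.98) and "strong recombination" if the
upper bound is < 0.90; a candidate block needs a strong-LD outermost pair
and ≥ 95% strong-LD among informative pairs; candidates are accepted
longest-first without overlap.  The size-dependent relaxations some tools
apply to 2–4-SNP blocks are deliberately not applied; the thresholds live
in one config dict (`GABRIEL_RULES`).

## LOH / micro-deletions (the core statistic)

A hemizygous germline deletion is invisible to an allelic-discrimination
assay except as apparent homozygosity.  Per SNP the homozygous-genotype
frequency f_hom (missing calls excluded from numerator and denominator) is
computed per group; the statistic is T/N = f_hom(case)/f_hom(control) with
a df-1 Pearson χ² on the homozygous/heterozygous × case/control table (a
zero margin yields p = 1 with a degenerate flag).  Frequent-LOH requires
**strictly** T/N > 1.0 and p < 0.05.  A micro-deletion region is a maximal
run of ≥ 3 frequent-LOH loci *adjacent in the full QC-passed panel order* —
adjacency among all genotyped markers, not among significant loci only.
For the packaged printed table, where the original full panel order is not
recoverable, the table's own region flags serve as the adjacency surrogate.

Power note: with n = 360+360, a deletion carried by 20% of cases vs 5% of
controls shifts f_hom by ~0.06–0.08, giving per-SNP power ≈ 0.4–0.5 at
α = 0.05; requiring three simultaneous adjacent hits drops region-level
power to ~10–25%.  The region caller is therefore a high-specificity,
modest-sensitivity instrument at these carrier frequencies (the measured
false-region rate on null flanks is ≈ 0), which is what the acceptance
script quantifies.

## Runs of homozygosity

PLINK-style scanner.  Window internals (50 SNPs, ≤ 1 heterozygote, ≤ 5
missing, hit threshold 0.05) follow the tool defaults because only the
segment-level criteria are part of the emulated design; all are exposed in
`RohParams`.  Per SNP the fraction of overlapping homozygous windows uses a
reduced denominator at panel edges.  Runs split at inter-SNP gaps > 1000 kb
*before* the segment criteria (≥ 1000 kb span, ≥ 100 SNPs, ≤ 50 kb/SNP
density) are applied; segment length is end − start in kb of the 1-based
inclusive positions.  Note the window mechanics trim roughly one SNP from
each edge of a perfect tract (edge SNPs are covered by too few all-inside
windows to clear the 5% hit threshold).

At the emulated study density (233 SNPs over 24 Mb ≈ 103 kb/SNP) the
density and SNP-count criteria are unsatisfiable, so a null cohort yields
zero segments — reproducing the negative screen such panels report.
Implant-recovery checks therefore use a dense panel (10 kb spacing) where a
2 Mb autozygous tract is detectable; this separates "the scanner is
correct" from "the study panel cannot support segment calls".

## qPCR relative quantification

2^(−ΔΔCt) with amplification efficiency assumed exactly 2.0 (no efficiency
correction — out of scope).  Replicate Ct values are arithmetically
averaged before ΔCt = Ct(target) − Ct(endogenous control); ΔΔCt subtracts
the reference specimen's ΔCt; fold = 2^(−ΔΔCt).  Inference runs on the
ΔΔCt (log2) scale for symmetry: paired two-sided t-test and Wilcoxon
signed-rank (exact for n ≤ 25, no ties), both reported because small-n
expression panels are routinely analysed both ways.  All-zero differences
return p = 1 with a degenerate flag.  "Unchanged" is reported for
|log2 fold| < 0.1 — a display convention, never an inference.

## Synthetic data: what it emulates, what it does not

The generator draws two haplotypes per individual per LD block from a
specified pool (blocks mutually independent), assigns disease either by a
logistic model on a risk haplotype (intercept set for ~50% marginal
prevalence; fixed group sizes filled by rejection, matching a matched
case-control design) or by block-specific case-chromosome frequencies
(retrospective sampling, used for the fixed case/control frequency
designs).  Deletion carriers have one haplotype removed over the span and
are typed homozygous for the surviving allele — never missing — which is
precisely the mechanism the T/N statistic presumes.  ROH samples have the
second haplotype copied from the first over a tract.  Missingness is
uniform at 2% by default (matching a ≥ 97.8% call-rate design); ages and
sex frequencies follow the emulated cohort demographics.  Defaults: 360
cases, 360 controls, 233 evenly spaced SNPs on chr6: 6,095,364–30,048,467,
independent SNPs with MAF ~ U(0.05, 0.5) unless blocks are specified.  All
randomness flows from one mandatory seed.

Not emulated: coalescent-realistic LD decay (blocks are exchangeable and
inter-block LD is zero), population stratification, genotyping batch
effects, strand ambiguity, and any correlation between deletion carriership
and haplotype background.  Passing tests therefore certify the statistics
and the calling logic under the assumed sampling model, not robustness to
real-data artefacts.

Problem sizes used by the test and acceptance runs (chosen to estimate each
quantity with comfortable Monte-Carlo margin): 2,000 replicates for type-I
error (SE ≈ 0.5%), 100 for the risk-haplotype sampling distribution, 200
for deletion recovery and qPCR power, n = 2,000 chromosomes for EM
recovery.

## Known limitations

* The allelic test's independent-alleles assumption inflates the statistic
  under HWE departure; the genotypic and logistic tests are the guards.
* D' confidence intervals use a profile (not full joint) likelihood; for
  very small samples the interval is approximate.
* The micro-deletion caller's sensitivity at modest carrier contrasts is
  low by construction (see power note above).
* Wilcoxon exact p-values require no ties; ties fall back to the normal
  approximation.
* Monomorphic markers get a placeholder second allele ("N") on load; they
  are removed by the MAF screen before any analysis.
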