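# Methods

## Model and procedure

The pipeline tests, probe by probe, whether a disease association at a
CpG probe's cis region is consistent with mediation through genetically
driven methylation, using only summary statistics from a GWAS (or GWAS
meta-analysis) and a cis-mQTL study, plus a reference genotype panel for
LD.

Per-cohort GWAS effects are first pooled by fixed-effects
inverse-variance meta-analysis (weights 1/se²; a SNP absent from a
cohort is pooled over the cohorts that report it, with the contributing
count recorded).  No random-effects variant is offered: the pooling
model is the fixed-effects one throughout.  Alleles are harmonized to a
reference table before any cross-table algebra: swapped (A1,A2) flips
the effect sign and frequency; strand-ambiguous palindromic SNPs (A/T,
C/G) with frequency in [0.4, 0.6] are dropped; incompatible allele sets
are an error (record API) or are dropped (vectorized table API).

A probe is eligible when at least one cis-mQTL (same chromosome, within
2 Mb) reaches p < 5e-8 and its SNP is covered by the GWAS.  The top
instrument is the shared SNP with minimum mQTL p; ties break by larger
|z|, then smaller position.  The SMR statistic and its delta-method SE
are as in the README; se_SMR is *defined* as |b_SMR|/sqrt(T) so the
identity P_SMR = chi-square tail of (b_SMR/SE_SMR)² holds exactly, and
T <= min(z_GWAS², z_mQTL²) is enforced by construction.  Published
tables of this design sometimes print P_SMR below the top SNP's P_GWAS,
which that inequality forbids; this implementation keeps the theoretical
inequality and treats the (b_SMR, SE_SMR, P_SMR) triple as the
internally consistent unit.

HEIDI candidate SNPs are cis SNPs sharing the probe, with mQTL p <
1.6e-3 (chi-square(1) > 10), r² to the top instrument in [0.05, 0.9],
greedily pruned (strongest mQTL |z| first) so no kept pair exceeds
r² = 0.9, and capped so the total SNP count including the top is 20 —
the printed N_HEIDI convention.  At least 3 candidates besides the top
are required; otherwise the probe is flagged `heidi_not_evaluable`
rather than silently passed, and counts as not passing unless
`keep_unevaluable` is set.  The deviation vector d_i = b_SMR(i) −
b_SMR(top) gets its covariance from first-order error propagation:
within each study, estimator correlations across SNPs equal the panel
dosage correlation r_ij (signed by harmonized effect alleles); the GWAS
and mQTL studies are independent.  Q = sum z_d,i² is referred to
sum_k lambda_k chi²_1 with lambda the eigenvalues of the z_d correlation
matrix.

The weighted-chi-square tail is computed by Imhof's
characteristic-function inversion.  Because the integrand oscillates
with asymptotic period 4*pi/q while its envelope decays only
polynomially, adaptive quadrature over the half-line is unreliable
(silent failures of several percent were observed in low-dimension
cases); the implementation instead integrates one oscillation period at
a time with 16-point Gauss–Legendre, vectorized over periods, truncating
when the envelope bound falls below 1e-8 — which also bounds the
truncation error.  Absolute accuracy ~1e-8 is ample for a filter applied
at the 0.05 level; far-tail *relative* accuracy is not attempted.

Stratified contrasts use the Wald chi-square (b1−b2)²/(se1²+se2²) with
1 df.  Candidates for a group-specific scan are probes passing both SMR
and HEIDI in exactly one group (exclusive or): probes significant in
both groups (e.g. the APOE-region cluster in the published scans) are
reported separately, not re-tested.  The other group's estimate enters
even when non-significant; probes absent from the other group's tested
set are skipped and logged, never imputed.  The family size m is the
candidate count and the flag threshold 0.05/m.  Cross-tissue
concordance uses m = shared tested probes.

Annotation assigns a probe to a gene if it lies in the gene body or
within 1.5 kb of a TSS (closest TSS wins ties); otherwise to the nearest
gene by TSS distance (a `boundary` metric is available as a config
switch, since the published nearest-gene metric is unstated).  Catalog
classification within ±1 Mb uses strict inequalities: p exactly 5e-8 is
S, exactly 5e-6 is N.  Cytogenetic-band bookkeeping is skipped when no
band table is supplied, not fabricated.

Enrichment scores a gene by the maximum −log10 P_SMR over its probes —
the simplest defensible competitive score; the external tool the
published scans used applies a k-th-best/monotonization scheme that is
not reproducible from its description, so the two are not equivalent.
The z-score uses the population (not sample) SD, since a set is compared
against the full scored population; location shifts of all scores cancel
exactly.  q-values are Benjamini–Hochberg; the reporting FDR level is
the largest grid level q in {0.05,...,0.25} with q x count(q) < 1, and
the full admissible set is reported so any published choice can be
expressed.

## Synthetic data: what it emulates, what it does not

Genotypes follow a latent-Gaussian AR(1) haplotype model: each haplotype
is an AR(1) Gaussian vector (adjacent correlation `ld_rho`) thresholded
at the allele-frequency quantile; two independent haplotypes sum to a
Hardy–Weinberg dosage.  Thresholding attenuates correlation: at
ld_rho = 0.9 the realized mean adjacent dosage r is about 0.66 (maf
0.2–0.5) — the tests freeze Monte-Carlo-derived bands, not the latent
value.  Under linkage the disease variant is chosen as the SNP whose
*realized* panel r to the methylation variant is closest to 0.5.

Methylation is y = beta_zx * g_causal + N(0,1); per-SNP marginal OLS
gives the mQTL table.  Disease status follows a logistic model on the
genetically driven methylation component b_xy * beta_zx * g_causal
(pleiotropy), on a direct per-allele effect of the second variant
(linkage, reusing b_xy as the direct log-odds), or on nothing (null);
cases and controls are ascertained from a simulated pool (base
prevalence 0.3) and per-SNP logistic Wald statistics computed by IRLS,
vectorized across SNPs, with separation-guarded fits dropped and
logged.  Group-heterogeneity multiplies b_xy by `group_ratio` in group-B
cohorts.

Defaults mirror the emulated study's layout at desk scale: mQTL n =
1980 (the blood resource's sample size), four cohorts totalling ~2700
cases / ~14700 controls, a 2000-individual reference panel, 20 cis SNPs
per probe, maf 0.1–0.5, ld_rho 0.8.  Effect sizes beta_zx = 0.5
(methylation SD per allele) and b_xy = 0.4 (log-odds per methylation SD)
are calibration choices — the emulated study reports no mQTL effect
magnitudes — picked to give strong but not degenerate instruments at
those sample sizes.  Each probe occupies an independent LD block 10 Mb
from its neighbours; multi-probe studies are unions of independent
blocks (no cross-probe LD, no polygenic background, no covariates,
no family structure — the cohort-level covariate and random-effect
adjustments of real analyses require individual data and are out of
scope).  Because of this, passing tests demonstrate correctness of the
summary-level machinery under the stated generative model, not
robustness to population structure, cryptic relatedness, or tissue
heterogeneity in real data.

All randomness derives from one integer seed: stage streams are
`default_rng((seed, stage, index))` with stage 0 = panel, 1 = mQTL,
2 = GWAS cohorts, so each stage is independently reproducible.

## Calibration checks and problem sizes

`mwas.validation` runs the generators and inference end to end at fixed
desk-scale sizes chosen to keep each check to seconds while leaving
binomial error bands informative:

- SMR type-I error: 500 null-disease probes (strong mQTL, b_xy = 0),
  n_mqtl = 1500, one 800/800 cohort; nominal 0.05 within 3 binomial SDs.
- Effect recovery: 200 pleiotropy replicates at n_mqtl = 5000, one
  2500/2500 cohort; relative bias < 10%, 95%-interval coverage in
  [0.90, 0.98].
- HEIDI discrimination: 500 replicates each of pleiotropy and linkage
  (n_mqtl = 2000, 1500/1500 cohort, ld_rho = 0.85, beta_zx = 0.8,
  b_xy = 0.5); linkage rejection must strictly exceed pleiotropy
  rejection.  Observed rates are roughly 0.03–0.08 vs > 0.98.
- Weighted-chi-square tail: 20 random correlation structures, each
  checked against 200,000 Monte-Carlo draws within 3 MC SEs.
- Stratified contrast: 1000 replicate pairs of independently simulated
  equal-effect strata; the Wald statistic's KS test against chi²(1)
  must give p > 0.01.
- Toy study: the five-probe mixed fixture (seed 42) must recover exactly
  the two pleiotropy probes at the study-wide 0.05/91000 threshold.
  The realized-eligible denominator (5 probes → threshold 0.01) is no
  real filter at toy scale, so the fixture pins the study-wide
  convention.

## Numerical and degenerate-input choices

- b_mQTL = 0 is an undefined-ratio error; b_GWAS = 0 returns
  (0, inf, 1).  Non-positive SEs are errors everywhere.
- Monomorphic SNPs: redrawn up to 10 times in the panel, then excluded;
  dropped with a log entry in simulated samples.  Logistic separation
  (|b| >= 10 or singular information) drops the SNP from that cohort.
- mQTL p-values printed as 0 in published tables are stored as 1e-300
  (the dialect requires p in (0, 1]).
- Readers drop invalid rows with logged line numbers by default; a
  strict mode escalates to errors.  Read-then-write is the identity on
  canonical records for all dialects; BED conversion is the only place
  0-based coordinates appear.
- Bonferroni denominator defaults to the realized eligible-probe count;
  a fixed override (e.g. 91000) reproduces a study-wide convention.

## Known limitations

- Single-SNP instrument only; no multi-SNP SMR or other colocalization
  methods.
- Fixed-effects pooling only; no heterogeneity modelling, genomic
  control, or sample-overlap correction.
- The enrichment score is intentionally simpler than the external
  tool's; ranking agreement, not score equality, is the design goal.
- The far tail of the HEIDI p-value is reported with absolute (not
  relative) accuracy; it is a 0.05-level filter, not an effect-size
  estimate.
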