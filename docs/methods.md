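# Methods

## The statistic

The pipeline tests whether a prioritized set of candidate ("case") genes is
enriched for nominal SNP associations with a quantitative behavioral
outcome, relative to frequency-matched resamples of control-gene SNPs.
Inference is at the gene-set level: per-SNP p-values below 0.05 are treated
purely as counting units, with no per-SNP multiplicity correction — many of
them are false positives by construction, and the matched resampling null
accounts for the number of variants counted.

For an epoch (training genes plus the top p% of ranked case genes) with
case SNP set `S`:

- observed = #{j ∈ S : p_j < 0.05} over valid association rows;
- R control draws each sample, without replacement and per MAF band,
  exactly the case set's band counts (bands [0.10, 0.15), [0.15, 0.20),
  [0.20, 0.30), [0.30, 0.50]; left-closed, final band closed at 0.50);
- q95 = 95th percentile of the R null counts (linear/type-7 interpolation,
  fixed so results are bit-reproducible);
- enriched ⇔ observed > q95; empirical p = (1 + #{null ≥ observed})/(1 + R),
  never zero by the +1 correction.

Matching is at the SNP level, stratified by band with exact counts. A
gene-level sampling scheme cannot guarantee the band profile, so the SNP
scheme is the default; the band profile of every draw equals the case
profile by construction. Epoch gene counts use the ceiling, ⌈p/100·N⌉
(with N = 847 ranked genes the 10% epoch holds exactly 85). Epochs are
nested and no correction is applied across them.

## Association models

Per SNP, two OLS fits with two-sided t-tests on residual degrees of
freedom (never the normal approximation):

    y ~ 1 + d + G + X          →  β_main, p_main
    y ~ 1 + d + G + X + d·G    →  β_int,  p_int

`d` is minor-allele dosage (orientation by sample frequency; at a 0.5 tie
the lexicographically smaller allele is counted), `G` the group indicator
(OI = 0, TBI = 1), `X` the retained covariates. Missing genotypes are
dropped listwise per SNP, never imputed. SNP columns without missing calls
are fitted in one vectorized Frisch–Waugh pass (residualize y and the
dosage columns on the fixed design, then solve the 1- or 2-parameter
system per SNP); columns with missingness use the per-SNP solver. The two
paths are algebraically identical and are cross-checked against
statsmodels OLS to 1e-8 in the test suite. Rows are flagged invalid — and
excluded from enrichment counts and matching profiles — when the SNP is
monomorphic in-sample, the design is rank-deficient, or fewer than
(parameters + 5) complete samples remain.

Outcome preprocessing: samples whose short-to-long change score deviates
more than 3 SDs of change from the mean change are excluded (the rule
needs ≥3 change scores and a nonzero SD); outcome T scores above 90 (four
normative SDs) are Winsorized to 90. Covariate trimming happens once, on
the no-SNP model `y ~ G (+ PC1) + candidates`, backward-dropping the least
significant candidate at α = 0.05 — per-SNP trimming would be both
irreproducible and computationally explosive. Ancestry PC1 and the group
indicator are never trimmed.

## Quality control

Rules apply in a fixed order so per-rule counts are reproducible:
sample call rate (< 99% removed) first, then per SNP: non-autosomal or
mitochondrial → indel → intergenic/no gene assignment → SNP call rate
(< 90%) → HWE exact p < 1e-4 → MAF < 10%. Each SNP is attributed to the
first rule it triggers; removals plus retentions always sum to the input
count, and a second pass removes nothing.

The HWE test is the exact conditional test, two-sided by probability
ordering: given the allele counts, each possible heterozygote count h has
conditional weight n!/(n_AA! h! n_bb!)·2^h; the p-value sums the
normalized weights not exceeding the observed one. Weights are exact
integers (Python arbitrary precision), so probability ties are resolved
exactly; the test suite checks every genotype table with up to 30
individuals against an independent dynamic-programming enumeration.

Ancestry PCA standardizes each marker by 2f̂ and √(2f̂(1−f̂)) with per-SNP
mean imputation of missing calls (used for PCA only); monomorphic markers
are dropped with a warning; each PC is oriented so the lexicographically
smallest sample id scores non-negatively. The relatedness screen computes
per-pair mean and SD of identity-by-state, (2 − |d_i − d_j|)/2, over
jointly called SNPs; its expectation under HWE at f = 0.5 is 0.625, used
as a calibration check.

## Gene ranking

The external prioritization service originally used for candidate ranking
publishes neither its similarity measure nor its meta-ranking, so the
package implements a transparent stand-in: per annotation category
(pathways, biological processes, phenotype, literature, protein
interactions, co-expression), a profile of terms hypergeometrically
over-represented in the training genes (one-sided, α = 0.05,
configurable); per gene, the Jaccard index against the profile; per gene,
the combined score as the mean of within-category percentile ranks
(average ranks for ties; final ties broken lexicographically). The
acceptance surface of this module is recovery of the synthetic
ground-truth order (Spearman ρ > 0.9), not replication of any external
tool's output; users holding real externally computed ranks can supply
them via `rank_case_genes(..., precomputed=...)` and bypass the stand-in.
Term enrichment of gene sets uses the same hypergeometric tail with
Benjamini–Hochberg control within category.

## Synthetic cohort

The generator reproduces the statistical structure the analysis assumes,
with defaults matching the study scale it emulates:

- n = 140 samples, TBI fraction 69/140; genotypes as two Bernoulli(MAF)
  draws per SNP (HWE), missing completely at random (default rate 0.002);
- post-QC MAF spectrum uniform on [0.10, 0.50] (the chip's true post-QC
  spectrum is unpublished; this choice makes every band populated);
- short-term outcome means 43.76 (OI) / 52.80 (TBI), long-term 45.12 /
  55.79; pre-injury means 45.62 / 50.43 with SD 12.5; SES z means 0.11 /
  −0.14 with SD 0.97 — all on the cohort's reported scale;
- residual noise SD 10 (the outcome's normative SD); covariate
  coefficients default to 0.40 T per pre-injury T (implying a pre-injury–
  outcome correlation near 0.5) and −1.5 T per SES SD;
- planted effects add β·(d − d̄) per allele (interaction effects only in
  the TBI group). Centering keeps group means at their design values, so
  planting effects does not push outcomes into the Winsorization cap and
  the per-allele slope is unchanged;
- optional two-subpopulation structure via Balding–Nichols Beta-perturbed
  allele frequencies at a given divergence;
- the annotation catalog gives training genes a shared core term set per
  category, case genes a linearly decaying share of the core (so the true
  similarity order is the generation order), and control genes uniform
  draws from the whole term universe (expected core overlap equals the
  chance rate).

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent), genotyping batch effects, informative missingness,
non-Gaussian outcome tails, and selection into the cohort. Passing
calibration on these cohorts therefore demonstrates the statistic's
correctness under its stated assumptions, not robustness to LD-induced
correlation between case and control SNPs.

## Calibration and power conditions

The calibration harness regenerates cohort + scan + enrichment per
replicate, using the generator's ground-truth ranking (it calibrates the
enrichment statistic, not the ranker) and skipping QC (generated SNPs
satisfy the QC conditions by design, and matching bands on the known
design MAF). Type-I calibration uses 200 null replicates at n = 140 with
300 case SNPs (75 genes × 4) and 3,000 control-pool SNPs, R = 500,
epochs every 25 percentiles: the enriched flag fires within the 99%
binomial band around 5% in every epoch. Power uses one causal SNP per
planted gene — so aggregate genetic variance stays realistic as the
effect grows — with 10 planted genes among 75 case genes at 2 SNPs/gene,
evaluated at the 25th-percentile epoch over a per-allele interaction grid
of 4, 7, 10 T-score units (chosen by pilot power analysis to span the
steep part of the power curve); replicate seeds are shared across the
grid (common random numbers), which stabilizes the monotonicity of flag
rates. Problem sizes throughout (R = 300–2,000 in tests and the
acceptance script versus the 10,000-draw production default; 100–300
replicates) are chosen to keep full calibration runs in the minutes range
on one CPU at these cohort sizes.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence`; per-stage and
  per-cell seeds derive from the master seed via fixed spawn keys, so any
  stage or enrichment cell can be re-run in isolation.
- A full pipeline re-run under the same config and seed is byte-identical,
  figures included (PNG metadata is pinned).
- Degenerate inputs: monomorphic SNPs yield valid=False rows; empty draws
  and empty gene sets return zero counts with warnings; a band whose
  control pool cannot cover the case profile raises an error naming the
  band and deficit rather than silently approximating.
- The empirical p and the q95 quantile definitions are fixed as stated
  above; changing either changes results at the ±1-count level, which
  matters at small R.

## Known limitations

- Independence of SNPs is the central simplification; with real chip data
  LD makes nominal-association counts overdispersed relative to this
  null, and band-matched resampling absorbs only the frequency component
  of that. The enriched flag's type-I rate on real data is therefore not
  guaranteed by these simulations.
- The ranking stand-in shares only its *intent* with the external
  prioritization service; ranks from the real service should be supplied
  when fidelity to a published analysis matters.
- The cohort generator draws covariates as Gaussians and injects effects
  linearly; threshold or interaction structures among covariates are out
  of scope.
- With ~140 samples the interaction scan has useful power only for
  per-allele effects of several T-score units; the calibration harness
  quantifies this regime rather than hiding it.
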