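# Methods

This note records the statistical definitions the package implements, the
design parameters of the synthetic generators, and the numerical choices
made along the way.

## 1. Score construction (`rriscore.scores`)

**Per-SNP regression.** For each SNP, ordinary least squares of the regional
volume on the major-allele count (2 − minor-allele dosage) plus covariates:
intercept, sex, pubertal development score, total intracranial volume, and
scanner site as dummy variables (first site dropped). Rows with missing
dosage or covariates are dropped per SNP; at least 10 complete cases are
required. A constant dosage raises `DegenerateSNPError`; a rank-deficient
design raises `RankDeficientError` naming the collinear columns.

**Screening.** SNPs with a strict two-sided p < 0.1 for the allele term are
retained. The nominal (not FDR-adjusted) threshold is deliberate: the score
is a composite predictor whose downstream validity is evaluated by the
battery and the random-SNP control, not by per-SNP inference.

**LD pruning.** Pairwise genotypic r² (squared Pearson correlation of
dosage vectors over pairwise-complete subjects) defines a graph with edges
at r² > 0.5; within each connected component only the smallest-p SNP is
kept (ties broken lexicographically by SNP id for determinism).

**Weights and normalization.** The retained SNP's weight is minus its
major-allele coefficient, i.e. its per-minor-allele volume effect. The raw
score is the weighted sum of minor-allele dosages (missing dosages imputed
at the SNP's cohort mean), then min-max normalized to 0–10 on the
construction cohort. By construction the construction-cohort minimum and
maximum are exactly 0.0 and 10.0. Out-of-sample values are *not* clipped;
scores outside [0, 10] are flagged via an `out_of_range` column.

**Control score.** A panel of SNPs drawn uniformly without replacement from
a non-candidate pool (seeded, recorded in the definition's provenance) is
passed through the identical pipeline. On a null cohort this frequently
retains nothing (`NoScoreError`), which is itself the expected negative
result.

## 2. Association battery (`rriscore.association`)

**Derived predictors.** CM (childhood maltreatment) = min(max of six CTQ
subscale severities, 2), merging the top three severity groups; SDQ
externalizing = conduct + hyperactivity, internalizing = emotional + peer.

**Models.** For each score × outcome: a main-effect model
`outcome ~ score + sex + CM` and an interaction model adding `CM:score`,
with CM entered numerically (0/1/2). Count-like outcomes (DAWBA depression
band, SDQ composites) use a Poisson GLM with log link (statsmodels IRLS,
convergence tolerance 1e-12 so that standard errors agree with an
independent Newton–Raphson implementation to 1e-8); CAPE dimensions use OLS
on the natural-log outcome, requiring strictly positive values. At n = 861
the main model has 857 residual df and the interaction model 856.

**Inference.** The reported row is the `score` (main) or `CM:score`
(interaction) coefficient with its Wald statistic and two-sided p.
Benjamini–Hochberg adjustment is applied within per-instrument families
(DAWBA / SDQ / CAPE). CAPE interaction rows are computed but flagged
`reported=False` (exploratory only). Poisson fits also report an upper-tail
χ² p for the residual deviance as a goodness-of-fit diagnostic.

## 3. Mouse behavior (`rriscore.mouse`)

Sucrose preference = sucrose/(sucrose+water)×100. Each readout is
z-normalized against the NS (non-separated) group using the sample (n−1)
SD, multiplied by −1 for readouts where lower raw values are more
depressive-like (sucrose preference, lit-box time), so positive z always
means more depressive. The depression index is the mean of the two z-scores;
the NS mean of every z is 0 by construction. Group contrasts use the
pooled-variance Student t (df = n₁+n₂−2; 13 vs 10 animals gives df 21).
The sex-ratio design check uses the two-sided Fisher exact test
(minimum-likelihood definition: sum of hypergeometric probabilities of
tables no more likely than the observed one, margins fixed).

## 4. qPCR statistics (`rriscore.qpcr`)

**Quantification.** ΔCt = mean(target triplicate) − mean(reference
triplicate, gene Rab5a); the calibrator is the NS-group mean ΔCt per gene,
so the NS geometric-mean relative level is exactly 1; relative level =
2^−ΔΔCt. Measurements with fewer than 2 usable wells are excluded
(`LowQualityError` at the single-measurement API, logged exclusion in the
table API).

**Permutation factorial ANOVA.** Type-II F statistics for gene, group and
gene×group, computed from residual-sum-of-squares differences between
nested dummy-coded models. The exchangeable unit is the animal: group and
interaction effects permute group labels across animals (each animal's
gene profile travels intact); the gene effect permutes gene labels within
each animal. Monte-Carlo p-values use the add-one estimator
(1+#{F* ≥ F})/(1+n_perm); an exhaustive mode enumerates all distinct
relabelings for tiny designs and was verified against an independent
statsmodels-formula enumeration oracle.

**Pairwise tests.** Per-gene MS-vs-NS pooled-t permutation tests, exact by
enumeration when C(n, n₁) ≤ 20 000 and Monte-Carlo otherwise, BH-adjusted
across genes.

**Correlogram.** Pairwise-complete Pearson correlations with two-sided
p-values; pairs with fewer than 4 shared observations or a constant
variable are undefined (NaN). Variables are ordered by their loadings on
the first principal component of the correlation matrix (NaN entries
treated as 0 for the eigendecomposition; the eigenvector sign is fixed so
the largest-magnitude loading is positive, making the order
deterministic — anticorrelated variables land at opposite ends). The
default significance mask is unadjusted p < 0.05; `fdr=True` masks on
BH-adjusted p.

## 5. Synthetic generators (`rriscore.synthetic`)

All randomness flows from one `numpy.random.default_rng(seed)`; outputs
are byte-identical across reruns.

**Human cohort.** Genotypes are binomial(2, MAF) with MAF uniform on
[0.05, 0.5] unless pinned per SNP. LD blocks use copy-with-resampling: each
block member copies the block template and independently resamples each
subject with probability 1 − √r², giving expected pairwise correlation √r²
(hence r² near the target between template and copies, ~r² between copies)
while preserving the marginal MAF. Volumes are a linear predictor
(sex, puberty, TIV, scanner offsets, plus injected per-SNP minor-allele
effects) plus Gaussian noise; defaults anchor the hippocampus at mean
1.20 ml (residual SD 0.08) and the mPFC at 30.1 ml (residual SD 2.4).
Outcomes are Poisson (log link) or log-normal on
`intercept + b_score·true_score + b_cm·CM + b_int·CM·true_score + b_sex·sex`,
where `true_score` is the causal weighted allele sum normalized to 0–10;
instrument ranges can be imposed via `clip` (depression band capped at 5,
SDQ composites at 20). Note a capped Poisson is no longer exactly Poisson;
coverage checks therefore use an uncapped outcome. CM categories are drawn
with probabilities proportional to 588/283/108, and the six CTQ subscales
are constructed so that their maximum (capped at 2) reproduces the CM
category exactly.

**Mouse experiment.** NS behavioral readouts are Gaussian (sucrose
preference 78 ± 6 %, lit time 210 ± 45 s); MS group shifts are expressed in
NS-SD units, defaulting to 1.75 (sucrose) and 0.93 (lit time) —
back-computed as d = t·√(1/13+1/10) from the group contrasts the design is
powered for. Triplicate Ct values are per-animal true Ct plus iid
measurement noise (SD 0.15 by default) with a per-animal biological ΔCt SD
of 0.3; MS log2 expression shifts (defaults: Ikbkb −0.6, Il10ra −0.6,
Il10rb −0.8, Il18 −0.5, Pla2g6 −0.6, Ptgs1 +0.6 on a 14-gene panel) are
injected as −shift cycles on the target ΔCt, so 2^−ΔΔCt recovers the
injected fold change in expectation. Ct values are written at 4-decimal
precision (≈1e-4 relative quantification error).

**Realism limits.** Genotypes are in Hardy–Weinberg equilibrium without
population structure; LD is block-wise exchangeable rather than
distance-decaying; outcome margins are idealized (no zero-inflation,
no item-level structure); mouse readouts ignore litter and housing
effects. These are deliberate: the generators exist to give the analysis
code data with known ground truth, not to emulate every cohort artifact.

## 6. Verification strategy

Every nontrivial computation is checked against an independent route in
the test suite: OLS against closed-form normal equations, the Poisson GLM
against a hand-written Newton–Raphson MLE, BH against the literal step-up
definition, Fisher's exact test against hypergeometric enumeration (all
2×2 tables with N ≤ 30), and the permutation ANOVA's exhaustive mode
against a statsmodels-formula enumeration oracle.

Monte-Carlo properties use pre-committed seed sequences (`range(n)`,
fixed offsets) chosen before observing outcomes:

- **Screening power**: five injected causal SNPs (−0.02 ml per allele,
  MAFs 0.2–0.4, n = 2000) must all pass p < 0.1 screening in ≥ 90 of 100
  seeds. A-priori per-SNP power exceeds 99.9% (|z| ≈ 6.3 at residual SD
  0.08), so the joint criterion holds with large margin by design.
- **Coefficient coverage**: at n = 5000, the generating (b_score, b_cm,
  b_int) of an uncapped Poisson outcome should each lie within 2 Wald SEs
  of their estimates. Coverage is pooled per coefficient across 100 seeds
  (300 trials). Because a 2-SE interval's nominal coverage is 95.45%, the
  ≥ 95% requirement is asserted via an exact one-sided binomial bound at
  α = 10⁻³ (observed successes must exceed the 0.001 quantile of
  Binomial(300, 0.95)); a point comparison of a Monte-Carlo proportion to
  its own asymptote would reject a correct implementation almost half the
  time, while genuinely broken coverage (e.g. 87%) fails the bound
  essentially always.
- **Null calibration**: on 500 null cohorts (n = 250, 60-SNP random pool,
  40-SNP control panels) the control-score battery's pooled raw p < 0.05
  rate must lie in [0.04, 0.06]; seeds where no SNP survives screening
  (expected ≈ 0.9⁴⁰ ≈ 1.5%) contribute no score, which is recorded and
  skipped.
- **qPCR recovery**: the recovered log2 fold change (MS−NS difference in
  mean log2 relative level) averaged over 20 seeds must lie within ±0.2 of
  each injected shift at triplicate noise SD 0.3 with 10 animals per group;
  a single draw has SE ≈ 0.11, so averaging implements the generator's
  "recovery in expectation" guarantee at Monte-Carlo resolution.

Problem sizes in the acceptance checks (cohort sizes, panel sizes, seed
counts) are the package's own verification design, chosen for statistical
resolution at desk-scale runtimes.

## 7. Limitations

- The battery's Poisson Wald p-values are asymptotic; at small n they are
  only approximately uniform under the null (the calibration check runs at
  n = 250 where the approximation is adequate).
- Min-max normalization ties the score scale to the construction cohort;
  out-of-sample scores can leave [0, 10] and are flagged, not clipped.
- LD pruning keeps a single representative per connected component; no
  attempt is made to re-estimate joint effects of partially correlated
  SNPs.
- The permutation ANOVA conditions on the observed design; with very small
  groups the discrete permutation distribution bounds attainable p-values
  at 1/(n_perm+1) (or the exact enumeration granularity).
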