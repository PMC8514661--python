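# rriscore

Candidate-gene neuroimaging scores and their downstream statistics, with a
translational mouse arm.

## The scientific problem

Immune signalling genes are plausible contributors to stress-related
psychopathology, but individual SNP effects on the brain are tiny. One way to
aggregate them is a **region-related immune-gene score (RRI)**: for a panel of
SNPs in immune genes, regress a regional gray-matter volume (hippocampus or
medial prefrontal cortex) on each SNP's allele count, keep nominally
associated SNPs, remove redundant SNPs in linkage disequilibrium, and combine
the survivors into a weighted allele sum per subject, min-max normalized to
0–10. Higher scores mean an immune-allele profile associated with smaller
regional volume.

The package implements that construction and everything around it:

- **`io_formats`** — genotype I/O (PLINK `.raw`-style TSV and VCF via
  `cyvcf2`, with minor-allele orientation), plus validated TSV schemas for
  covariates, phenotypes, mouse behavior and qPCR plates.
- **`scores`** — per-SNP volume regressions (adjusting for sex, pubertal
  stage, total intracranial volume, scanner site), screening at p < 0.1,
  greedy LD pruning at genotypic r² > 0.5, weighting, normalization, and a
  random-SNP negative-control score built by the identical pipeline.
- **`association`** — the score-to-symptom battery: Poisson GLMs for
  count-like instruments (DAWBA depression band, SDQ composites), log-OLS for
  CAPE dimensions, each with a childhood-maltreatment (CM) main-effect and
  interaction model, Benjamini–Hochberg FDR within instrument families, and a
  residual-deviance goodness-of-fit check.
- **`mouse`** — maternal-separation arm behavior: sucrose preference,
  NS-referenced z-scores with the depressive sign convention, a composite
  depression index, pooled Student t-tests and Fisher's exact test.
- **`qpcr`** — 2^–ΔΔCt relative quantification against a reference gene with
  the control group as calibrator, a permutation factorial (gene × group)
  ANOVA, per-gene permutation t-tests with FDR, PC1-ordered
  behavior–expression correlograms, and regressions with confidence bands.
- **`synthetic`** — generators for both arms with injectable ground truth
  (causal SNP effects, outcome coefficients, log2 expression shifts), so
  every stage is testable without restricted data.
- **`pipeline` / CLI** — one YAML config drives both arms end to end and
  writes a manifest with checksums for byte-identical reruns.

## Worked example

Build a hippocampal score on a synthetic cohort with two injected causal
SNPs (`examples/01_build_score.py`):

```python
from rriscore import HumanSimSpec, build_rri, simulate_human_cohort

spec = HumanSimSpec(
    n_subjects=800, n_candidate_snps=40, n_random_snps=0,
    causal_snp_effects={"cand0010": -0.03, "cand0011": 0.03},
    snp_mafs={"cand0010": 0.3, "cand0011": 0.25}, seed=7,
)
genotypes, covariates, phenotypes, truth = simulate_human_cohort(spec)
definition, scores, effects = build_rri(
    genotypes, phenotypes["hippocampus_ml"], covariates, region="hippocampus"
)
```

Output:

```
SNPs screened at p < 0.1 : 8
SNPs retained after LD pruning: 8
score range: 0.00 - 10.00
retained SNPs and weights:
  cand0002: +0.0088
  cand0009: -0.0077
  cand0010: -0.0330
  cand0011: +0.0312
  ...
```

Both injected SNPs are recovered with weights close to their generating
effects (the weight convention is minus the major-allele coefficient, i.e.
the per-minor-allele effect), and six null SNPs slip through nominal
screening, as expected at p < 0.1 with 38 null tests.

The mouse arm (`examples/03_mouse_behavior.py`):

```
       sucrose_pref_pct  lit_time_s  depression_index
group
MS                66.79      171.35              1.42
NS                78.60      189.60             -0.00

         measure      t  df      p
     z_anhedonia 3.7328  21 0.0012
       z_anxiety 0.8572  21 0.4010
depression_index 3.7872  21 0.0011

sex-ratio Fisher exact p: 1.0000
```

The other examples cover the association battery (`02`), the qPCR statistics
(`04`) and the full pipeline with its manifest (`05`). The same pipeline is
available from the command line:

```bash
rri run-all --config config.yaml --out run_dir
rri simulate mouse --out mouse_data
rri mouse-behavior --in mouse_data/behavior.tsv --out z.tsv --stats stats.tsv
```

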