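# polyburden

Population differentiation and polygenic burden analysis for GWAS-derived SNP
sets, built as a tested, fully synthetic-data-capable pipeline.

Given multi-population genotypes (VCF + sample→population panel), a GWAS
association table and per-individual phenotypes, the pipeline:

1. **harmonizes** the association table (strand complements, OR < 1 flips,
   duplicate collapse, genome-wide p ≤ 5e−8, risk = OR ≥ 1.2);
2. computes per-population **effect-allele frequencies** and cross-population
   fold differences;
3. quantifies **population differentiation**: per-SNP Weir–Cockerham Fst for
   every population pair, a high-Fst selection test against a
   frequency-matched random-SNP null (Pearson chi-square, 1 df), and genotype
   PCA on standardized dosages;
4. tests per-SNP, per-population risk-allele **enrichment/depletion** against
   the pooled global population (two-sided Fisher exact, Benjamini–Hochberg
   FDR within population, FDR < 0.05), with gene-level rankings and a signed
   −log10(FDR) heatmap matrix ordered by hierarchical clustering;
5. **LD-clumps** the enriched risk SNPs (greedy by p-value, r² > 0.1 removed
   within 250 kb) and computes the ln(OR)-weighted **polygenic risk score**
   with quintiles and low/moderate/high risk categories;
6. estimates the **association** of PRS quintile with prevalent disease
   (robust Poisson prevalence ratios), incident disease (Cox hazard ratios,
   age/sex/BMI and full-biomarker models; Kaplan–Meier cumulative incidence)
   and quantitative biomarkers (adjusted OLS).

A first-class simulator (`polyburden.synthetic_data`) generates
multi-population genotypes with controllable Fst (Balding–Nichols) and block
LD, a GWAS summary table with OR ≥ 1.2 risk variants, and phenotypes from a
log-link prevalence model plus a proportional-hazards incidence model — so
every stage is testable without external data.

## CLI

One subcommand per stage plus `run-all`, driven by a YAML config:

```yaml
# config.yaml
seed: 11
outdir: runs/demo
sim:
  n_snps: 2000
  n_assoc_snps: 1000
  n_risk_snps: 300
  ld_block_size: 5
  ld_r2: 0.8
  n_planted: 30          # two opposite-direction SNP groups for validation
  planted_shift: 0.25
  prevalence_beta: 0.145 # log-PR per PRS SD
  hazard_beta: 0.248     # log-HR per PRS SD
  populations:
    - {name: POP1, n_samples: 834, fst_to_ancestral: 0.05}
    - {name: POP2, n_samples: 834, fst_to_ancestral: 0.05}
    - {name: POP3, n_samples: 833, fst_to_ancestral: 0.05}
    - {name: POP4, n_samples: 833, fst_to_ancestral: 0.05}
    - {name: POP5, n_samples: 833, fst_to_ancestral: 0.05}
    - {name: POP6, n_samples: 833, fst_to_ancestral: 0.05}
```

```bash
polyburden run-all --config config.yaml
# or stage by stage (each stage checks its upstream inputs):
polyburden simulate --config config.yaml
polyburden catalog  --config config.yaml
polyburden freqs    --config config.yaml
polyburden fst      --config config.yaml
polyburden pca      --config config.yaml
polyburden enrich   --config config.yaml
polyburden clump    --config config.yaml
polyburden score    --config config.yaml
polyburden assoc    --config config.yaml
```

To analyse existing data instead of simulating, set `vcf`, `panel`,
`summary` and `phenotypes` paths in the config and use
`polyburden run-all --skip-simulate`.

Outputs are plain TSV/JSON under `outdir`, and `manifest.json` records the
full config, seed and a sha256 per output file; reruns with the same config
are byte-identical.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests (estimator
symmetry, BH monotonicity, clumping post-conditions, CI calibration) and
`tests/test_acceptance.py`, which checks each acceptance criterion —
estimator-vs-oracle equivalences, parameter recovery and the end-to-end run
with planted enrichment structure — at its stated tolerance. Independent
oracle implementations live in `tests/oracles.py`.

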