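# telomr

A tested Python toolkit for bidirectional two-sample Mendelian randomization
(MR) and multivariable-MR mediation analysis of leukocyte telomere length
(LTL) against complex traits, together with the observational cohort arm and
a ground-truthed synthetic-data generator that makes every stage verifiable
by parameter recovery — no external data downloads required.

## What's inside

| Module | Purpose |
| --- | --- |
| `telomr.sumstats` | Read/validate GWAS summary statistics, harmonize against a reference panel (palindrome removal, strand flips, allele swaps), standardize effects to the explained-variance scale, derive difference traits (e.g. reproductive lifespan) |
| `telomr.instruments` | LD clumping (greedy index-SNP selection, PLINK-style p1/p2/kb/r2), HBB/HLA region masks, allele-frequency concordance filter, Steiger directionality filter, multi-trait Steiger pleiotropy filter, two-phase mediation clumping, minimum-rank clumping for MVMR |
| `telomr.mr` | Wald ratio, IVW, MR-Egger, weighted median, simple/weighted mode, Cochran's Q, full bidirectional MR driver |
| `telomr.mvmr` | Multivariable MR with conditional F-statistics, mediation decomposition (product and difference of coefficients), regression-dilution correction, simulated mediation-proportion CIs, causal-network construction |
| `telomr.observational` | LTL covariate adjustment, per-trait regressions, outlier trimming, Welch tests, statin correction, Lasso stability selection (one-SE rule), effective number of tests, female reproductive-phase model |
| `telomr.simulate` | Block-AR(1) LD, GWAS summary-statistic triplets under a structural model E→M→O with pleiotropic/reverse-causal variants and sample overlap (analytic and individual-level backends), observational cohorts with planted effects |
| `telomr.pipeline` / `telomr.cli` | End-to-end orchestration with seeded determinism, attrition-reconciled reports, significance gating, `telomr` console script |

## CLI

```bash
# synthetic GWAS triplet (exposure/mediator/outcome + panel + LD + truth)
telomr simulate --seed 1 --out-dir runs/sim

# synthetic observational cohort
telomr simulate-cohort --seed 1 --n 10000 --out runs/cohort.tsv

# harmonize summary statistics against a panel
telomr harmonize --sumstats runs/sim/exposure.tsv --panel runs/sim/panel.tsv \
    --out runs/exposure_harmonized.tsv

# full pipeline: simulate -> harmonize -> select IVs -> MR -> mediation
telomr run --seed 1 --out-dir runs/full
```

`telomr run` accepts a YAML config overriding any threshold (genome-wide
5e-8; clump p1=1e-4, p2=0.01, kb=250, r2=0.01; AF difference 0.05; Steiger
Z −1.96; significance 0.05/141 and 0.05/323) or simulation parameter.
Identical seed + config produce byte-identical outputs.

## Library example

```python
from telomr import SimulationConfig, simulate_gwas_triplet, mediate

cfg = SimulationConfig(alpha_EM=0.5, theta_M=0.3, theta_direct=0.35, seed=1)
study = simulate_gwas_triplet(cfg)          # truth: P_M = 30%
res = mediate(study.exposure, study.mediator, study.outcome,
              study.panel, study.ld, seed=2, harmonized=True)
print(res.p_m, res.p_m_ci)                  # recovered mediation proportion
```
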