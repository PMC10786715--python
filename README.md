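# hemascan

Perturbational whole-blood cytometry phenotyping: from per-event optical
measurements to genetic and clinical discovery.

Clinical hematology analyzers record three optical axes per cell event —
forward scatter (FSC, cell size), side scatter (SSC, internal structure)
and side fluorescence (SFL, nucleic-acid content) — across four dyed
channels (WDF, WNR, RET, PLT-F). Incubating whole blood with chemical or
physiological stressors before measurement evokes cell populations that
are invisible at baseline (for example a high-SSC/high-SFL neutrophil
population, NE2, associated with neutrophil apoptosis). `hemascan`
implements the full analysis chain for such a perturbational screen, plus
a synthetic-data generator with known ground truth so every stage can be
validated without access to any cohort data:

1. **Gating & featurization** — axis-aligned priority gates per channel;
   per gate the event count, in-channel percentage, and robust statistics
   per axis (median; robust s.d. = 1.4826 × MAD; robust CV), plus derived
   count ratios such as NE2/NE4 (evoked over total neutrophils). Trait
   names follow `<CHANNEL>_<Condition>_<Gate>_<Stat>`.
2. **Phenotype QC** — cells beyond 4 MADs of the column median are
   masked; donors whose distance in a 2-D ICA projection of each
   channel × condition block is robustly extreme (2.5 MADs) are removed;
   remaining values are rank-based inverse-normal transformed,
   Φ⁻¹((r − ½)/n). Block-wise PCA counts effective independent traits
   (components to 90% cumulative variance).
3. **Genetic association** — variant QC (missingness > 10%, Wigginton
   exact Hardy–Weinberg p < 10⁻⁵⁰, MAF < 0.05, MAC < 10), KING-robust
   kinship pruning at φ > 0.177, genotype PCs, then per-variant OLS of
   each transformed trait on allele dosage with variance-standardized
   covariates (β, SE, t, two-sided p). Genome-wide-significant hits
   (p < 5 × 10⁻⁸) are greedily LD-clumped (r² > 0.5, < 250 kb) and a
   region is kept only with ≥ 2 distinct supporting traits; the lead
   variant has the smallest p across all traits.
4. **Clinical association** — logistic (Wald z) and linear (t) models of
   diagnoses/labs on each readout with age, race, sex and draw-time
   covariates; Storey q-values (π₀ from a cubic smoother on a λ grid);
   fastICA projection of the signed score matrix into two independent
   components.
5. **PGS & survival** — clumping-and-thresholding polygenic scores
   (clump p1 = 0.5, r² = 0.5, 100 kb; score threshold p < 0.1; additive
   scoring with 2×MAF imputation of missing dosages); EHR outcomes
   encoded as counting-process records with delayed entry, where
   diagnoses within 1 year of the first visit and undated problem-list
   diagnoses become "instant events" in (birth, entry]; Cox
   proportional-hazards fits (Efron ties) on sex + 2 genotype PCs +
   scaled score; left-truncation-aware Kaplan–Meier curves by score
   quartile; REML random-effects meta-analysis across cohorts; CKD
   staging from eGFR bands (45–59 → 3a, 30–44 → 3b, 15–29 → 4, <15 → 5).
6. **Orchestration** — a seeded, manifest-checked pipeline
   (`simulate → gate → qc → scan → clump → clinical → pgs → survive →
   meta → ica`) that reruns byte-identically, with a thin CLI.

## Worked example

`examples/` has one short script per capability. The PGS/survival script
builds a polygenic score from simulated summary statistics, scores two
cohorts, fits delayed-entry Cox models and pools them:

```bash
$ python examples/06_pgs_survival_meta.py
PGS weights retained: 28 variants (clump p1=0.5, r2=0.5, 100 kb; score threshold p<0.1)
encoded records: 2000 (132 instant events), 0 dropped
cohortA: log HR per PGS s.d. = 0.305 +/- 0.060
cohortB: log HR per PGS s.d. = 0.286 +/- 0.059
meta: pooled log HR 0.295 +/- 0.042, tau^2 = 0.0000, p = 2.12e-12
```

The simulation planted a log hazard ratio of 0.3 per score s.d.; both
cohort estimates and the pooled REML estimate recover it within one
standard error, and τ² ≈ 0 because both halves share one data-generating
process. The gating script (`02_gate_and_featurize.py`) likewise prints
`NE2/NE4 = 0.2518 (configured 0.25, 3-sigma band +/- 0.0130)`: the
evoked-neutrophil fraction estimate sits inside the binomial sampling
band of the configured mixture weight.

The end-to-end pipeline runs from a YAML config or library call:

```bash
hemascan run-all --config my_config.yaml --out runs/demo
# or stage by stage: hemascan simulate|gate|qc|scan|clump|clinical|pgs|survive|meta|ica
```

Every stage writes TSV outputs (plus VCF for genotypes and per-sample
CSV event tables) and records SHA-256 checksums in `manifest.json`;
rerunning with the same config and seed reproduces every file byte for
byte.

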