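# Methods

This note documents the models, algorithms and design choices behind
`hemascan`, and what the synthetic-data validation does and does not
establish.

## Synthetic cohort model

The generator produces every input the pipeline consumes, with known
ground truth.

**Genotypes.** Each haplotype is a latent Gaussian AR(1) chain inside LD
blocks: within a block of `ld_block_size` variants, adjacent latent
liabilities correlate at `ld_rho` (default 0.8) and blocks are
independent. Thresholding the liability at Φ⁻¹(1 − f) for a per-variant
alt-allele frequency f (drawn uniformly from `maf_range`, default
0.05–0.5) yields haplotypes whose sum is a diploid dosage in {0, 1, 2}
under Hardy–Weinberg equilibrium. The latent-threshold construction has
closed-form marginals (empirical MAF → f) and monotone LD in `ld_rho`;
genotype-scale correlation is attenuated relative to the latent scale
(ρ = 0.8 gives genotype r² ≈ 0.3), which is sufficient for exercising
clumping and kinship without claiming a specific recombination map.
Positions are cumulative random gaps of 1–9 kb on one chromosome, so a
250 kb clump window spans tens of variants.

**Event clouds.** Each analyzer channel carries a Gaussian-mixture
anchor per gate (mean and diagonal spread in (FSC, SSC, SFL),
per-condition baseline weight). Per donor, gate weights are modulated on
the log scale: each configured causal effect adds
`effect_size × standardized dosage` to its target (condition, gate); a
per-donor "inflammatory tone" latent (standard normal, shifted by
`tone_disease_shift` for diseased donors) loads on every evoked gate
with coefficient `tone_loading`; independent noise with s.d.
`latent_noise_sd` completes the latent trait. Weights are renormalized
and events drawn multinomially, then Gaussian per component, truncated
to the instrument range [0, 2¹⁸) — an 18-bit scale chosen as a
configuration constant, not a claim about any instrument. Event counts
per sample default to 2,000 (10,000 in the featurization benchmarks);
neither is asserted as an instrument property.

**Outcomes.** Disease onset follows Weibull proportional hazards,
S(t) = exp(−(t/scale)^shape · e^η), η = Σ log-HR × latent, with default
shape 5 and scale 80 years. The age-increasing hazard matters: with a
constant (exponential) hazard, lifetime exposure before the first visit
makes the large majority of events prevalent at entry, which is neither
realistic for chronic disease nor compatible with a moderate
instant-event share. Donors enter observation at a first-visit age
independent of onset (uniform 30–60) and are administratively censored
5–25 years later. Onsets before entry surface either as undated
problem-list diagnoses (30%) or as diagnoses recorded within a year of
entry, exercising the instant-event encoding. Continuous labs (eGFR,
HbA1C) are Gaussian with configured means, linked to age, tone and
disease status.

**What the generator does not emulate.** Optical physics and dye
chemistry (gates are well-separated Gaussian anchors, so gate leakage is
negligible by construction); imputation uncertainty; population
structure beyond exchangeable donors; batch effects; informative entry
or censoring. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under a clean generative model,
not robustness to instrument drift or EHR coding noise.

## Gating and featurization

Gates are axis-aligned boxes, lower-inclusive/upper-exclusive so
adjacent boxes tile without double counting, with integer priority ranks
resolving overlaps (lowest rank wins). Hand-drawn polygon gates are an
extension point; boxes are reproducible from plain config and are exact
for the synthetic anchors. Robust statistics use the median, the
Gaussian-consistent robust s.d. 1.4826 × median(|x − median|), and
robust CV = 100 × robust s.d. / median (missing when the median is 0).
Gates with fewer than `min_count` events (default 10) report missing
distributional statistics — medians of near-empty gates are noise — but
keep Count and Pct. The default gate roster (WDF neutrophil/monocyte/
lymphocyte/eosinophil gates incl. the evoked NE2; WNR white-count,
basophil, NRBC and ghost gates; RET red-cell/reticulocyte gates; PLT-F
platelet gates) is illustrative config, and the parameter-schema size is
config-dependent. Event tables are CSV (`FSC,SSC,SFL` columns, one file
per donor × condition × channel); donor identifiers must not contain
underscores since condition names may.

## Phenotype QC

Order is fixed: cell-level MAD filter → sample-level ICA filter →
quantile transform.

* **Univariate filter**: a cell is masked iff |x − median| > k × MAD
  (default k = 4). When MAD = 0 (≥ half the column tied) nothing is
  removed: legitimately discrete traits would otherwise be destroyed.
* **Sample filter**: per fluorophore-channel × condition block, donors
  are projected onto 2 independent components (fastICA, fixed seed;
  PCA fallback for rank-deficient blocks; columns standardized and
  missing values median-imputed for the projection only). A donor is
  removed when its Euclidean distance to the componentwise-median
  sample exceeds median + k × 1.4826 × MAD of the distance distribution
  (default k = 2.5). The threshold is a robust z-score on distances:
  comparing the raw distance to k × MAD alone would remove over half of
  homogeneous Gaussian donors (for Rayleigh-distributed distances,
  2.5 × MAD lies below the median), so the centred, Gaussian-consistent
  form is used.
* **Quantile transform**: rank r of n maps to Φ⁻¹((r − ½)/n), average
  ranks for ties, missing preserved, constant columns to 0 with a
  warning.

The univariate filter is idempotent to well under 0.1% of cells on
stable columns. The sample filter is only approximately idempotent: the
ICA projection refits after removal, so each additional pass trims
another ~1% tail of donors. This is inherent to robust-threshold rules
on continuous data and is why the pipeline applies the filter exactly
once, in the fixed order above.

Independent-trait counting quantile-transforms each mostly-complete
measurement block, median-imputes residual missingness, centres, and
takes the smallest number of principal components reaching 90%
cumulative variance. Blocks are aggregated by their maximum — a
deliberately conservative rule, since blocks share conditions and
structure; the per-block counts are always reported alongside.

## Genetic association

Variant QC thresholds: missingness > 10%, Hardy–Weinberg exact
p < 10⁻⁵⁰ (Wigginton-style exact two-sided test summing heterozygote
configurations no more likely than observed, conditional on allele
counts), MAF < 0.05, MAC < 10. Kinship uses the KING-robust estimator
φ = (N_Aa,Aa − 2 N_AA,aa)/(N_Aa(i) + N_Aa(j)) on hard calls (dosage
thresholds 0.5/1.5); of each pair with φ > 0.177 (first-degree or
closer) the member with higher missingness is removed. Genotype PCs
come from the SVD of centred, frequency-standardized dosages with signs
fixed by the largest-magnitude loading.

The scan is OLS of the transformed trait on dosage plus an intercept
and variance-standardized covariates, computed by Frisch–Waugh–Lovell
residualization: trait and dosages are projected off the covariate
design once (thin QR), reducing each variant to a one-parameter
regression whose β, SE, t and p are algebraically identical to the full
multiple regression. Variants with missing dosages are refit on their
complete rows; collinear covariate columns are dropped with a warning;
p-values are floored at 10⁻³²⁰ against underflow.

Clumping is greedy: the unassigned significant variant with the
smallest p (ties by position) indexes a region; unassigned significant
variants within 250 kb and genotype r² > 0.5 of the index join it;
regions with fewer than two distinct supporting traits are discarded,
and the lead variant is the member with minimum p across all traits.
"Two independent hits from different traits" is read as two distinct
trait names among the members' significant associations; a stricter
variant additionally requiring distinct variants is available as
`require_distinct_variants`. The greedy output is verified against a
naive loop-based oracle on 50-variant instances.

## Clinical association

Binary endpoints: logistic regression (statsmodels GLM, binomial) of
diagnosis on readout + age + race + sex + draw time, Wald z test on the
readout coefficient; race enters as a categorical factor with the
alphabetically first level as reference. Cells with separation,
non-convergence, constant readouts or fewer than 10 cases are flagged
and excluded rather than reported — the case-count floor prevents
separation artifacts. Continuous endpoints use OLS with a t test.

Storey q-values: π₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95 (step
0.05), smoothed by a cubic polynomial and evaluated at λ = 0.95, clamped
to (0, 1]; q is the usual step-up with the π₀ factor, monotone in p.
With π₀ forced to 1 the procedure reproduces Benjamini–Hochberg exactly,
which serves as the oracle; below 20 p-values π₀ estimation is hopeless
and the BH fallback engages with a warning.

The ICA projection treats endpoints as samples of the trait × endpoint
signed score matrix (missing cells zeroed with a recorded mask):
fastICA with the logcosh contrast and fixed seed yields per-endpoint
component coordinates and per-trait mixing loadings; components are
ordered by mixing-column variance and sign-fixed so the
largest-magnitude loading is positive. Restarts with derived seeds
handle non-convergence; near-Gaussian inputs (no column with
significant excess kurtosis) are logged as weakly identifiable since
ICA is only defined up to rotation for Gaussian data.

## Polygenic scores and survival

Scores are clumping + thresholding: summary statistics are clumped on
the reference panel at (p1 = 0.5, r² = 0.5, 100 kb) — reusing the
association clumper with the multi-trait rule disabled — and lead
variants with p < 0.1 keep their per-dose betas, oriented to the effect
allele. Scoring is the additive dosage dot product with missing dosages
imputed to 2 × effect-allele frequency of the scoring cohort; scores
are z-scaled within cohort before model entry.

Survival encoding follows the counting-process convention (start,
stop, event]: normal diagnoses give (entry, diagnosis, 1); censoring
gives (entry, censor, 0); diagnoses within 1 year of entry and undated
problem-list diagnoses become (0, entry, 1) — the subject contributes
risk from birth to entry and the event at entry. This is the simplest
encoding compatible with an event known only to precede the observation
period; records whose stop would not exceed their start are dropped
with a report, and every input row lands in exactly one of output or
report. Cox models (lifelines, Efron ties, delayed entry via the entry
column) use sex, the first two genotype PCs and the scaled score;
Kaplan–Meier curves stratify by score quartile (cohort-specific cut
points at the 0.25/0.5/0.75 quantiles, ties to the lower stratum) with
left-truncation-aware risk sets. The instant-event encoding slightly
misdates pre-entry onsets, which inflates the Cox estimate's dispersion
by ~25% relative to its nominal SE in the recovery benchmark — within
the 3-SE recovery band, but a known approximation.

Meta-analysis: the between-study variance τ² maximizes the restricted
likelihood (scalar bounded optimization, τ² ≥ 0, with an explicit check
of the τ² = 0 boundary); the pooled estimate is inverse-variance
weighted with weights 1/(SE² + τ²). The implementation matches
`metafor::rma(method = "REML")` to ~10⁻⁵ on fixture data. CKD stages
use eGFR bands 45–59 (3a), 30–44 (3b), 15–29 (4), <15 (5), inclusive at
each band's lower edge; the prediabetes/diabetes subset for CKD
progression is the HbA1C > 5.7 row filter.

## Orchestration and reproducibility

One global seed fans out to per-stage child seeds via
blake2b("seed:stage") mod 2³¹, so a stage's draws are independent of
stage order. Each stage writes TSVs with a fixed float format and
records SHA-256 checksums in the manifest, which suffices to detect any
modified intermediate; reruns with identical config and seed are
byte-identical. The demo configuration (200 donors, 500 variants,
3 conditions, 2,000 events/sample) runs end-to-end in well under a
minute per pass on one CPU; benchmark sizes elsewhere (2,000 × 5,000
null scan, n = 5,000 survival recovery, 200-repeat featurization
coverage) were chosen to make the sampling bounds sharp at desk scale.

## Validation benchmarks

`hemascan.validation` regenerates inputs from a seed and measures:
NE2/NE4 coverage of the 3σ binomial band (w ∈ {0.05, 0.25, 0.5},
10,000 neutrophil events, 200 repeats); planted-outlier recovery of the
4-MAD filter (20 cells displaced 10 MADs among 10,000 clean cells —
clean cells are bounded uniform noise, since any filter at 4 MADs has an
irreducible ~0.7% false-positive rate on unbounded Gaussian columns and
planted-outlier recovery is only well-posed for bounded noise); ICA
sample-filter detection of a donor displaced 20 column-s.d.; null-scan
type-I calibration and injected-effect power (the 0.5 s.d./allele
effect is compared on the rank-normalized scale, where it becomes
β/√(β²·2f(1−f)+1)); oracle equivalences (scan vs closed-form least
squares, q-values vs BH, delayed-entry vs standard Cox at zero entries,
scoring vs dot product, HWE vs exhaustive enumeration); delayed-entry
Cox recovery of log HR 0.3 at n = 5,000 with ~20% instant events; KING
calibration on duplicates and unrelateds; REML pooling of identical and
heterogeneous studies; and byte-identity of the demo pipeline rerun.
`scripts/acceptance.py` writes all of these to JSON.

## Known limitations

* Gate geometry is boxes, not polygons; real gate shapes from manual
  gating software are out of scope.
* FCS files are not read or written; event tables are CSV.
* The sample-level outlier filter is approximately idempotent only (see
  above).
* The instant-event Cox encoding is an approximation whose bias grows
  with the prevalent-case share; it is validated at ~20% instant
  events.
* No mixed-model or genomic-control correction in the scan; population
  structure is handled by PC covariates only, matching plain linear
  regression practice.
* The synthetic generator's clean separability means featurization
  benchmarks bound sampling error, not gating mis-specification.
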