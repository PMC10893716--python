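# Methods note

This note specifies the statistical procedures implemented in `hpameth`,
the parameter defaults with their rationale, what the synthetic-cohort
simulator does and does not emulate, and the open design decisions taken
where the procedure description leaves room.

## 1. Data model and scales

- **Beta value** β ∈ [0,1]: proportion methylated at a CpG. Used for QC,
  normalization and descriptive effect sizes (absolute group difference in
  mean beta).
- **M value** M = log₂(β/(1−β)): the modelling scale, on which linear
  models are closer to homoscedastic. β is clipped to [ε, 1−ε] with
  ε = 10⁻⁶ before the transform; `m_to_beta` uses the numerically stable
  form ½(1 + tanh(½·ln2·M)) and is the exact inverse for unclipped values.
- `MethylationMatrix` (probes × samples, optional detection p-values),
  `SampleTable` (group, covariates, `outcome_*` scores; patient-only
  fields are enforced missing for controls), `ProbeAnnotation` (1-based
  position, gene, gene section, SNP flag, control-probe designation).
  BED input (0-based, half-open) is converted to 1-based on read.

## 2. Quality control

**Samples.** A sample passes when its beta distribution is bimodal,
operationalised as: fraction of betas in the open mid band (0.3, 0.7) must
not exceed `midband_threshold = 0.4`. A well-hybridised array concentrates
mass near 0 and 1; degraded or failed samples flatten toward the middle.
The threshold sits far from both failure modes: clean bimodal samples have
mid-band fractions well under 0.2, fully degraded ones well over 0.6, so
the decision is insensitive to the exact cut. An externally supplied set
of insufficient-DNA-yield samples is merged into the same report (reason
`insufficient_yield`).

**Probes.** A probe is removed when its detection p-value exceeds
`p_thresh = 0.01` in at least `frac = 0.5` of samples (boundary
inclusive), or when its SNP flag is set. Probe filtering is idempotent.

**Normalization.** Quantile normalization forces every sample onto the
across-sample mean quantile vector, with tie averaging within a sample.
It assumes identical marginal distributions across samples — reasonable
genome-wide, increasingly wrong for small targeted panels, where strong
group effects at a few probes can leak rank shifts into other probes (see
§8 Limitations). It can be disabled (`normalize: false`).

**Age at exposure.** For controls (never admitted), age at exposure is
imputed as follow-up age minus two years; a negative result is an error
naming the sample.

## 3. Control-probe batch adjustment

Technical control probes (hybridisation, staining, conversion controls)
measure array performance, not biology. Following the control-probe PCA
approach, the probe-wise-centred matrix of control-probe betas (negative
controls excluded — they carry background, not batch) is decomposed by
SVD; the leading `n_pcs = 30` sample-score vectors become technical
covariates. Signs are fixed deterministically (non-negative loading sum)
so results do not depend on the SVD implementation. The number of PCs is
bounded by min(#control probes, #samples − 1), with a warning when the
request exceeds the rank. At desk scale only `n_pcs_model = 5` PCs enter
the models, keeping fold-level refits estimable; the simulator's batch
structure has rank 2, so 5 is already generous.

Perfect confounding caveat: when group and batch-factor space are nearly
collinear (few batches, low-rank structure), conditioning on the PCs
inflates rather than removes the group coefficient's error; the bias-
reduction guarantee applies when batches vary within groups.

## 4. DMP discovery

Per CpG, ordinary least squares of M on intercept + group contrast +
covariates (categoricals dummy-encoded dropping the first level; designs
are checked for rank, with aliased columns named in the error).
Empirical-Bayes moderation shrinks residual variances s² toward a scaled
inverse-chi-square prior (d₀, s₀²) fitted by moments of log s² using
digamma/trigamma identities and a Newton trigamma-inverse; posterior
variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) give moderated t statistics on
d₀ + d degrees of freedom and confidence intervals at `ci_level = 0.95`.
The limits d₀ = 0 (ordinary t) and d₀ = ∞ (full shrinkage) are exposed for
testing (`force_df_prior`). The implementation is verified against
Bioconductor limma on shared data (t, p, d₀, s₀² to ≤ 10⁻⁴ relative).

Multiple testing uses the Benjamini–Hochberg step-up procedure
(`fdr = 0.05`), tested against a brute-force oracle.

**Interaction scans** add group × sex and group × age terms one at a time
and report the interaction p-value per CpG. **Glucocorticoid subgroup
contrast**: within patients only, treated vs untreated, adjusting for the
baseline covariates plus illness-severity variables; requires both arms
present.

## 5. DMR detection

Squared per-CpG t statistics are smoothed along each chromosome with a
Gaussian kernel, σ = λ/C with λ = 1000 bp and C = 2 (the conventional
bandwidth pairing for this method family): S_i = Σ_j w_ij t_j² / Σ_j w_ij.
Each S_i is approximated as a scaled chi-square with Satterthwaite
effective degrees of freedom ν_i = (Σw)²/Σw² — exact for equal weights on
independent unit-df inputs — giving p = P(χ²_ν ≥ S·ν). After BH
adjustment across all CpGs, maximal runs of significant CpGs whose
consecutive gaps are ≤ λ become regions; regions with fewer than
`min_cpgs = 2` members are dropped. Reported per region: 1-based closed
coordinates (width = end − start + 1), member probes, minimum member q
(the most conservative single-number summary available per region),
direction (Hypo/Hyper when all member effects share a sign, else Mixed),
and mean M-scale effect.

Known behaviour: a very strong single-CpG effect inside a dense locus
spreads through the kernel and flags its neighbourhood (often labelled
Mixed); this mirrors the reference method and is demonstrated in
`examples/07_full_pipeline.py`. Smoothed statistics of neighbouring CpGs
are correlated, so the BH guarantee is per-CpG, not per-region.

## 6. Outcome association and robustness

Within patients with a non-missing outcome, OLS of outcome on intercept +
covariates + methylation (M scale). Robustness: `n_iterations = 100`
random partitions into `k_folds = 10` disjoint folds; per fold the model
is refitted on the fold's samples alone (`per_fold_refit`, the default, so
the k p-values come from disjoint subsamples and are independent, as
Fisher's method requires); the k fold p-values are combined by
−2Σln p ~ χ²₂ₖ, and the iteration is significant when the combined
p ≤ α = 0.05. The robustness score is the percentage of significant
iterations; 100% is labelled robust. An alternative mode
(`train_test_predict`) fits on k−1 folds and tests the held-out
association; its fold p-values are not strictly independent, which is why
it is not the default.

Degenerate-fold rules (conservative by construction): a fold in which the
methylation regressor is constant, or whose design is rank deficient by
chance collinearity, identifies nothing about the coefficient and
contributes p = 1; adjustment covariates constant within a fold are
dropped for that fold. Every stream is seeded; per-pair substreams are
derived with CRC32 of "probe|outcome", so batch evaluation order is
irrelevant and results are bit-reproducible.

**B/H labels**: the outcome shift predicted in the direction of the
patients' abnormal methylation is −coef for hypomethylation and +coef for
hypermethylation; B when that shift improves the score under the outcome's
declared polarity (`higher_is_better`), H otherwise; `none` when the
full-data p exceeds α.

## 7. Synthetic cohort simulator

What it emulates:

- Bimodal baselines: per-probe baseline M drawn from a three-part mixture
  (modes near β ≈ 0.1 and 0.9, plus a minority of intermediate probes).
- Group effects: additive on the M scale, sized per probe so the realised
  group difference in mean beta matches the requested Δβ (valid range
  0 < Δβ < 0.5); coherent clustered effects can be planted as regions
  (members relocated to one tight locus).
- Batch: rank-`n_latent = 2` latent factors per batch
  (`batch_sd = 0.5` M-scale), with loadings shared between biological and
  control probes — the mechanism that makes control-probe PCA work.
  Optionally confounded with group (patients concentrated in the first
  half of the batches).
- Residual noise: per-probe SDs drawn around `sigma_m = 0.4`
  (inverse-chi-square spread, `sigma_df = 10`). 0.4 reflects a typical
  M-scale SD for mid-range probes and gives Δβ = 0.05 spikes detection
  power ≈ 0.8–0.97 at desk scale — large enough to be findable, small
  enough that recovery tests are non-trivial.
- Covariate marginals resembling a PICU follow-up cohort (≈58% male
  patients, ≈54% male controls, severity scores for patients only,
  glucocorticoid-treated subgroup fraction 0.25).
- Detection p-values (clean probes ~U(0, 0.005); designated failing
  probes fail detection in 60% of samples), outcome scores causally
  linked to chosen CpGs with specified coefficient and noise.
- Ground truth is returned (`TruthTable`) for recovery testing.

What it does not emulate: realistic genome-wide probe density, SNP and
haplotype structure, probe-type (Infinium I/II) chemistry differences,
cell-type composition, longitudinal sampling.

Desk-scale defaults (120 patients / 60 controls, 3,000 + 300 probes, 4
batches) keep every stage testable in seconds; a full-scale cohort is a
matter of changing three numbers.

The 821-sample QC fixture (`make_qc_fixture`) contains 818 clean bimodal
samples, two samples drawn uniform(0.3, 0.7) (guaranteed to fail the
mid-band rule) and one flagged insufficient-yield sample; the pass count
818 is a structural property, independent of the seed used to draw the
betas.

## 8. Numerical and design choices

- All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; per-pair CV substreams use CRC32 (process-stable),
  never Python's salted `hash()`.
- OLS via solves/`lstsq` with explicit rank checks; probe-wise models are
  vectorised (single solve + einsum residual sums) rather than looped.
- Trigamma inverse by Newton iteration on 1/trigamma (monotone,
  convex-adjusted step), with closed-form asymptotes at both extremes.
- Fisher's method clips exact-zero p-values to the smallest positive
  float (logged) rather than returning 0/−∞.
- `summarize_dmps` rounds percentages to one decimal, matching the
  reporting convention of the summary statistics it reproduces.
- Pipeline outputs are plain headered TSV plus a JSON summary; the
  pipeline config is one YAML-serialisable object whose SHA-256 digest is
  logged for provenance, and unknown config keys are rejected.

## 9. Limitations

- The mid-band bimodality rule is a simple operationalisation; array-
  specific QC (control-probe dashboards, sex checks) is out of scope.
- Quantile normalization over a small targeted panel can propagate strong
  localised effects into other probes' normalized values; with ~10³
  probes the distortion is visible in simulations, so `normalize: false`
  is advisable for very small panels.
- Control-probe PCA cannot separate batch from group under (near-)perfect
  confounding with low-rank batch structure.
- Region-level inference is descriptive: the FDR guarantee is per-CpG,
  and smoothing correlates neighbouring statistics.
- CV fold p-values in `per_fold_refit` are independent given the
  partition, but iterations reuse the same data, so iteration counts for
  one pair are dependent; the robustness percentage is a stability
  heuristic, not a calibrated probability.
- Problem sizes exercised in tests: up to 2,000 probes × 180 samples
  (calibration), 1,000 × 180 (recovery), 20 seeded replicates for region
  recovery; the full suite runs in ~10 s, the acceptance script in ~1 s.
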