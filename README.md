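# hpameth

Targeted DNA-methylation analysis of hypothalamus–pituitary–adrenal (HPA)
axis genes in former paediatric-intensive-care (PICU) patients versus
healthy children: quality control, control-probe batch adjustment,
moderated-model discovery of differentially methylated positions (DMPs)
with false-discovery-rate control, kernel-smoothed detection of
differentially methylated regions (DMRs), interaction and
glucocorticoid-subgroup contrasts, and a repeated cross-validation +
Fisher's-method robustness assessment of methylation–outcome associations.

Because the original cohort data are not publicly deposited, the package
ships two substitutes:

- a **synthetic-cohort simulator** that emulates an EPIC-like two-group
  cohort — bimodal beta values, plate/chip batch effects expressed in
  technical control probes, realistic covariate marginals, spiked group
  effects of chosen magnitude Δβ, clustered effects forming regions, and
  outcome scores causally linked to methylation at chosen CpGs — so every
  stage can be validated against known ground truth;
- a **packaged reference table** of 26 differentially methylated CpGs in
  11 HPA-axis genes (with effect sizes, confidence intervals, interaction
  and glucocorticoid p-values) whose study-level summary statistics the
  package reproduces exactly.

## The model, briefly

Beta values β ∈ [0,1] (proportion methylated) are modelled on the M scale,
M = log₂(β/(1−β)). For each CpG *j* a linear model

  M_j = α_j + γ_j·group + covariates + technical PCs + ε_j

is fitted; residual variances are shrunk toward a common prior with a
limma-style empirical-Bayes scheme (the prior degrees of freedom d₀ and
prior variance s₀² are estimated from the variance distribution by
moments), giving moderated t statistics with d₀ + d degrees of freedom.
P-values are Benjamini–Hochberg adjusted. Technical PCs are the leading
principal components of the (probe-centred) control-probe betas — control
probes measure array performance, not biology, so their PCs proxy batch.

Regions are found by smoothing squared t statistics along the genome with
a Gaussian kernel (σ = λ/C, defaults λ = 1000 bp, C = 2), converting each
smoothed value to a p-value with a Satterthwaite scaled-chi-square
approximation, BH-adjusting, and joining runs of significant CpGs whose
gaps are at most λ.

Methylation–outcome association in patients uses a multivariable linear
model per (CpG, outcome) pair, and its robustness is the percentage of
repeated 10-fold cross-validation iterations (100 by default) in which the
k per-fold p-values, combined by Fisher's method (−2Σln p ~ χ² with 2k
degrees of freedom), stay below α. Significant pairs get a **B**
(benefit) or **H** (harm) label from the direction of the patients'
methylation abnormality, the sign of the coefficient, and the outcome's
polarity.

## Worked example

Spike two CpGs with a group effect of Δβ = 0.05 in a simulated cohort of
120 patients and 60 controls, then recover them (`examples/03_dmp_discovery.py`):

```python
from hpameth.dmp import (DesignSpec, abs_mean_beta_diff, bh_adjust,
                         empirical_bayes_moderate, fit_probewise_models)
from hpameth.io import SampleTable
from hpameth.qc import beta_to_m
from hpameth.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_patients=120, n_controls=60, n_probes=500, n_control_probes=50,
    spike_table=[(25, 0.05, -1), (250, 0.05, 1)],   # (probe, delta-beta, sign)
    seed=3,
)
matrix, samples, annotation, truth = simulate_cohort(config)

m_values = beta_to_m(matrix.subset_probes(annotation.biological_probes()).beta)
df = samples.df.copy()
df["group_patient"] = (df["group"] == "patient").astype(float)
design = DesignSpec(contrast="group_patient", covariates=["sex", "age_exposure"])
fit = empirical_bayes_moderate(fit_probewise_models(m_values, SampleTable(df), design))
q = bh_adjust(fit.p)
```

Running the script prints:

```
empirical Bayes prior: d0 = 3.7, s0^2 = 0.655

2 DMPs at FDR <= 0.05:
            logfc_m  ci_low  ci_high  abs_mean_diff       q
probe_id
cg00000250   1.1828  0.9229   1.4428         0.0616  0.0000
cg00000025  -0.7063 -0.9784  -0.4342         0.0577  0.0002

truly spiked probes: ['cg00000025', 'cg00000250']
```

Summarizing the packaged 26-row reference table
(`examples/06_fixture_summary.py`) prints:

```
26 DMPs across 11 genes; 76.9% hypomethylated in patients
absolute group difference in mean beta: mean 2.2%, SD 1.5%, max 5.5%
FKBP5: 7 DMPs = 13.7% of its 51 selected CpGs
interaction rows at p <= 0.05: age 4, sex 0
rows associated with glucocorticoid treatment: 5 (of which 3 in FKBP5)
```

The other scripts in `examples/` cover QC (`01`), batch adjustment (`02`),
DMR detection (`04`), outcome robustness (`05`), and the full end-to-end
pipeline with its TSV report bundle (`07`).

## Command line

A thin CLI wraps the library (no analysis logic of its own):

```bash
hpameth simulate --config sim.yaml --seed 5 --out-dir sim
hpameth qc --beta sim/beta.tsv --detection sim/detection_p.tsv \
           --sheet sim/samples.tsv --annotation sim/annotation.tsv --out-dir qc
hpameth adjust --beta qc/beta_filtered.tsv --annotation sim/annotation.tsv --out pcs.tsv
hpameth dmr --stats stats.tsv --out dmrs.tsv
hpameth associate --m-matrix m.tsv --sheet sheet.tsv --dmps dmps.tsv \
                  --outcomes iq --out-dir assoc
hpameth run-all --seed 9 --out-dir report     # everything, one command
```

## Repository layout

```
src/hpameth/        io, qc, batch, dmp, dmr, outcomes, simulate, report, cli
src/hpameth/data/   packaged 26-row DMP reference table (TSV)
examples/           short narrative scripts, one per capability
tests/              unit, property and acceptance tests (pytest + hypothesis)
scripts/            acceptance.py (recomputes the acceptance target)
docs/methods.md     methods note: models, parameters, assumptions, limitations
```

See `docs/methods.md` for the full statistical specification, every
parameter default with its rationale, what the simulator does and does not
emulate, and known limitations.
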