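"""Simulate a small methylation cohort and run sample/probe QC.

The simulator produces an EPIC-like two-group cohort: bimodal beta values,
plate/chip batch effects expressed in technical control probes, and
Table-1-like covariates.  QC drops samples whose beta distribution is not
bimodal (too much mass in the 0.3-0.7 mid band) and probes that fail
detection in at least half the samples or carry a SNP flag.
"""

from hpameth.qc import probe_filter, sample_qc
from hpameth.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_patients=120,
    n_controls=60,
    n_probes=1000,
    n_control_probes=100,
    n_failing_probes=8,  # probes with failed detection in most samples
    seed=1,
)
matrix, samples, annotation, truth = simulate_cohort(config)
print(f"simulated {matrix.shape[0]} probes x {matrix.shape[1]} samples")

sample_report = sample_qc(matrix)
print(f"sample QC: {sample_report.n_samples_pass}/{len(sample_report.samples)} pass")

filtered, probe_report = probe_filter(matrix, annotation)
n_fail = (~probe_report.probes["passed"]).sum()
print(f"probe QC: removed {n_fail} probes "
      f"({probe_report.probes.loc[~probe_report.probes['passed'], 'reason'].value_counts().to_dict()})")
print(f"matrix after QC: {filtered.shape[0]} probes x {filtered.shape[1]} samples")
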