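"""End-to-end pipeline orchestration and cohort-description tables.

``run_pipeline`` composes the stages in analysis order — simulate (or load)
-> sample/probe QC -> normalization -> control-probe PCs -> moderated DMP
models with FDR -> interaction and glucocorticoid contrasts -> kernel-
smoothed DMRs -> cross-validated outcome-association robustness — and
writes every stage output as headered TSV with seed and parameter
provenance logged.  ``cohort_compare`` produces the demographics table
(medians/IQR, counts/%, chi-square p for categoricals, rank-sum p for
continuous variables).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import batch, dmp, dmr, outcomes, qc, simulate
from .io import SampleTable, write_beta_matrix, write_probe_annotation, write_sample_sheet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "cohort_compare", "run_pipeline"]

#: baseline risk factors adjusted for in the group-contrast models
BASELINE_COVARIATES = [
    "age_exposure",
    "centre",
    "race",
    "sex",
    "geographic_origin",
    "malignancy",
    "syndrome",
]

#: additions for the glucocorticoid-subgroup contrast (within patients)
GC_EXTRA_COVARIATES = [
    "los_picu",
    "diagnosis_category",
    "pim3",
    "pelod",
    "randomisation_arm",
    "strongkids",
]


@dataclass
class PipelineConfig:
    """Every stage parameter in one serializable object.

    Unknown keys are rejected on load so typos never silently fall back to
    defaults.
    """

    seed: int = 0
    # simulation (used when no input paths are given)
    simulation: dict = field(default_factory=dict)
    # QC
    midband_threshold: float = 0.4
    detection_p: float = 0.01
    detection_frac: float = 0.5
    normalize: bool = True
    # batch adjustment
    n_pcs: int = 30
    n_pcs_model: int = 5  # PCs entering the models (desk-scale estimability)
    # DMP / DMR
    fdr: float = 0.05
    dmr_lambda: float = 1000.0
    dmr_scaling: float = 2.0
    dmr_min_cpgs: int = 2
    # outcome association
    cv_k_folds: int = 10
    cv_iterations: int = 100
    cv_alpha: float = 0.05
    cv_covariates: list = field(default_factory=lambda: ["age_exposure", "sex"])
    run_association: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cohort description


def cohort_compare(
    sample_table: SampleTable,
    group_col: str = "group",
    categorical=None,
    continuous=None,
) -> pd.DataFrame:
    """Demographics comparison of the two groups.

    Categorical variables: counts (%) per level and a chi-square test
    without continuity correction.  Continuous variables: median (IQR) and
    an unpaired rank-sum (Mann-Whitney) p-value.
    """
    df = sample_table.df
    groups = df[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    g1, g2 = sorted(groups)
    d1, d2 = df[df[group_col] == g1], df[df[group_col] == g2]
    if len(d1) == 0 or len(d2) == 0:
        raise ValueError("a comparison group is empty")

    if categorical is None:
        categorical = [
            c
            for c in df.columns
            if c != group_col and (df[c].dtype == object or df[c].dtype == bool) and df[c].notna().all()
        ]
    if continuous is None:
        continuous = [
            c
            for c in df.columns
            if c != group_col
            and np.issubdtype(df[c].dtype, np.number)
            and df[c].notna().all()
            and not c.startswith("pc")
        ]

    rows = []
    for col in categorical:
        tab = pd.crosstab(df[col], df[group_col])
        if tab.shape[0] < 2:
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        for level in tab.index:
            n1 = int(tab.loc[level, g1]) if g1 in tab.columns else 0
            n2 = int(tab.loc[level, g2]) if g2 in tab.columns else 0
            rows.append(
                {
                    "variable": col,
                    "level": str(level),
                    g1: f"{n1} ({100 * n1 / len(d1):.1f})",
                    g2: f"{n2} ({100 * n2 / len(d2):.1f})",
                    "p": p,
                    "test": "chi-square",
                }
            )
    for col in continuous:
        x1, x2 = d1[col].to_numpy(dtype=float), d2[col].to_numpy(dtype=float)
        p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)

        def _miqr(x):
            q1, q2, q3 = np.percentile(x, [25, 50, 75])
            return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"

        rows.append(
            {
                "variable": col,
                "level": "median (IQR)",
                g1: _miqr(x1),
                g2: _miqr(x2),
                "p": p,
                "test": "rank-sum",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: PipelineConfig, out_dir, inputs: tuple | None = None) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    ``inputs`` may supply (MethylationMatrix, SampleTable, ProbeAnnotation);
    otherwise a cohort is simulated from ``config.simulation`` (seeded by
    ``config.seed``).  Returns a dict of in-memory artifacts; all outputs
    are also written as TSV.  A stage failure aborts with the failing stage
    named; artifacts from completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    logger.info(
        "pipeline start: seed=%d config=%s numpy=%s pandas=%s",
        config.seed,
        config.digest(),
        np.__version__,
        pd.__version__,
    )
    config.to_yaml(out / "config.yaml")
    artifacts: dict = {}
    stage = "simulate"
    try:
        if inputs is None:
            sim_cfg = simulate.SimulationConfig(**{**config.simulation, "seed": config.seed})
            matrix, table, annotation, truth = simulate.simulate_cohort(sim_cfg)
            artifacts["truth"] = truth
            write_beta_matrix(matrix, out / "beta.tsv")
            write_sample_sheet(table, out / "samples.tsv")
            write_probe_annotation(annotation, out / "annotation.tsv")
        else:
            matrix, table, annotation = inputs

        stage = "qc"
        table = qc.impute_age_at_exposure(table)
        sqc = qc.sample_qc(matrix, config.midband_threshold)
        keep = sqc.samples.index[sqc.samples["passed"]].tolist()
        matrix = matrix.subset_samples(keep)
        table = SampleTable(table.df.loc[keep], dict(table.outcome_polarity))
        matrix, pqc = qc.probe_filter(matrix, annotation, config.detection_p, config.detection_frac)
        sqc.samples.to_csv(out / "qc_samples.tsv", sep="\t")
        pqc.probes.to_csv(out / "qc_probes.tsv", sep="\t")
        artifacts["qc"] = (sqc, pqc)
        if config.normalize:
            matrix = qc.quantile_normalize(matrix)

        stage = "batch_adjust"
        pcs = batch.control_probe_pcs(matrix, annotation, n_pcs=config.n_pcs)
        pcs.scores.to_csv(out / "control_pcs.tsv", sep="\t", index_label="sample_id")
        model_pcs = batch.ControlPcs(
            pcs.scores.iloc[:, : config.n_pcs_model],
            pcs.explained_variance[: config.n_pcs_model],
        )
        table = batch.attach_technical_covariates(table, model_pcs)
        artifacts["pcs"] = pcs

        stage = "dmp"
        bio = [p for p in annotation.biological_probes() if p in set(matrix.probe_ids)]
        bio_matrix = matrix.subset_probes(bio)
        m_vals = qc.beta_to_m(bio_matrix.beta)
        covars = [c for c in BASELINE_COVARIATES if table.df[c].nunique() > 1]
        covars += list(model_pcs.scores.columns[: config.n_pcs_model])
        design = dmp.DesignSpec(contrast="group_patient", covariates=covars)
        tdf = table.df.copy()
        tdf["group_patient"] = (tdf["group"] == "patient").astype(float)
        work = SampleTable(tdf, dict(table.outcome_polarity))
        fit = dmp.fit_probewise_models(m_vals, work, design)
        fit = dmp.empirical_bayes_moderate(fit)
        qvals = dmp.bh_adjust(fit.p)
        absdiff = dmp.abs_mean_beta_diff(bio_matrix.beta, table.df["group"])
        dmp_table = pd.DataFrame(
            {
                "gene": annotation.df.loc[bio, "genes"].to_numpy(),
                "probe_id": bio,
                "gene_section": annotation.df.loc[bio, "gene_section"].to_numpy(),
                "status": np.where(fit.coef < 0, "Hypo", "Hyper"),
                "logfc_m": fit.coef,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "abs_mean_diff": absdiff.reindex(bio).to_numpy(),
                "p_group": fit.p,
                "q_group": qvals,
            },
            index=pd.Index(bio),
        )
        dmps = dmp_table[dmp_table["q_group"] <= config.fdr].copy()
        logger.info("dmp stage: %d/%d probes significant at FDR %.2f", len(dmps), len(bio), config.fdr)

        stage = "interaction"
        if len(dmps) >= 2:
            sub_m = m_vals.loc[dmps.index]
            dmps["p_int_sex"] = dmp.interaction_scan(sub_m, work, design, "sex")
            dmps["p_int_age"] = dmp.interaction_scan(sub_m, work, design, "age_exposure")
            stage = "gc_contrast"
            gc_covars = [
                c
                for c in BASELINE_COVARIATES + GC_EXTRA_COVARIATES
                if work.patients()[c].nunique() > 1
            ] + list(model_pcs.scores.columns[: config.n_pcs_model])
            gc_design = dmp.DesignSpec(contrast="gc_treated", covariates=gc_covars)
            gc_res = dmp.gc_subgroup_contrast(sub_m, work, gc_design)
            dmps["p_gc"] = gc_res["p_gc"]
        dmps.to_csv(out / "dmps.tsv", sep="\t", index=False)
        artifacts["dmps"] = dmps

        stage = "dmr"
        stats_df = pd.DataFrame(
            {
                "chrom": annotation.df.loc[bio, "chrom"],
                "pos": annotation.df.loc[bio, "pos"].astype(int),
                "t": fit.t,
                "logfc_m": fit.coef,
            },
            index=pd.Index(bio, name="probe_id"),
        )
        params = dmr.SmoothingParams(config.dmr_lambda, config.dmr_scaling)
        dmrs = dmr.find_dmrs(stats_df, params, fdr=config.fdr, min_cpgs=config.dmr_min_cpgs)
        dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
        artifacts["dmrs"] = dmrs

        stage = "outcome_association"
        outcome_names = table.outcome_names
        if config.run_association and outcome_names and len(dmps) > 0:
            cvc = outcomes.CvConfig(
                k_folds=config.cv_k_folds,
                n_iterations=config.cv_iterations,
                alpha=config.cv_alpha,
                seed=config.seed,
            )
            results = []
            for probe in dmps.index:
                for name in outcome_names:
                    r = outcomes.cv_robustness(
                        name, m_vals.loc[probe], table, config.cv_covariates, cvc
                    )
                    r.label = outcomes.label_direction(
                        r,
                        str(dmps.loc[probe, "status"]),
                        table.outcome_polarity.get(name, True),
                        alpha=config.cv_alpha,
                    )
                    results.append(r)
            pct, labels, counts = outcomes.robustness_matrix(results)
            pct.to_csv(out / "robustness_pct.tsv", sep="\t", index_label="probe_id")
            labels.to_csv(out / "robustness_labels.tsv", sep="\t", index_label="probe_id")
            artifacts["robustness"] = (pct, labels, counts)
        else:
            counts = {"n_pairs": 0, "n_significant": 0, "n_robust": 0, "pct_robust_of_significant": None}

        stage = "report"
        summary = {
            "seed": config.seed,
            "config_digest": config.digest(),
            "samples_pass": sqc.n_samples_pass,
            "probes_pass": pqc.n_probes_pass,
            "n_dmps": int(len(dmps)),
            "n_dmrs": int(len(dmrs)),
            "association_counts": counts,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        cohort = cohort_compare(
            table,
            categorical=["sex"],
            continuous=["age_followup"],
        )
        cohort.to_csv(out / "cohort_table.tsv", sep="\t", index=False)
        artifacts["summary"] = summary
        return artifacts
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
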