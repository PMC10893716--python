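"""Sample and probe quality control, normalization and scale transforms.

Samples are excluded when their beta-value distribution is not the typical
bi-peak curve (operationalised as a mid-band-fraction rule: a clean buccal
sample has most betas near 0 or 1, so a large fraction inside (0.3, 0.7)
indicates a degraded sample) or when DNA yield was insufficient.  Probes are
excluded when the detection p-value exceeds 0.01 in at least half of the
samples, or when they span a SNP.

Analysis happens on the M scale (logit2 of beta); both directions of the
transform live here, together with quantile normalization and the
age-at-exposure imputation for healthy controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ProbeAnnotation, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "sample_qc",
    "probe_filter",
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "impute_age_at_exposure",
]

M_EPS = 1e-6  # clip bound for the logit2 transform; bounds |M| at ~19.9


@dataclass
class QcReport:
    """Pass/fail decisions with reasons, one row per sample and per probe.

    Sample failure reasons: ``insufficient_yield``, ``non_bimodal``.
    Probe failure reasons: ``detection_p``, ``snp``.
    """

    samples: pd.DataFrame  # index sample_id; columns: passed, reason
    probes: pd.DataFrame | None = None  # index probe_id; columns: passed, reason

    @property
    def n_samples_pass(self) -> int:
        return int(self.samples["passed"].sum())

    @property
    def n_probes_pass(self) -> int:
        return 0 if self.probes is None else int(self.probes["passed"].sum())

    def summary(self) -> dict:
        out = {
            "samples_total": len(self.samples),
            "samples_pass": self.n_samples_pass,
            "samples_fail_by_reason": self.samples.loc[~self.samples["passed"], "reason"]
            .value_counts()
            .to_dict(),
        }
        if self.probes is not None:
            out["probes_total"] = len(self.probes)
            out["probes_pass"] = self.n_probes_pass
            out["probes_fail_by_reason"] = (
                self.probes.loc[~self.probes["passed"], "reason"].value_counts().to_dict()
            )
        return out


def sample_qc(
    matrix: MethylationMatrix,
    midband_threshold: float = 0.4,
    insufficient_yield: set | None = None,
) -> QcReport:
    """Flag samples whose beta distribution lacks the typical bi-peak shape.

    A sample fails when the fraction of its (non-missing) beta values inside
    the open interval (0.3, 0.7) exceeds ``midband_threshold``.  Externally
    known insufficient-DNA-yield samples are merged into the report and take
    precedence as the failure reason.  Decisions do not depend on sample or
    probe order.
    """
    if matrix.beta.size == 0:
        raise ValueError("sample_qc: empty methylation matrix")
    insufficient_yield = set(insufficient_yield or ())
    vals = matrix.beta.to_numpy(dtype=float)
    inside = (vals > 0.3) & (vals < 0.7)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    frac = np.where(n_obs > 0, inside.sum(axis=0) / np.maximum(n_obs, 1), np.nan)

    rows = []
    for j, sid in enumerate(matrix.sample_ids):
        if sid in insufficient_yield:
            rows.append((sid, False, "insufficient_yield"))
        elif n_obs[j] == 0:
            logger.warning("sample %s has no observed beta values; failed as non_bimodal", sid)
            rows.append((sid, False, "non_bimodal"))
        elif frac[j] > midband_threshold:
            rows.append((sid, False, "non_bimodal"))
        else:
            rows.append((sid, True, ""))
    df = pd.DataFrame(rows, columns=["sample_id", "passed", "reason"]).set_index("sample_id")
    return QcReport(samples=df)


def probe_filter(
    matrix: MethylationMatrix,
    annotation: ProbeAnnotation,
    p_thresh: float = 0.01,
    frac: float = 0.5,
) -> tuple[MethylationMatrix, QcReport]:
    """Remove probes failing detection in >= ``frac`` of samples or spanning
    a SNP; returns the filtered matrix and the per-probe report.

    The sample-fraction rule is inclusive (>=): a probe undetected in exactly
    half of the samples is removed.  Control probes are exempt from the SNP
    rule (their flag is ignored on read) but not from the detection rule.
    """
    missing = set(matrix.probe_ids) - set(annotation.probe_ids)
    if missing:
        raise ValueError(f"annotation missing {len(missing)} matrix probes, e.g. {sorted(missing)[:3]}")
    n = len(matrix.sample_ids)
    snp = annotation.df.reindex(matrix.probe_ids)["snp_flag"].to_numpy(dtype=bool)
    if matrix.detection_p is not None:
        dp = matrix.detection_p.to_numpy(dtype=float)
        fail_frac = np.nansum(dp > p_thresh, axis=1) / n
        det_fail = fail_frac >= frac
    else:
        det_fail = np.zeros(len(matrix.probe_ids), dtype=bool)

    reason = np.where(det_fail, "detection_p", np.where(snp, "snp", ""))
    passed = ~(det_fail | snp)
    report = pd.DataFrame(
        {"passed": passed, "reason": reason}, index=pd.Index(matrix.probe_ids, name="probe_id")
    )
    kept = report.index[passed]
    return matrix.subset_probes(kept), QcReport(
        samples=pd.DataFrame(columns=["passed", "reason"]), probes=report
    )


def beta_to_m(beta, eps: float = M_EPS):
    """logit2 transform: M = log2(beta / (1 - beta)), beta clipped to
    [eps, 1 - eps].  Accepts scalars, arrays, Series or DataFrames."""
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(
            beta_to_m(beta.to_numpy(dtype=float), eps), index=beta.index, columns=beta.columns
        )
    if isinstance(beta, pd.Series):
        return pd.Series(
            beta_to_m(beta.to_numpy(dtype=float), eps), index=beta.index, name=beta.name
        )
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1); exact inverse of
    :func:`beta_to_m` for unclipped values."""
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(m_to_beta(m.to_numpy(dtype=float)), index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(m_to_beta(m.to_numpy(dtype=float)), index=m.index, name=m.name)
    m = np.asarray(m, dtype=float)
    # exp2(m)/(1+exp2(m)) in a form stable for large |m|
    return 0.5 * (1 + np.tanh(0.5 * np.log(2.0) * m))


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the across-sample mean quantile vector.

    After normalization the sorted values of every sample coincide; ranks
    within each sample are preserved, and ties share the mean of their
    quantile span.  Requires complete data.
    """
    beta = matrix.beta
    if beta.isna().any().any():
        raise ValueError("quantile_normalize requires complete data; impute or drop missing first")
    if beta.shape[1] == 1:
        warnings.warn("quantile_normalize on a single sample is the identity", stacklevel=2)
        return MethylationMatrix(beta.copy(), matrix.detection_p)
    vals = beta.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = ref
        # ties share the mean of their quantile span
        uniq, inv = np.unique(vals[:, j], return_inverse=True)
        if len(uniq) < vals.shape[0]:
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    res = pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return MethylationMatrix(res, matrix.detection_p)


def impute_age_at_exposure(table: SampleTable) -> SampleTable:
    """Fill age at exposure for healthy controls as follow-up age minus two
    years (the follow-up visit happens two years after the admission the
    patients were exposed to); patients keep their recorded admission age."""
    df = table.df.copy()
    if "age_exposure" not in df.columns:
        df["age_exposure"] = np.nan
    ctrl = df["group"] == "control"
    imputed = df.loc[ctrl, "age_followup"] - 2.0
    neg = imputed < 0
    if neg.any():
        raise ValueError(
            f"imputed age_exposure negative for control sample {neg[neg].index[0]!r} "
            f"(age_followup < 2 years)"
        )
    df.loc[ctrl, "age_exposure"] = imputed
    return SampleTable(df, dict(table.outcome_polarity))
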