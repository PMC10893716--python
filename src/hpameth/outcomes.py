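"""Methylation-outcome association with repeated cross-validated robustness.

For each (CpG, outcome) pair a multivariable linear model relates the
outcome score of patients to the CpG's M value, adjusting for baseline risk
factors and technical PCs.  Robustness is assessed by repeated ten-fold
cross-validation: per iteration the samples are partitioned at random into
k folds, a p-value for the methylation coefficient is obtained from each
fold, the k fold p-values are combined by Fisher's method
(-2 * sum(ln p) ~ chi2 with 2k df), and the iteration counts as significant
when the combined p <= alpha.  The percentage of significant iterations
(over 100 by default) quantifies robustness; 100% is labelled robust.
Significant pairs are tagged B (benefit) or H (harm) according to whether
the patients' abnormal methylation direction predicts a better or worse
outcome score under the outcome's polarity.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "RobustnessResult",
    "fit_outcome_model",
    "fisher_combine",
    "cv_robustness",
    "label_direction",
    "robustness_matrix",
]

_MIN_P = np.finfo(float).tiny


@dataclass
class CvConfig:
    """Cross-validation settings for the robustness procedure.

    ``fold_p_mode``: ``per_fold_refit`` (default) refits the full model
    inside each fold, so the k fold p-values come from disjoint subsamples
    and are independent; ``train_test_predict`` fits on the other k-1 folds
    and tests the correlation between the held-out residualised outcome and
    methylation.
    """

    k_folds: int = 10
    n_iterations: int = 100
    alpha: float = 0.05
    seed: int = 0
    fold_p_mode: str = "per_fold_refit"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.fold_p_mode not in ("per_fold_refit", "train_test_predict"):
            raise ValueError(f"unknown fold_p_mode {self.fold_p_mode!r}")


@dataclass
class RobustnessResult:
    probe_id: str
    outcome: str
    mean_coefficient: float
    full_data_p: float
    pct_iterations_significant: float
    label: str = "none"  # B / H / none

    @property
    def robust(self) -> bool:
        return self.pct_iterations_significant == 100.0


def _design_from(df: pd.DataFrame, covariates, extra: np.ndarray | None = None):
    """Intercept + encoded covariates (+ optional methylation column last)."""
    from .dmp import _encode  # shared categorical encoding

    parts = [pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)]
    for name in covariates:
        if name not in df.columns:
            raise ValueError(f"covariate {name!r} not in sample table")
        parts.append(_encode(df[name], name))
    X = pd.concat(parts, axis=1).to_numpy(dtype=float)
    if extra is not None:
        X = np.column_stack([X, extra])
    return X


def _ols_last_coef(y: np.ndarray, X: np.ndarray):
    """OLS; returns (coef, p) for the last column of X."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"model not estimable: {n} samples for {p} parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient within this subset")
    resid = y - X @ beta
    df = n - p
    s2 = resid @ resid / df
    invXtX = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * invXtX[-1, -1])
    if se == 0:
        return float(beta[-1]), 1.0
    t = beta[-1] / se
    return float(beta[-1]), float(2 * stats.t.sf(abs(t), df))


def fit_outcome_model(
    outcome: str,
    probe_m_values: pd.Series,
    sample_table: SampleTable,
    covariates,
) -> tuple:
    """Linear model outcome ~ methylation + covariates on patients with a
    non-missing outcome; returns (methylation coefficient, two-sided p)."""
    pat = sample_table.patients()
    col = f"outcome_{outcome}" if f"outcome_{outcome}" in pat.columns else outcome
    if col not in pat.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    sub = pat[pat[col].notna()]
    y = sub[col].to_numpy(dtype=float)
    if len(np.unique(y)) <= 1:
        raise ValueError(f"outcome {outcome!r} is constant")
    m = probe_m_values.reindex(sub.index).to_numpy(dtype=float)
    X = _design_from(sub, covariates, extra=m)
    return _ols_last_coef(y, X)


def fisher_combine(pvals) -> tuple:
    """Fisher's method: statistic = -2 * sum(ln p) ~ chi2 with 2k df.

    Exact zeros are clipped to the smallest positive float (logged).
    Returns (statistic, df, combined p).
    """
    p = np.asarray(pvals, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("fisher_combine: %d zero p-values clipped", int((p == 0).sum()))
        p = np.maximum(p, _MIN_P)
    statistic = -2.0 * np.sum(np.log(p))
    df = 2 * len(p)
    return float(statistic), int(df), float(stats.chi2.sf(statistic, df))


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random disjoint partition into k folds of near-equal size."""
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def cv_robustness(
    outcome: str,
    probe_m_values: pd.Series,
    sample_table: SampleTable,
    covariates,
    config: CvConfig,
) -> RobustnessResult:
    """Repeated k-fold cross-validated Fisher-combined robustness for one
    (CpG, outcome) pair.  Fully seeded: the same config yields bit-identical
    results, and streams are derived per pair so evaluation order of a batch
    does not matter.
    """
    pat = sample_table.patients()
    col = f"outcome_{outcome}" if f"outcome_{outcome}" in pat.columns else outcome
    sub = pat[pat[col].notna()]
    y = sub[col].to_numpy(dtype=float)
    m = probe_m_values.reindex(sub.index).to_numpy(dtype=float)
    X = _design_from(sub, covariates, extra=m)
    n, n_par = X.shape
    if config.fold_p_mode == "per_fold_refit" and n // config.k_folds <= n_par:
        raise ValueError(
            f"fold size {n // config.k_folds} cannot estimate {n_par} parameters; "
            "reduce the covariate list (e.g. fewer technical PCs)"
        )
    if np.ptp(m) == 0:
        # a probe constant across all patients cannot associate with anything
        return RobustnessResult(
            probe_id=str(probe_m_values.name),
            outcome=outcome,
            mean_coefficient=0.0,
            full_data_p=1.0,
            pct_iterations_significant=0.0,
        )
    full_coef, full_p = _ols_last_coef(y, X)

    # independent stream per (probe, outcome) pair; crc32 is stable across runs
    pair_key = zlib.crc32(f"{probe_m_values.name}|{outcome}".encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, pair_key]))
    n_sig = 0
    coef_sum, coef_n = 0.0, 0
    for _ in range(config.n_iterations):
        folds = _fold_assignments(n, config.k_folds, rng)
        fold_ps = []
        for f in range(config.k_folds):
            test = folds == f
            if config.fold_p_mode == "per_fold_refit":
                Xf = X[test]
                if np.ptp(Xf[:, -1]) == 0:
                    # methylation constant in this fold: no information
                    # about the coefficient, so the fold contributes p = 1
                    fold_ps.append(1.0)
                    continue
                # adjustment columns constant within a small fold carry no
                # information there and would alias the intercept; drop them
                keep = [0] + [
                    j for j in range(1, Xf.shape[1] - 1) if np.ptp(Xf[:, j]) > 0
                ] + [Xf.shape[1] - 1]
                try:
                    c, p = _ols_last_coef(y[test], Xf[:, keep])
                except ValueError:
                    # chance collinearity within a tiny fold leaves the
                    # coefficient unidentified: the fold contributes p = 1
                    fold_ps.append(1.0)
                    continue
                coef_sum += c
                coef_n += 1
            else:
                train = ~test
                beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
                coef_sum += float(beta[-1])
                coef_n += 1
                # association between held-out residualised outcome and methylation
                Xc = X[test][:, :-1]
                beta0, *_ = np.linalg.lstsq(Xc, y[test], rcond=None)
                resid = y[test] - Xc @ beta0
                if np.std(resid) == 0 or np.std(m[test]) == 0:
                    p = 1.0
                else:
                    _, p = stats.pearsonr(resid, m[test])
            fold_ps.append(p)
        _, _, combined = fisher_combine(fold_ps)
        n_sig += combined <= config.alpha
    return RobustnessResult(
        probe_id=str(probe_m_values.name),
        outcome=outcome,
        mean_coefficient=coef_sum / max(coef_n, 1),
        full_data_p=full_p,
        pct_iterations_significant=100.0 * n_sig / config.n_iterations,
    )


def label_direction(
    result: RobustnessResult,
    patient_abnormality: str,
    higher_is_better: bool,
    alpha: float = 0.05,
) -> str:
    """Benefit/harm label for a significant association.

    The predicted outcome shift in the direction of the patients' abnormal
    methylation is -coef for hypomethylation and +coef for hypermethylation;
    B when that shift improves the score under the outcome's polarity,
    H otherwise; 'none' when the full-data p exceeds alpha.
    """
    if patient_abnormality not in ("Hypo", "Hyper"):
        raise ValueError("patient_abnormality must be 'Hypo' or 'Hyper'")
    if result.full_data_p > alpha:
        return "none"
    if result.mean_coefficient == 0:
        warnings.warn("zero mean coefficient with significant p; labelled none", stacklevel=2)
        return "none"
    shift = -result.mean_coefficient if patient_abnormality == "Hypo" else result.mean_coefficient
    improves = (shift > 0) == higher_is_better
    return "B" if improves else "H"


def robustness_matrix(results) -> tuple:
    """Arrange RobustnessResults into the percent-significant heatmap matrix.

    Returns (pct matrix probes x outcomes, label matrix, counts dict) with
    rows/columns in canonical sorted order regardless of input order.
    Duplicate (probe, outcome) pairs are an error.
    """
    seen = set()
    for r in results:
        key = (r.probe_id, r.outcome)
        if key in seen:
            raise ValueError(f"duplicate (probe, outcome) pair {key}")
        seen.add(key)
    probes = sorted({r.probe_id for r in results})
    outs = sorted({r.outcome for r in results})
    pct = pd.DataFrame(np.nan, index=probes, columns=outs)
    labels = pd.DataFrame("", index=probes, columns=outs)
    n_sig = n_robust = 0
    for r in results:
        pct.loc[r.probe_id, r.outcome] = r.pct_iterations_significant
        labels.loc[r.probe_id, r.outcome] = r.label
        sig = r.full_data_p <= 0.05
        n_sig += sig
        n_robust += sig and r.robust
    counts = {
        "n_pairs": len(results),
        "n_significant": int(n_sig),
        "n_robust": int(n_robust),
        "pct_robust_of_significant": round(100 * n_robust / n_sig, 1) if n_sig else None,
    }
    return pct, labels, counts
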