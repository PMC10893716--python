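"""Per-CpG moderated multivariable linear models.

Each CpG's M values are regressed on a shared design matrix (group contrast
plus baseline risk factors and technical-variation PCs).  Residual variances
are then shrunk across probes by empirical Bayes: a scaled inverse-chi-square
prior (d0, s0^2) is fitted to the ensemble of residual variances by matching
moments of log s^2 (digamma/trigamma equations), and each probe's variance is
replaced by the posterior mean

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

yielding moderated t statistics on d0 + d degrees of freedom.  Group-contrast
p-values are adjusted by Benjamini-Hochberg; interaction (group x sex,
group x age) and glucocorticoid-subgroup contrasts are evaluated on the
identified DMP set and reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import GENE_CPG_TOTALS, SampleTable

__all__ = [
    "DesignSpec",
    "ModeratedFit",
    "build_design",
    "fit_probewise_models",
    "empirical_bayes_moderate",
    "trigamma_inverse",
    "bh_adjust",
    "interaction_scan",
    "gc_subgroup_contrast",
    "abs_mean_beta_diff",
    "summarize_dmps",
]


@dataclass
class DesignSpec:
    """Model specification: contrast variable, adjustment covariates and an
    optional interaction of the contrast with one covariate.

    Categorical covariates are one-hot encoded against a first-level
    reference; booleans and numerics enter as single columns.  The response
    is always on the M scale.
    """

    contrast: str
    covariates: list = field(default_factory=list)
    interaction: str | None = None  # covariate name, e.g. "sex" or "age_exposure"
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.contrast in self.covariates:
            raise ValueError("contrast variable must not be repeated among covariates")
        if self.interaction is not None and self.interaction not in self.covariates:
            raise ValueError("interaction term requires its main effect among the covariates")


@dataclass
class ModeratedFit:
    """Per-probe results for a single model coefficient (pre/post moderation)."""

    probe_ids: list
    coef: np.ndarray  # contrast coefficient (logFC on M scale)
    stdev_unscaled: np.ndarray  # sqrt of (X'X)^-1 diagonal entry for the contrast
    sigma2: np.ndarray  # residual variance s^2
    df_residual: float
    coef_name: str = ""
    # populated by empirical_bayes_moderate
    df_prior: float | None = None
    s2_prior: float | None = None
    s2_post: np.ndarray | None = None
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def ordinary_t(self) -> np.ndarray:
        se = np.sqrt(self.sigma2) * self.stdev_unscaled
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, self.coef / se, 0.0)

    def ordinary_p(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.ordinary_t()), self.df_residual)

    def to_frame(self) -> pd.DataFrame:
        d = {"coef": self.coef, "sigma2": self.sigma2}
        if self.t is not None:
            d.update(t=self.t, p=self.p, ci_low=self.ci_low, ci_high=self.ci_high)
        return pd.DataFrame(d, index=pd.Index(self.probe_ids, name="probe_id"))


# ---------------------------------------------------------------------------
# design matrices


def _encode(series: pd.Series, name: str) -> pd.DataFrame:
    """Encode one variable as model column(s)."""
    if series.dtype == bool or set(series.dropna().unique()) <= {True, False}:
        return pd.DataFrame({name: series.astype(float)})
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(series, prefix=name, drop_first=True, dtype=float)
        return dummies
    return pd.DataFrame({name: series.astype(float)})


def build_design(df: pd.DataFrame, spec: DesignSpec):
    """Assemble the design matrix.

    Returns (X, column names, index of the contrast column, index of the
    interaction column or None).  Raises on missing values in model
    variables, rank deficiency (naming aliased columns) and on a contrast
    that ends up multi-column.
    """
    parts = []
    if spec.intercept:
        parts.append(pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index))
    used = [spec.contrast] + list(spec.covariates)
    for name in used:
        if name not in df.columns:
            raise ValueError(f"model variable {name!r} not in sample table")
        if df[name].isna().any():
            raise ValueError(f"model variable {name!r} has missing values; subset first")
    contrast_enc = _encode(df[spec.contrast], spec.contrast)
    if contrast_enc.shape[1] != 1:
        raise ValueError(
            f"contrast variable {spec.contrast!r} must be binary/numeric "
            f"(got {contrast_enc.shape[1]} encoded columns)"
        )
    parts.append(contrast_enc)
    for name in spec.covariates:
        parts.append(_encode(df[name], name))

    inter_idx = None
    if spec.interaction is not None:
        term_enc = _encode(df[spec.interaction], spec.interaction)
        if term_enc.shape[1] != 1:
            raise ValueError(
                f"interaction term {spec.interaction!r} must encode to one column"
            )
        tvals = term_enc.iloc[:, 0]
        # a term constant within either contrast level makes the product aliased
        for level, sub in tvals.groupby(contrast_enc.iloc[:, 0]):
            if sub.nunique() <= 1:
                raise ValueError(
                    f"interaction term {spec.interaction!r} is constant within "
                    f"contrast level {level}"
                )
        prod = contrast_enc.iloc[:, 0] * tvals
        parts.append(pd.DataFrame({f"{spec.contrast}:{spec.interaction}": prod}, index=df.index))

    Xdf = pd.concat(parts, axis=1)
    X = Xdf.to_numpy(dtype=float)
    names = Xdf.columns.tolist()
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"fewer samples ({X.shape[0]}) than parameters + 1 ({X.shape[1] + 1})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR on the correlation structure
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * max(1, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased or 'unknown'}")
    c_idx = names.index(contrast_enc.columns[0])
    if spec.interaction is not None:
        inter_idx = names.index(f"{spec.contrast}:{spec.interaction}")
    return X, names, c_idx, inter_idx


# ---------------------------------------------------------------------------
# probewise OLS and empirical-Bayes moderation


def _ols_all_probes(Y: np.ndarray, X: np.ndarray):
    """Vectorised OLS of every probe (rows of Y) on the shared design X.

    Returns (B, sigma2, invXtX, df_residual) with B of shape probes x params.
    """
    n, p = X.shape
    xtx = X.T @ X
    invXtX = np.linalg.inv(xtx)
    B = Y @ X @ invXtX  # probes x params
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    df = n - p
    sigma2 = rss / df
    return B, sigma2, invXtX, df


def fit_probewise_models(
    matrix_m: pd.DataFrame,
    sample_table: SampleTable,
    design: DesignSpec,
    coef: str | None = None,
) -> ModeratedFit:
    """Ordinary least squares per probe with a shared design.

    ``matrix_m`` is probes x samples on the M scale.  The returned fit
    carries the coefficient named by ``coef`` (default: the contrast
    variable; pass the interaction column name to extract that instead).
    """
    df = sample_table.df.loc[list(matrix_m.columns)]
    X, names, c_idx, inter_idx = build_design(df, design)
    which = c_idx
    if coef is not None:
        if coef == "interaction":
            if inter_idx is None:
                raise ValueError("no interaction term in the design")
            which = inter_idx
        else:
            which = names.index(coef)
    Y = matrix_m.to_numpy(dtype=float)
    B, sigma2, invXtX, dfres = _ols_all_probes(Y, X)
    return ModeratedFit(
        probe_ids=matrix_m.index.tolist(),
        coef=B[:, which],
        stdev_unscaled=np.full(Y.shape[0], np.sqrt(invXtX[which, which])),
        sigma2=sigma2,
        df_residual=float(dfres),
        coef_name=names[which],
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone update on the inverse scale, which converges from the
    starting value 0.5 + 1/y for any y > 0.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def empirical_bayes_moderate(
    fit: ModeratedFit, ci_level: float = 0.95, force_df_prior: float | None = None
) -> ModeratedFit:
    """Shrink residual variances toward a common prior and recompute t/p/CI.

    The scaled inverse-chi-square prior (d0, s0^2) is estimated by matching
    the mean and variance of log s^2 against the theoretical moments of a
    log-F distribution: with e = log(s^2) - digamma(d/2) + log(d/2),

        E[e]   = log(s0^2) + digamma(d0/2) - log(d0/2)
        Var[e] = trigamma(d/2) + trigamma(d0/2)

    When the observed variance of e does not exceed trigamma(d/2) the
    equations imply d0 = inf and every posterior variance equals s0^2.
    ``force_df_prior`` pins d0 (0 recovers ordinary t; inf full shrinkage).
    """
    if len(fit.sigma2) < 2 and force_df_prior is None:
        raise ValueError("need at least 2 probes to estimate the variance prior")
    d = fit.df_residual
    if d <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    s2 = np.maximum(fit.sigma2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)

    if force_df_prior is not None:
        d0 = float(force_df_prior)
        if d0 == 0:
            s02 = float(np.mean(s2))
        elif np.isinf(d0):
            s02 = float(np.exp(np.mean(e)))
        else:
            s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
        if evar > 0:
            d0 = 2.0 * trigamma_inverse(evar)
            s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        else:
            d0 = np.inf
            s02 = float(np.exp(emean))

    if d0 == 0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)

    df_total = d0 + d
    se = np.sqrt(s2_post) * fit.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.coef / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
        tcrit = stats.norm.ppf(0.5 + ci_level / 2)
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
        tcrit = stats.t.ppf(0.5 + ci_level / 2, df_total)
    return ModeratedFit(
        probe_ids=fit.probe_ids,
        coef=fit.coef,
        stdev_unscaled=fit.stdev_unscaled,
        sigma2=fit.sigma2,
        df_residual=fit.df_residual,
        coef_name=fit.coef_name,
        df_prior=d0,
        s2_prior=s02,
        s2_post=s2_post,
        t=t,
        p=p,
        ci_low=fit.coef - tcrit * se,
        ci_high=fit.coef + tcrit * se,
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# secondary contrasts


def interaction_scan(
    matrix_m: pd.DataFrame,
    sample_table: SampleTable,
    design: DesignSpec,
    term: str,
) -> pd.Series:
    """Moderated p-value of the group x ``term`` interaction per probe.

    Run on the identified DMP set (pass the subset matrix): the interaction
    model extends the main-effects model with a single product column.
    """
    spec = DesignSpec(
        contrast=design.contrast,
        covariates=list(design.covariates),
        interaction=term,
        intercept=design.intercept,
    )
    fit = fit_probewise_models(matrix_m, sample_table, spec, coef="interaction")
    if len(fit.sigma2) >= 2:
        fit = empirical_bayes_moderate(fit)
    else:
        fit = empirical_bayes_moderate(fit, force_df_prior=0.0)
    return pd.Series(fit.p, index=matrix_m.index, name=f"p_int_{term}")


def gc_subgroup_contrast(
    matrix_m: pd.DataFrame,
    sample_table: SampleTable,
    design_gc: DesignSpec,
) -> pd.DataFrame:
    """Glucocorticoid-treated vs untreated contrast within patients only.

    ``design_gc`` contrasts ``gc_treated`` with the extended covariate list
    (baseline risk factors + PICU length of stay, admission diagnosis,
    severity scores, randomisation arm, malnutrition risk + technical PCs).
    Evaluated on the previously identified DMP set.
    """
    patients = sample_table.patients()
    if "gc_treated" not in patients.columns or patients["gc_treated"].isna().any():
        raise ValueError("gc_treated must be defined for every patient")
    n_gc = int(patients["gc_treated"].sum())
    if n_gc == 0 or n_gc == len(patients):
        raise ValueError("glucocorticoid contrast needs both treated and untreated patients")
    sub_m = matrix_m[patients.index.tolist()]
    sub_table = SampleTable(patients.copy(), dict(sample_table.outcome_polarity))
    fit = fit_probewise_models(sub_m, sub_table, design_gc)
    fit = empirical_bayes_moderate(fit) if len(fit.sigma2) >= 2 else empirical_bayes_moderate(fit, force_df_prior=0.0)
    return pd.DataFrame({"coef_gc": fit.coef, "p_gc": fit.p}, index=sub_m.index)


# ---------------------------------------------------------------------------
# descriptive columns and summaries


def abs_mean_beta_diff(matrix_beta: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Unadjusted |mean beta (patients) - mean beta (controls)| per probe."""
    groups = groups.reindex(matrix_beta.columns)
    pat = matrix_beta.loc[:, (groups == "patient").to_numpy()]
    ctl = matrix_beta.loc[:, (groups == "control").to_numpy()]
    if pat.shape[1] == 0 or ctl.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    return (pat.mean(axis=1) - ctl.mean(axis=1)).abs().rename("abs_mean_diff")


def summarize_dmps(table: pd.DataFrame, gene_totals: dict | None = None, alpha: float = 0.05) -> dict:
    """Headline summary of a DMP result table.

    Percentages are reported to one decimal; the SD of the absolute beta
    differences uses the sample (n-1) formula and is absent for a single row.
    """
    if table.empty:
        raise ValueError("empty DMP table")
    gene_totals = GENE_CPG_TOTALS if gene_totals is None else gene_totals
    diffs = table["abs_mean_diff"].to_numpy(dtype=float)
    n = len(table)
    genes = table["gene"].value_counts()
    per_gene = {}
    for gene, cnt in genes.items():
        total = gene_totals.get(gene)
        per_gene[gene] = {
            "n_dmps": int(cnt),
            "n_selected_cpgs": total,
            "pct_of_selected": round(100 * cnt / total, 1) if total else None,
        }
    out = {
        "n_dmps": n,
        "mean_abs_diff_pct": round(float(np.mean(diffs)) * 100, 1),
        "sd_abs_diff_pct": round(float(np.std(diffs, ddof=1)) * 100, 1) if n > 1 else None,
        "max_abs_diff_pct": round(float(np.max(diffs)) * 100, 1),
        "pct_hypo": round(100 * float((table["status"] == "Hypo").mean()), 1),
        "n_genes": int(table["gene"].nunique()),
        "per_gene": per_gene,
        "n_age_interaction": int((table["p_int_age"] <= alpha).sum()),
        "n_sex_interaction": int((table["p_int_sex"] <= alpha).sum()),
        "n_gc_associated": int((table["p_gc"] <= alpha).sum()),
    }
    return out
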