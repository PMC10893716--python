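"""Domain containers and delimited-text readers/writers.

The pipeline's central objects are thin, validated wrappers around pandas
DataFrames:

* :class:`MethylationMatrix` — probes x samples beta values in [0, 1], with
  an optional detection p-value matrix of the same shape.
* :class:`SampleTable` — one row per sample: group label, covariates,
  batch label and continuous developmental outcome scores.
* :class:`ProbeAnnotation` — one row per probe: genomic coordinate, gene
  assignment, gene section, SNP flag and control-probe designation.

Coordinates are 1-based closed internally (array-manifest convention); BED
input (0-based half-open) is converted on read.  Missing values are explicit
NaN, never sentinel zeros.  All writers emit headered TSV.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MalformedDataError",
    "SchemaError",
    "MethylationMatrix",
    "SampleTable",
    "ProbeAnnotation",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "read_probe_annotation_bed",
    "write_probe_annotation",
    "load_table2_fixture",
    "validate_dmp_table",
    "GENE_CPG_TOTALS",
]


class MalformedDataError(ValueError):
    """A cell value violates a domain invariant (e.g. beta outside [0, 1])."""


class SchemaError(ValueError):
    """A table is missing a mandatory column or has duplicate identifiers."""


#: Number of CpG sites interrogated per gene of the HPA-axis panel (used as
#: denominators when reporting per-gene DMP fractions).
GENE_CPG_TOTALS = {
    "CRH": 0,
    "CRHR1": 41,
    "AVP": 0,
    "AVPR1B": 0,
    "POMC": 27,
    "MC2R": 20,
    "NR3C1": 89,
    "FKBP5": 51,
    "HSD11B1": 25,
    "HSD11B2": 0,
    "SRD5A1": 31,
    "SRD5A2": 0,
    "AKR1D1": 15,
    "DUSP1": 33,
    "ANXA1": 0,
    "PCSK1": 0,
    "TSC22D3": 50,
    "TNF": 27,
}

_CONTROL_TYPES = frozenset({"none", "negative", "other_control"})


def _sniff_sep(path, dialect=None):
    """Auto-detect comma vs tab from the header line; ``dialect`` overrides."""
    if dialect is not None:
        return {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}[dialect]
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


# ---------------------------------------------------------------------------
# MethylationMatrix


@dataclass
class MethylationMatrix:
    """Beta-value matrix (probes x samples) with optional detection p-values.

    ``beta`` is indexed by probe id, with sample ids as columns.  Non-missing
    entries must be finite and lie in [0, 1]; missingness is explicit NaN.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].tolist()
            raise SchemaError(f"duplicate probe ids: {dups[:5]}")
        if self.beta.columns.has_duplicates:
            dups = self.beta.columns[self.beta.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < 0) | (vals > 1) | ~np.isfinite(vals))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MalformedDataError(
                f"beta value {vals[i, j]!r} out of [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise SchemaError(
                    "detection_p shape does not match beta "
                    f"({self.detection_p.shape} vs {self.beta.shape})"
                )
            dp = self.detection_p.to_numpy(dtype=float)
            bad = ~np.isnan(dp) & ((dp < 0) | (dp > 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MalformedDataError(
                    f"detection p {dp[i, j]!r} out of [0, 1] at probe "
                    f"{self.detection_p.index[i]!r}, sample "
                    f"{self.detection_p.columns[j]!r}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return self.beta.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.beta.columns.tolist()

    @property
    def shape(self) -> tuple:
        return self.beta.shape

    def subset_probes(self, probes) -> "MethylationMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probes]
        return MethylationMatrix(self.beta.loc[probes], dp)

    def subset_samples(self, samples) -> "MethylationMatrix":
        dp = None if self.detection_p is None else self.detection_p[list(samples)]
        return MethylationMatrix(self.beta[list(samples)], dp)


def read_beta_matrix(path, dialect=None, detection_path=None) -> MethylationMatrix:
    """Read a beta matrix from delimited text (first column = probe id).

    Out-of-range values and duplicate identifiers raise, naming the offending
    probe/sample.  Empty cells become NaN (absent), never zero.
    """
    sep = _sniff_sep(path, dialect)
    beta = pd.read_csv(path, sep=sep, index_col=0)
    dp = None
    if detection_path is not None:
        dp = pd.read_csv(detection_path, sep=_sniff_sep(detection_path, dialect), index_col=0)
    return MethylationMatrix(beta, dp)


def write_beta_matrix(matrix: MethylationMatrix, path, detection_path=None) -> None:
    matrix.beta.to_csv(path, sep="\t", index_label="probe_id")
    if detection_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# SampleTable

#: Columns that may only be populated for patients.
_PATIENT_ONLY = (
    "gc_treated",
    "pim3",
    "pelod",
    "strongkids",
    "los_picu",
    "diagnosis_category",
    "randomisation_arm",
)


@dataclass
class SampleTable:
    """Per-sample metadata: group, covariates, batch and outcome scores.

    ``df`` is indexed by sample id and must contain a ``group`` column with
    values in {patient, control}.  Outcome scores live in columns named
    ``outcome_<name>``; ``outcome_polarity`` records, per outcome, whether a
    higher score means a better result (used for benefit/harm labelling).
    Unknown columns are preserved as opaque covariates.
    """

    df: pd.DataFrame
    outcome_polarity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if "group" not in self.df.columns:
            raise SchemaError("sample sheet is missing mandatory column 'group'")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        groups = set(self.df["group"].dropna().unique())
        if not groups <= {"patient", "control"}:
            raise SchemaError(f"unknown group labels: {sorted(groups - {'patient', 'control'})}")
        ctrl = self.df["group"] == "control"
        for col in _PATIENT_ONLY:
            if col in self.df.columns and self.df.loc[ctrl, col].notna().any():
                raise SchemaError(f"patient-only column {col!r} set for control samples")
        if "age_exposure" in self.df.columns:
            neg = self.df["age_exposure"].dropna() < 0
            if neg.any():
                raise MalformedDataError(
                    f"negative age_exposure for sample {neg[neg].index[0]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return self.df.index.tolist()

    @property
    def outcome_names(self) -> list:
        return [c[len("outcome_"):] for c in self.df.columns if c.startswith("outcome_")]

    def patients(self) -> pd.DataFrame:
        return self.df[self.df["group"] == "patient"]

    def controls(self) -> pd.DataFrame:
        return self.df[self.df["group"] == "control"]

    def copy(self) -> "SampleTable":
        return SampleTable(self.df.copy(), dict(self.outcome_polarity))


def read_sample_sheet(path, dialect=None) -> SampleTable:
    """Read a sample sheet; patients missing severity scores are retained
    with absent values (logged), never dropped."""
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in ("gc_treated", "malignancy", "syndrome"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    for col in ("pim3", "pelod", "los_picu"):
        if col in df.columns:
            n_missing = int(df.loc[df["group"] == "patient", col].isna().sum()) if "group" in df else 0
            if n_missing:
                logger.info("%d patient rows missing %s; retained with absent value", n_missing, col)
    return SampleTable(df)


def write_sample_sheet(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# ProbeAnnotation


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: 1-based coordinate, genes, section, SNP flag
    and control-probe class ({none, negative, other_control}).

    A probe can sit in several genes/splice variants; ``genes`` and
    ``gene_section`` are therefore slash- or semicolon-joined strings.
    Control probes need no genomic assignment.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = {"chrom", "pos"} - set(self.df.columns)
        if missing:
            raise SchemaError(f"probe annotation missing mandatory columns: {sorted(missing)}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise SchemaError(f"duplicate probe ids: {dups[:5]}")
        if "control_type" not in self.df.columns:
            self.df["control_type"] = "none"
        bad = set(self.df["control_type"].dropna().unique()) - _CONTROL_TYPES
        if bad:
            raise SchemaError(f"unknown control_type values: {sorted(bad)}")
        if "snp_flag" not in self.df.columns:
            self.df["snp_flag"] = False
        self.df["snp_flag"] = self.df["snp_flag"].fillna(False).astype(bool)
        is_ctrl = self.df["control_type"] != "none"
        flagged_ctrl = is_ctrl & self.df["snp_flag"]
        if flagged_ctrl.any():
            warnings.warn(
                f"snp_flag set on {int(flagged_ctrl.sum())} control probes; ignored",
                stacklevel=2,
            )
            self.df.loc[flagged_ctrl, "snp_flag"] = False
        pos = self.df.loc[~is_ctrl, "pos"].dropna()
        if (pos < 1).any():
            raise MalformedDataError("probe position < 1 (coordinates are 1-based)")

    @property
    def probe_ids(self) -> list:
        return self.df.index.tolist()

    def control_probes(self, exclude_negative: bool = True) -> list:
        """Probe ids of technical control probes; negative controls excluded
        by default (they measure background, not batch)."""
        ct = self.df["control_type"]
        mask = ct == "other_control" if exclude_negative else ct != "none"
        return self.df.index[mask].tolist()

    def biological_probes(self) -> list:
        return self.df.index[self.df["control_type"] == "none"].tolist()


def read_probe_annotation(path, dialect=None) -> ProbeAnnotation:
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ProbeAnnotation(df)


def read_probe_annotation_bed(path) -> ProbeAnnotation:
    """Read probe coordinates from BED (3+1 columns: chrom, start, end, name).

    BED is 0-based half-open; internal coordinates are 1-based closed, so
    pos = start + 1.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise SchemaError(f"BED line has fewer than 4 columns: {line!r}")
            chrom, start, _end, name = parts[:4]
            rows.append((name, chrom, int(start) + 1))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]).set_index("probe_id")
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.df.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# DMP result table and packaged fixture

_DMP_COLUMNS = [
    "gene",
    "probe_id",
    "gene_section",
    "status",
    "logfc_m",
    "ci_low",
    "ci_high",
    "abs_mean_diff",
    "q_group",
    "p_int_sex",
    "p_int_age",
    "p_gc",
]


def validate_dmp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check DMP-table invariants: CI brackets the estimate, status matches
    the sign of the M-scale log fold change, absolute differences >= 0."""
    missing = set(_DMP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"DMP table missing columns: {sorted(missing)}")
    if not ((df["ci_low"] <= df["logfc_m"]) & (df["logfc_m"] <= df["ci_high"])).all():
        raise MalformedDataError("confidence interval does not bracket logfc_m")
    expected = np.where(df["logfc_m"] < 0, "Hypo", "Hyper")
    if not (df["status"] == expected).all():
        raise MalformedDataError("status inconsistent with sign of logfc_m")
    if (df["abs_mean_diff"] < 0).any():
        raise MalformedDataError("abs_mean_diff must be >= 0")
    return df


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 26-row table of differentially methylated CpG sites
    within the HPA-axis panel (gene, section, direction, M-scale log fold
    change with 95% CI, unadjusted absolute beta difference, FDR-adjusted
    group p, sex/age interaction p, glucocorticoid-subgroup p).

    Two adjusted group p-values below the table's printing precision are
    stored at the printed bound (1e-5).
    """
    text = resources.files("hpameth.data").joinpath("table2_dmps.tsv").read_text()
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    return validate_dmp_table(df)
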