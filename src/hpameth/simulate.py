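"""Synthetic EPIC-like cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
two-group cohort (former patients, a glucocorticoid-treated patient
subgroup, and healthy controls), per-probe bimodal baseline methylation,
additive M-scale group effects calibrated so the realised beta-scale
difference matches a requested delta-beta, plate/chip batch effects that
load on technical control probes through shared latent factors (so
control-probe PCA can recover them), clustered effects forming genomic
regions, covariates with marginals resembling a paediatric ICU follow-up
cohort, and developmental outcome scores causally linked to methylation at
chosen CpGs.

Everything is determined by the config seed: the same config yields
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ProbeAnnotation, SampleTable
from .qc import beta_to_m, m_to_beta

__all__ = ["SimulationConfig", "TruthTable", "simulate_cohort", "simulate_outcomes", "make_qc_fixture"]

_CHROMS = ["chr1", "chr2", "chr5", "chr6", "chr7", "chr17", "chr20", "chrX"]


@dataclass
class SimulationConfig:
    """Cohort generator settings.

    Desk-scale defaults (120 patients of whom a quarter glucocorticoid-
    treated, 60 controls, 3,000 biological + 300 control probes, 4 batches)
    keep every downstream stage testable in seconds; a full-scale cohort
    (818/210/392) is a matter of changing three numbers.

    ``spike_table`` rows are (probe index, delta_beta, sign); the effect is
    added on the M scale, sized at the probe's baseline so that the realised
    group difference in mean beta is ~delta_beta.  ``region_spikes`` rows are
    (chrom, start probe index, n_cpgs, max span bp, delta_beta): the
    generator places those probes consecutively within the span and spikes
    them coherently.  ``gc_spike_table`` rows (probe index, delta_beta, sign)
    add an extra effect in glucocorticoid-treated patients only.
    ``outcome_links`` rows are (probe index, outcome name, coefficient on the
    M scale, noise sd).
    """

    n_patients: int = 120
    n_controls: int = 60
    gc_fraction: float = 0.25
    n_probes: int = 3000
    n_control_probes: int = 300
    n_batches: int = 4
    batch_sd: float = 0.5  # M-scale magnitude of the latent batch factors
    n_latent: int = 2  # rank of the shared batch structure
    sigma_m: float = 0.4  # typical residual SD on the M scale
    sigma_df: float = 10.0  # spread of per-probe residual variances (inv-chi2 df)
    spike_table: list = field(default_factory=list)
    region_spikes: list = field(default_factory=list)
    gc_spike_table: list = field(default_factory=list)
    outcome_links: list = field(default_factory=list)
    n_failing_probes: int = 0  # probes with failed detection in >half the samples
    batch_confounded_with_group: bool = False
    male_frac_patients: float = 0.581
    male_frac_controls: float = 0.541
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, db, _sign in self.spike_table:
            if not 0 < db < 0.5:
                raise ValueError(f"delta_beta must lie in (0, 0.5); got {db} at probe {idx}")
        spiked = {i for i, *_ in self.spike_table}
        for _, start, n_cpgs, _, _ in self.region_spikes:
            spiked.update(range(start, start + n_cpgs))
        if spiked and max(spiked) >= self.n_probes:
            raise ValueError("spike table references probe indices beyond n_probes")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort, for recovery tests.

    ``probes``: per biological probe — true M- and beta-scale group effect,
    region membership, linked outcomes.  ``samples``: batch assignment.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    outcome_links: list


def _baseline_m(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-probe baseline means on the M scale whose beta-scale marginal is
    the characteristic bimodal curve (modes near 0.1 and 0.9)."""
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    lo = beta_to_m(0.1) + 0.8 * rng.standard_normal(n)
    hi = beta_to_m(0.9) + 0.8 * rng.standard_normal(n)
    mid = 1.0 * rng.standard_normal(n)
    return np.select([comp == 0, comp == 1], [lo, hi], default=mid)


def _effect_m_for_delta_beta(m0: float, delta_beta: float, sign: int) -> float:
    """M-scale shift whose beta-scale displacement at baseline m0 is
    sign * delta_beta (target beta clipped inside (0.01, 0.99))."""
    b0 = float(m_to_beta(m0))
    target = float(np.clip(b0 + sign * delta_beta, 0.01, 0.99))
    return float(beta_to_m(target) - m0)


def _layout_probes(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene-like loci of ~25 CpGs, ~60-400 bp apart, loci >= 20 kb apart."""
    n = cfg.n_probes
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    genes = np.empty(n, dtype=object)
    locus_size = 25
    i = gene_no = 0
    while i < n:
        chrom = _CHROMS[gene_no % len(_CHROMS)]
        start = 1_000_000 + (gene_no // len(_CHROMS)) * 50_000
        k = min(locus_size, n - i)
        gaps = rng.integers(60, 400, size=k)
        p = start + np.cumsum(gaps)
        chroms[i : i + k] = chrom
        pos[i : i + k] = p
        genes[i : i + k] = f"GENE{gene_no:04d}"
        gene_no += 1
        i += k
    return chroms, pos, genes


def simulate_cohort(config: SimulationConfig):
    """Generate (MethylationMatrix, SampleTable, ProbeAnnotation, TruthTable).

    Beta values are drawn as inverse-logit2 of (baseline + group effect +
    batch effect + noise); control probes carry batch effect and noise but
    never a group effect; detection p-values are small except for configured
    failing probes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pat, n_ctl = cfg.n_patients, cfg.n_controls
    n_samp = n_pat + n_ctl
    n_bio, n_ctrlp = cfg.n_probes, cfg.n_control_probes

    # --- samples ----------------------------------------------------------
    sample_ids = [f"P{i:04d}" for i in range(n_pat)] + [f"C{i:04d}" for i in range(n_ctl)]
    is_patient = np.r_[np.ones(n_pat, bool), np.zeros(n_ctl, bool)]
    n_gc = int(round(cfg.gc_fraction * n_pat))
    gc = np.zeros(n_samp, bool)
    gc[rng.choice(n_pat, size=n_gc, replace=False)] = True

    if cfg.batch_confounded_with_group:
        # patients concentrate in the first half of the batches
        half = max(cfg.n_batches // 2, 1)
        pat_b = rng.choice(half, size=n_pat)
        ctl_b = half + rng.choice(max(cfg.n_batches - half, 1), size=n_ctl)
        batch = np.r_[pat_b, ctl_b]
    else:
        batch = rng.integers(0, cfg.n_batches, size=n_samp)

    # --- covariates (marginals loosely matching a PICU follow-up cohort) --
    sex = np.where(
        rng.random(n_samp) < np.where(is_patient, cfg.male_frac_patients, cfg.male_frac_controls),
        "male",
        "female",
    )
    age_exposure = np.clip(np.exp(rng.normal(np.log(1.6), 1.0, n_samp)), 0.0, 16.9)
    age_followup = age_exposure + 2.0
    centre = np.where(rng.random(n_samp) < 0.6, "Leuven", "Rotterdam")
    race = np.where(rng.random(n_samp) < 0.08, "non_caucasian", "caucasian")
    geo = np.where(rng.random(n_samp) < 0.16, "non_european", "european")
    lingo = np.where(rng.random(n_samp) < 0.22, "other", "dutch_english")
    malignancy = is_patient & (rng.random(n_samp) < 0.048)
    syndrome = rng.random(n_samp) < np.where(is_patient, 0.205, 0.01)

    df = pd.DataFrame(
        {
            "group": np.where(is_patient, "patient", "control"),
            "sex": sex,
            "age_followup": age_followup,
            "age_exposure": age_exposure,
            "centre": centre,
            "race": race,
            "geographic_origin": geo,
            "linguistic_origin": lingo,
            "malignancy": malignancy,
            "syndrome": syndrome,
            "batch": [f"plate{b + 1}" for b in batch],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # patient-only clinical fields
    df["gc_treated"] = pd.Series(
        [bool(g) if p else np.nan for g, p in zip(gc, is_patient)], index=df.index, dtype=object
    )
    df["pim3"] = np.where(is_patient, rng.normal(-3.6, 1.0, n_samp), np.nan)
    df["pelod"] = np.where(is_patient, np.clip(rng.normal(22, 12, n_samp), 0, 71), np.nan)
    df["strongkids"] = np.where(
        is_patient, np.where(rng.random(n_samp) < 0.10, "high", "medium"), None
    )
    df["los_picu"] = np.where(is_patient, np.exp(rng.normal(np.log(3.0), 0.9, n_samp)), np.nan)
    df["diagnosis_category"] = np.where(
        is_patient,
        rng.choice(
            ["cardiac_surgery", "elective_surgery", "urgent_surgery", "medical"],
            size=n_samp,
            p=[0.445, 0.142, 0.174, 0.239],
        ),
        None,
    )
    df["randomisation_arm"] = np.where(
        is_patient, np.where(rng.random(n_samp) < 0.5, "late_pn", "early_pn"), None
    )

    # --- probe layout, baselines and effects ------------------------------
    chroms, pos, genes = _layout_probes(cfg, rng)
    m0 = _baseline_m(rng, n_bio)
    region_id = np.full(n_bio, -1)
    effect_m = np.zeros(n_bio)

    for idx, db, sign in cfg.spike_table:
        effect_m[idx] = _effect_m_for_delta_beta(m0[idx], db, sign)
    for rid, (chrom, start, n_cpgs, max_span, db) in enumerate(cfg.region_spikes):
        members = np.arange(start, start + n_cpgs)
        # relocate members into one tight locus on the requested chromosome
        chroms[members] = chrom
        gaps = rng.integers(20, max(max_span // max(n_cpgs - 1, 1), 21), size=n_cpgs)
        pos[members] = 10_000_000 + 100_000 * rid + np.cumsum(gaps)
        genes[members] = f"REGIONGENE{rid:02d}"
        region_id[members] = rid
        sign = 1 if db > 0 else -1
        for j in members:
            effect_m[j] = _effect_m_for_delta_beta(m0[j], abs(db), sign)
    gc_effect_m = np.zeros(n_bio)
    for idx, db, sign in cfg.gc_spike_table:
        gc_effect_m[idx] = _effect_m_for_delta_beta(m0[idx], db, sign)

    # --- batch structure: shared latent factors ---------------------------
    factors = cfg.batch_sd * rng.standard_normal((cfg.n_batches, cfg.n_latent))
    load_bio = rng.standard_normal((n_bio, cfg.n_latent))
    load_ctrl = rng.standard_normal((n_ctrlp, cfg.n_latent))
    sample_factor = factors[batch]  # samples x latent

    # per-probe residual SDs: scaled inverse-chi-square spread around sigma_m
    d0 = cfg.sigma_df
    sigma_bio = cfg.sigma_m * np.sqrt(d0 / rng.chisquare(d0, n_bio))
    sigma_ctrl = cfg.sigma_m * np.sqrt(d0 / rng.chisquare(d0, n_ctrlp))

    M_bio = (
        m0[:, None]
        + effect_m[:, None] * is_patient[None, :]
        + gc_effect_m[:, None] * gc[None, :]
        + load_bio @ sample_factor.T
        + sigma_bio[:, None] * rng.standard_normal((n_bio, n_samp))
    )
    m0_ctrl = 1.5 * rng.standard_normal(n_ctrlp)
    M_ctrl = (
        m0_ctrl[:, None]
        + load_ctrl @ sample_factor.T
        + sigma_ctrl[:, None] * rng.standard_normal((n_ctrlp, n_samp))
    )

    beta = m_to_beta(np.vstack([M_bio, M_ctrl]))
    beta = np.clip(beta, 1e-6, 1 - 1e-6)  # strictly inside (0, 1)

    probe_ids = [f"cg{i:08d}" for i in range(n_bio)] + [f"ctrl{i:05d}" for i in range(n_ctrlp)]
    detection = np.asarray(rng.uniform(0.0, 0.005, size=beta.shape))
    if cfg.n_failing_probes:
        fail = rng.choice(n_bio, size=cfg.n_failing_probes, replace=False)
        bad_samples = rng.random((cfg.n_failing_probes, n_samp)) < 0.6
        detection[fail] = np.where(bad_samples, rng.uniform(0.02, 0.5, bad_samples.shape), detection[fail])

    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    det_df = pd.DataFrame(detection, index=beta_df.index, columns=sample_ids)
    matrix = MethylationMatrix(beta_df, det_df)

    ann = pd.DataFrame(
        {
            "chrom": np.r_[chroms, np.full(n_ctrlp, "")],
            "pos": np.r_[pos, np.full(n_ctrlp, 1, dtype=np.int64)],
            "genes": np.r_[genes, np.full(n_ctrlp, "")],
            "gene_section": np.r_[
                np.where(np.arange(n_bio) % 25 < 5, "Promoter/5'UTR", "Body"),
                np.full(n_ctrlp, ""),
            ],
            "snp_flag": False,
            "control_type": np.r_[
                np.full(n_bio, "none"), np.full(n_ctrlp, "other_control")
            ],
        },
        index=beta_df.index,
    )
    annotation = ProbeAnnotation(ann)

    truth_probes = pd.DataFrame(
        {
            "effect_m": effect_m,
            "effect_beta": m_to_beta(m0 + effect_m) - m_to_beta(m0),
            "gc_effect_m": gc_effect_m,
            "region_id": region_id,
            "baseline_m": m0,
            "sigma_m": sigma_bio,
        },
        index=pd.Index(probe_ids[:n_bio], name="probe_id"),
    )
    truth_samples = pd.DataFrame(
        {"batch": batch, "latent_1": sample_factor[:, 0]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = TruthTable(probes=truth_probes, samples=truth_samples, outcome_links=list(cfg.outcome_links))

    table = SampleTable(df)
    if cfg.outcome_links:
        table = simulate_outcomes(table, matrix, cfg.outcome_links, seed=cfg.seed + 1)
    return matrix, table, annotation, truth


def simulate_outcomes(
    sample_table: SampleTable,
    matrix: MethylationMatrix,
    outcome_links,
    seed: int,
    higher_is_better: dict | None = None,
) -> SampleTable:
    """Attach continuous outcome scores causally linked to methylation.

    Each link (probe index or id, outcome name, coefficient, noise sd)
    contributes coefficient x M-value to that outcome; a mild age term and
    Gaussian noise complete the score.  Outcomes are measured in patients
    only (controls stay missing).  The polarity flag is metadata and never
    alters the values.
    """
    rng = np.random.default_rng(seed)
    df = sample_table.df.copy()
    pat = df["group"] == "patient"
    by_outcome: dict[str, list] = {}
    for probe, name, coef, noise_sd in outcome_links:
        by_outcome.setdefault(name, []).append((probe, coef, noise_sd))
    for name, links in by_outcome.items():
        probes = [p if isinstance(p, str) else matrix.probe_ids[p] for p, _, _ in links]
        missing = set(probes) - set(matrix.probe_ids)
        if missing:
            raise ValueError(f"outcome link references unknown probes: {sorted(missing)}")
        M = beta_to_m(matrix.beta.loc[probes])
        signal = np.zeros(len(df))
        for (_, coef, _), probe in zip(links, probes):
            signal += coef * M.loc[probe].reindex(df.index).to_numpy()
        noise_sd = max(ns for _, _, ns in links)
        score = (
            100.0
            + signal
            + 0.3 * df["age_followup"].to_numpy(dtype=float)
            + noise_sd * rng.standard_normal(len(df))
        )
        df[f"outcome_{name}"] = np.where(pat, score, np.nan)
    polarity = dict(sample_table.outcome_polarity)
    for name in by_outcome:
        polarity[name] = True if higher_is_better is None else higher_is_better.get(name, True)
    return SampleTable(df, polarity)


def make_qc_fixture(seed: int = 0, n_probes: int = 400):
    """The 821-patient-swab QC fixture.

    821 samples of which exactly one is marked insufficient-DNA-yield and
    exactly two have a uniform-like (non-bimodal) beta distribution; the
    remaining 818 show the typical bi-peak curve and pass sample QC.

    Returns (MethylationMatrix, set of insufficient-yield sample ids).
    """
    rng = np.random.default_rng(seed)
    n_samples = 821
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    # bimodal: half the probes near the low mode, half near the high mode
    low = rng.beta(2, 18, size=(n_probes // 2, n_samples))
    high = rng.beta(18, 2, size=(n_probes - n_probes // 2, n_samples))
    beta = np.vstack([low, high])
    bad = rng.choice(n_samples, size=3, replace=False)
    non_bimodal, yield_fail = bad[:2], bad[2]
    beta[:, non_bimodal] = rng.uniform(0.3, 0.7, size=(n_probes, 2))
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )
    return matrix, {sample_ids[yield_fail]}
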