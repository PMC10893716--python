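import numpy as np
import pandas as pd
import pytest

from hpameth import MethylationMatrix, ProbeAnnotation, SampleTable
from hpameth.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small spiked cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_patients=60,
        n_controls=40,
        n_probes=400,
        n_control_probes=60,
        spike_table=[(10, 0.05, -1), (50, 0.05, 1)],
        outcome_links=[(10, "iq", -1.0, 2.0)],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_matrix():
    beta = pd.DataFrame(
        [[0.10, 0.20], [0.50, 0.60], [0.85, 0.95]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return MethylationMatrix(beta)


@pytest.fixture()
def tiny_annotation():
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 600, 250],
            "genes": ["G1", "G1", "G2"],
            "gene_section": ["Promoter", "Body", "Body"],
            "snp_flag": [False, False, False],
            "control_type": ["none", "none", "none"],
        },
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
    )
    return ProbeAnnotation(df)


@pytest.fixture()
def tiny_samples():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "group": ["patient"] * 6 + ["control"] * 4,
            "sex": ["male", "female"] * 5,
            "age_followup": rng.uniform(2.5, 10, 10),
            "age_exposure": rng.uniform(0.5, 8, 10),
        },
        index=pd.Index([f"s{i}" for i in range(10)], name="sample_id"),
    )
    df["gc_treated"] = pd.Series(
        [True, False, True, False, False, False, np.nan, np.nan, np.nan, np.nan],
        index=df.index,
        dtype=object,
    )
    return SampleTable(df)
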