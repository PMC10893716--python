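import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hpameth.dmp import (
    DesignSpec,
    abs_mean_beta_diff,
    bh_adjust,
    empirical_bayes_moderate,
    fit_probewise_models,
    gc_subgroup_contrast,
    interaction_scan,
    summarize_dmps,
    trigamma_inverse,
)
from hpameth.io import SampleTable, load_table2_fixture
from hpameth.qc import beta_to_m
from hpameth.simulate import SimulationConfig, simulate_cohort


def _two_group_table(n1, n2, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "group_patient": np.r_[np.ones(n1), np.zeros(n2)],
            "age_exposure": rng.uniform(0.5, 10, n1 + n2),
            "sex": rng.choice(["male", "female"], n1 + n2),
        },
        index=pd.Index([f"s{i}" for i in range(n1 + n2)], name="sample_id"),
    )
    df["group"] = np.where(df["group_patient"] == 1, "patient", "control")
    return SampleTable(df)


class TestProbewiseOls:
    def test_identical_groups_give_zero_logfc(self):
        table = _two_group_table(5, 5)
        half = np.random.default_rng(0).standard_normal((5, 5))
        vals = np.hstack([half, half])  # patients and controls see identical data
        m = pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)], columns=table.sample_ids)
        fit = fit_probewise_models(m, table, DesignSpec(contrast="group_patient"))
        np.testing.assert_allclose(fit.coef, 0, atol=1e-12)
        mod = empirical_bayes_moderate(fit, force_df_prior=0.0)
        np.testing.assert_allclose(mod.p, 1, atol=1e-9)

    def test_matches_normal_equations_on_hand_example(self):
        # 6 samples, one probe: solve X'X beta = X'y explicitly as the oracle
        table = _two_group_table(3, 3, seed=1)
        y = np.array([2.1, 1.9, 2.3, 1.0, 0.8, 1.1])
        m = pd.DataFrame([y], index=["cg0"], columns=table.sample_ids)
        spec = DesignSpec(contrast="group_patient", covariates=["age_exposure"])
        fit = fit_probewise_models(m, table, spec)
        X = np.column_stack(
            [np.ones(6), table.df["group_patient"], table.df["age_exposure"]]
        )
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef[0] == pytest.approx(beta_oracle[1], abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        table = _two_group_table(5, 5)
        df = table.df.copy()
        df["dup"] = df["group_patient"]  # perfectly aliased
        m = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 10)),
                         index=["a", "b", "c"], columns=df.index)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_probewise_models(
                m, SampleTable(df), DesignSpec(contrast="group_patient", covariates=["dup"])
            )

    def test_ci_coverage_of_spiked_effect(self):
        """A simulated M-scale shift falls inside its own 95% CI in >= 93%
        of replicate probes (each probe is an independent replicate)."""
        rng = np.random.default_rng(10)
        n1 = n2 = 30
        delta = 0.5
        table = _two_group_table(n1, n2, seed=3)
        Y = rng.standard_normal((500, n1 + n2))
        Y[:, :n1] += delta
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(500)], columns=table.sample_ids)
        fit = empirical_bayes_moderate(
            fit_probewise_models(m, table, DesignSpec(contrast="group_patient")),
            force_df_prior=0.0,
        )
        covered = ((fit.ci_low <= delta) & (delta <= fit.ci_high)).mean()
        assert covered >= 0.93


class TestEmpiricalBayes:
    def _null_fit(self, n_probes=400, n=20, seed=0):
        rng = np.random.default_rng(seed)
        table = _two_group_table(n // 2, n - n // 2, seed=seed)
        Y = rng.standard_normal((n_probes, n)) * rng.uniform(0.5, 2.0, n_probes)[:, None]
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(n_probes)], columns=table.sample_ids)
        return fit_probewise_models(m, table, DesignSpec(contrast="group_patient"))

    def test_zero_prior_df_recovers_ordinary_t(self):
        fit = self._null_fit()
        mod = empirical_bayes_moderate(fit, force_df_prior=0.0)
        np.testing.assert_allclose(mod.t, fit.ordinary_t(), atol=1e-10)

    def test_infinite_prior_df_gives_full_shrinkage(self):
        fit = self._null_fit()
        mod = empirical_bayes_moderate(fit, force_df_prior=np.inf)
        assert np.ptp(mod.s2_post) == 0.0
        assert mod.s2_post[0] == pytest.approx(mod.s2_prior)

    def test_prior_df_recovered_from_known_mixture(self):
        # residual variances drawn from a scaled inv-chi-square(d0=4, s0^2=1)
        rng = np.random.default_rng(42)
        d0, s02, d = 4.0, 1.0, 10
        n_probes = 5000
        true_var = d0 * s02 / rng.chisquare(d0, n_probes)
        s2 = true_var * rng.chisquare(d, n_probes) / d
        fit = self._null_fit(n_probes=2, n=12)  # container; variances overwritten
        fit.sigma2 = s2
        fit.df_residual = float(d)
        fit.coef = np.zeros(n_probes)
        fit.stdev_unscaled = np.ones(n_probes)
        fit.probe_ids = [f"cg{i}" for i in range(n_probes)]
        mod = empirical_bayes_moderate(fit)
        assert 3.0 <= mod.df_prior <= 5.0
        assert 0.9 <= mod.s2_prior <= 1.1

    def test_identical_variances_hit_infinite_branch(self):
        fit = self._null_fit(n_probes=50)
        fit.sigma2 = np.full(50, 1.3)
        mod = empirical_bayes_moderate(fit)
        assert np.isinf(mod.df_prior)
        np.testing.assert_allclose(mod.s2_post, mod.s2_post[0])

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in [1e-4, 0.01, 0.5, 2.0, 50.0]:
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-5)

    def test_matches_limma_oracle(self, tmp_path):
        """Moderated t, prior df and prior variance agree with the
        Bioconductor limma reference on a shared small dataset."""
        rng = np.random.default_rng(8)
        n_probes, n1, n2 = 80, 7, 6
        table = _two_group_table(n1, n2, seed=5)
        Y = rng.standard_normal((n_probes, n1 + n2)) * rng.uniform(0.4, 1.8, n_probes)[:, None]
        Y[:10, :n1] += 1.0
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(n_probes)], columns=table.sample_ids)
        fit = empirical_bayes_moderate(
            fit_probewise_models(m, table, DesignSpec(contrast="group_patient"))
        )

        m.to_csv(tmp_path / "y.csv")
        pd.DataFrame({"grp": table.df["group_patient"].to_numpy()}).to_csv(
            tmp_path / "d.csv", index=False
        )
        rscript = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))
        grp <- read.csv("{tmp_path}/d.csv")$grp
        design <- model.matrix(~grp)
        fit <- eBayes(lmFit(y, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], s2post=fit$s2.post)
        write.csv(out, "{tmp_path}/limma.csv", row.names=FALSE)
        cat(fit$df.prior, fit$s2.prior, sep="\\n")
        """
        res = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        d0_r, s02_r = (float(x) for x in res.stdout.split())
        limma = pd.read_csv(tmp_path / "limma.csv")
        assert fit.df_prior == pytest.approx(d0_r, rel=1e-4)
        assert fit.s2_prior == pytest.approx(s02_r, rel=1e-4)
        np.testing.assert_allclose(fit.t, limma["t"], rtol=1e-5)
        np.testing.assert_allclose(fit.p, limma["p"], rtol=1e-5)


def _bh_oracle(p):
    """Brute-force step-up: q_i = min over the sorted tail of m*p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_all_equal_ties_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.01] * 10), [0.01] * 10)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5)

    def test_exhaustive_oracle_small_grids(self):
        grid = [0.001, 0.02, 0.2, 0.6, 1.0]
        for length in range(1, 5):
            for combo in itertools.product(grid, repeat=length):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), _bh_oracle(list(combo)), atol=1e-12
                )

    def test_never_decreases_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestInteractionAndSubgroup:
    def test_null_interaction_calibrated(self):
        cfg = SimulationConfig(n_patients=80, n_controls=60, n_probes=600,
                               n_control_probes=20, batch_sd=0.0, seed=30)
        matrix, table, ann, _ = simulate_cohort(cfg)
        m_vals = beta_to_m(matrix.subset_probes(ann.biological_probes()).beta)
        tdf = table.df.copy()
        tdf["group_patient"] = (tdf["group"] == "patient").astype(float)
        work = SampleTable(tdf)
        spec = DesignSpec(contrast="group_patient", covariates=["sex", "age_exposure"])
        p = interaction_scan(m_vals, work, spec, "age_exposure")
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < 4 * se
        # and the null interaction p-values look uniform
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_age_dependent_effect_detected(self):
        """A group-specific slope in age powers the interaction test."""
        rng = np.random.default_rng(31)
        n1 = n2 = 100
        table = _two_group_table(n1, n2, seed=31)
        age = table.df["age_exposure"].to_numpy()
        grp = table.df["group_patient"].to_numpy()
        delta_slope = 0.15
        Y = rng.standard_normal((40, n1 + n2)) * 0.5 + delta_slope * age * grp
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(40)], columns=table.sample_ids)
        spec = DesignSpec(contrast="group_patient", covariates=["age_exposure"])
        p = interaction_scan(m, table, spec, "age_exposure")
        assert (p < 0.05).mean() > 0.8

    def test_gc_aggravation_ranks_lowest(self):
        cfg = SimulationConfig(
            n_patients=120, n_controls=60, n_probes=200, n_control_probes=20,
            batch_sd=0.0, gc_fraction=0.4,
            gc_spike_table=[(i, 0.06, -1) for i in range(5)],
            seed=32,
        )
        matrix, table, ann, _ = simulate_cohort(cfg)
        m_vals = beta_to_m(matrix.subset_probes(ann.biological_probes()).beta)
        spec = DesignSpec(contrast="gc_treated", covariates=["sex", "age_exposure"])
        res = gc_subgroup_contrast(m_vals, table, spec)
        top5 = set(res.nsmallest(5, "p_gc").index)
        assert top5 == {f"cg{i:08d}" for i in range(5)}
        # coefficient signs match the simulated hypomethylating aggravation
        assert (res.loc[sorted(top5), "coef_gc"] < 0).all()

    def test_gc_contrast_needs_both_arms(self, tiny_samples):
        df = tiny_samples.df.copy()
        df.loc[df["group"] == "patient", "gc_treated"] = True
        m = pd.DataFrame(np.random.default_rng(0).standard_normal((3, len(df))),
                         index=["a", "b", "c"], columns=df.index)
        with pytest.raises(ValueError, match="treated and untreated"):
            gc_subgroup_contrast(m, SampleTable(df), DesignSpec(contrast="gc_treated"))


class TestDescriptives:
    def test_abs_mean_beta_diff_arithmetic(self):
        beta = pd.DataFrame(
            [[0.50, 0.50, 0.52, 0.52], [0.3, 0.3, 0.3, 0.3]],
            index=["cgA", "cgB"],
            columns=["p1", "p2", "c1", "c2"],
        )
        groups = pd.Series(["patient", "patient", "control", "control"], index=beta.columns)
        d = abs_mean_beta_diff(beta, groups)
        assert d["cgA"] == pytest.approx(0.02)
        assert d["cgB"] == 0.0
        shuffled = abs_mean_beta_diff(beta[["c2", "p1", "c1", "p2"]], groups)
        pd.testing.assert_series_equal(d, shuffled)

    def test_empty_group_rejected(self):
        beta = pd.DataFrame([[0.5]], index=["cgA"], columns=["p1"])
        with pytest.raises(ValueError, match="nonempty"):
            abs_mean_beta_diff(beta, pd.Series(["patient"], index=["p1"]))

    def test_single_row_summary_has_no_sd(self):
        df = load_table2_fixture().iloc[:1]
        s = summarize_dmps(df)
        assert s["n_dmps"] == 1
        assert s["sd_abs_diff_pct"] is None
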