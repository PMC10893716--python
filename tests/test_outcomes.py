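import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hpameth.io import SampleTable
from hpameth.outcomes import (
    CvConfig,
    RobustnessResult,
    cv_robustness,
    fisher_combine,
    fit_outcome_model,
    label_direction,
    robustness_matrix,
)


def _patient_table(n, seed=0, outcome=None, name="iq"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "group": "patient",
            "age_exposure": rng.uniform(0.5, 10, n),
            "sex": rng.choice(["male", "female"], n),
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="sample_id"),
    )
    if outcome is not None:
        df[f"outcome_{name}"] = outcome
    return SampleTable(df)


class TestFitOutcomeModel:
    def test_exact_linear_relationship_recovered(self):
        rng = np.random.default_rng(1)
        n = 50
        m = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)], name="cgX")
        table = _patient_table(n, seed=1)
        y = 5.0 + 2.0 * m.to_numpy() + 0.5 * table.df["age_exposure"].to_numpy()
        table.df["outcome_iq"] = y
        coef, p = fit_outcome_model("iq", m, table, ["age_exposure"])
        assert coef == pytest.approx(2.0, abs=1e-8)
        assert p < 1e-10

    def test_matches_scipy_simple_regression(self):
        # no covariates: coefficient equals scipy.stats.linregress slope/p
        rng = np.random.default_rng(2)
        n = 40
        m = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)], name="cgX")
        y = 1.0 + 0.3 * m.to_numpy() + rng.standard_normal(n)
        table = _patient_table(n, seed=2, outcome=y)
        coef, p = fit_outcome_model("iq", m, table, [])
        lr = stats.linregress(m.to_numpy(), y)
        assert coef == pytest.approx(lr.slope, rel=1e-10)
        assert p == pytest.approx(lr.pvalue, rel=1e-8)

    def test_missing_outcomes_dropped(self):
        rng = np.random.default_rng(3)
        n = 30
        m = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)], name="cgX")
        y = 2.0 * m.to_numpy() + rng.standard_normal(n) * 0.1
        y[:5] = np.nan
        table = _patient_table(n, seed=3, outcome=y)
        coef, _ = fit_outcome_model("iq", m, table, [])
        # oracle on the complete cases only
        lr = stats.linregress(m.to_numpy()[5:], y[5:])
        assert coef == pytest.approx(lr.slope, rel=1e-10)

    def test_constant_outcome_rejected(self):
        n = 20
        m = pd.Series(np.arange(n, dtype=float), index=[f"p{i}" for i in range(n)], name="cgX")
        table = _patient_table(n, outcome=np.ones(n))
        with pytest.raises(ValueError, match="constant"):
            fit_outcome_model("iq", m, table, [])

    def test_unknown_outcome_rejected(self):
        n = 20
        m = pd.Series(np.zeros(n), index=[f"p{i}" for i in range(n)], name="cgX")
        table = _patient_table(n)
        with pytest.raises(ValueError, match="unknown outcome"):
            fit_outcome_model("nope", m, table, [])


class TestFisherCombine:
    def test_all_ones_give_zero_statistic(self):
        stat, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0
        assert df == 6
        assert p == 1.0

    def test_single_p_identity(self):
        # with one p-value Fisher's method returns that p exactly
        for p0 in [0.01, 0.2, 0.77]:
            _, _, p = fisher_combine([p0])
            assert p == pytest.approx(p0, rel=1e-12)

    def test_hand_computed_ten_halves(self):
        stat, df, p = fisher_combine([0.5] * 10)
        assert stat == pytest.approx(20 * np.log(2), rel=1e-12)
        assert df == 20
        assert p == pytest.approx(stats.chi2.sf(20 * np.log(2), 20), rel=1e-12)

    def test_zero_pvalue_clipped_not_crash(self, caplog):
        stat, _, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(stat)
        assert 0 <= p <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])

    def test_null_uniformity_monte_carlo(self):
        """Combined p of k independent uniforms is itself uniform."""
        rng = np.random.default_rng(9)
        combined = np.array(
            [fisher_combine(rng.uniform(size=10))[2] for _ in range(1500)]
        )
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestCvRobustness:
    def _strong_pair(self, n=200, noise=0.05, seed=4):
        rng = np.random.default_rng(seed)
        m = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)], name="cgX")
        table = _patient_table(n, seed=seed)
        y = 3.0 * m.to_numpy() + noise * rng.standard_normal(n)
        table.df["outcome_iq"] = y
        return m, table

    def test_near_deterministic_signal_fully_robust(self):
        m, table = self._strong_pair()
        res = cv_robustness("iq", m, table, ["age_exposure"],
                            CvConfig(n_iterations=20, seed=1))
        assert res.pct_iterations_significant == 100.0
        assert res.robust
        assert res.mean_coefficient == pytest.approx(3.0, abs=0.05)

    def test_seed_determinism_and_order_independence(self):
        m, table = self._strong_pair(n=80, noise=2.0)
        cfg = CvConfig(n_iterations=15, seed=7)
        a = cv_robustness("iq", m, table, ["age_exposure"], cfg)
        b = cv_robustness("iq", m, table, ["age_exposure"], cfg)
        assert a.pct_iterations_significant == b.pct_iterations_significant
        assert a.mean_coefficient == b.mean_coefficient

    def test_null_pair_rarely_significant(self):
        rng = np.random.default_rng(11)
        n = 100
        m = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)], name="cgN")
        table = _patient_table(n, seed=11, outcome=rng.standard_normal(n))
        res = cv_robustness("iq", m, table, [], CvConfig(n_iterations=100, seed=2))
        # binomial(100, 0.05): values above 15 are essentially impossible
        assert res.pct_iterations_significant <= 15.0

    def test_fold_size_too_small_rejected(self):
        m, table = self._strong_pair(n=30)
        with pytest.raises(ValueError, match="fold size"):
            cv_robustness("iq", m, table, ["age_exposure", "sex"],
                          CvConfig(k_folds=10, n_iterations=2))

    def test_train_test_predict_mode_runs(self):
        m, table = self._strong_pair(n=100, noise=0.5)
        res = cv_robustness("iq", m, table, ["age_exposure"],
                            CvConfig(n_iterations=10, seed=3,
                                     fold_p_mode="train_test_predict"))
        assert res.pct_iterations_significant == 100.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CvConfig(k_folds=1)
        with pytest.raises(ValueError):
            CvConfig(fold_p_mode="bootstrap")


class TestLabelDirection:
    def _res(self, coef, p=0.001):
        return RobustnessResult("cgX", "iq", coef, p, 100.0)

    @pytest.mark.parametrize(
        "abnormality,coef,higher_better,expected",
        [
            # Hypo patients: shift = -coef
            ("Hypo", -1.0, True, "B"),   # shift +, higher better  -> benefit
            ("Hypo", -1.0, False, "H"),
            ("Hypo", 1.0, True, "H"),    # shift -, higher better  -> harm
            ("Hypo", 1.0, False, "B"),
            # Hyper patients: shift = +coef
            ("Hyper", 1.0, True, "B"),
            ("Hyper", 1.0, False, "H"),
            ("Hyper", -1.0, True, "H"),
            ("Hyper", -1.0, False, "B"),
        ],
    )
    def test_truth_table(self, abnormality, coef, higher_better, expected):
        assert label_direction(self._res(coef), abnormality, higher_better) == expected

    def test_polarity_flip_symmetry(self):
        r = self._res(0.7)
        for ab in ("Hypo", "Hyper"):
            a = label_direction(r, ab, True)
            b = label_direction(r, ab, False)
            assert {a, b} == {"B", "H"}

    def test_non_significant_is_none(self):
        assert label_direction(self._res(1.0, p=0.2), "Hypo", True) == "none"

    def test_zero_coefficient_warns_none(self):
        with pytest.warns(UserWarning, match="zero mean coefficient"):
            assert label_direction(self._res(0.0), "Hypo", True) == "none"

    def test_bad_abnormality_rejected(self):
        with pytest.raises(ValueError):
            label_direction(self._res(1.0), "Sideways", True)


class TestRobustnessMatrix:
    def _results(self):
        return [
            RobustnessResult("cgA", "iq", -0.5, 0.01, 100.0, "B"),
            RobustnessResult("cgA", "pedsql", 0.2, 0.30, 40.0, "none"),
            RobustnessResult("cgB", "iq", 0.9, 0.02, 95.0, "H"),
        ]

    def test_matrix_shape_and_counts(self):
        pct, labels, counts = robustness_matrix(self._results())
        assert pct.shape == (2, 2)
        assert pct.loc["cgA", "iq"] == 100.0
        assert np.isnan(pct.loc["cgB", "pedsql"])
        assert labels.loc["cgB", "iq"] == "H"
        assert counts["n_pairs"] == 3
        assert counts["n_significant"] == 2
        assert counts["n_robust"] == 1  # cgB significant but not 100%
        assert counts["pct_robust_of_significant"] == 50.0

    def test_input_order_invariance(self):
        a = robustness_matrix(self._results())
        b = robustness_matrix(list(reversed(self._results())))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_duplicate_pair_rejected(self):
        results = self._results() + [RobustnessResult("cgA", "iq", 0.0, 1.0, 0.0)]
        with pytest.raises(ValueError, match="duplicate"):
            robustness_matrix(results)

    def test_no_significant_pairs_pct_none(self):
        _, _, counts = robustness_matrix(
            [RobustnessResult("cgA", "iq", 0.1, 0.5, 10.0)]
        )
        assert counts["pct_robust_of_significant"] is None
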