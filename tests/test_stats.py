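"""Oracle and simulation checks for the statistical pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from korosound.stats import (
    bonferroni_alpha,
    compare_groups,
    fit_adjusted,
    fit_logistic,
    hosmer_lemeshow,
    logistic_derived,
    pearson_with_power,
)


@pytest.mark.parametrize(
    "family,m,expected",
    [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
)
def test_bonferroni_alpha(family, m, expected):
    assert bonferroni_alpha(family, m) == pytest.approx(expected, abs=1e-15)


def test_bonferroni_alpha_validation():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_alpha(1.5, 10)


class TestCompareGroups:
    def _table(self, g1, g2, name="f"):
        df = pd.DataFrame({name: np.concatenate([g1, g2])})
        labels = ["a"] * len(g1) + ["b"] * len(g2)
        return df, labels

    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df, labels = self._table(g, g.copy())
        res = compare_groups(df, labels)[0]
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        assert not res.significant

    def test_toy_pooled_t_against_scipy_oracle(self):
        """g1=(1,2,3,4), g2=(3,4,5,6): pooled t = -2.1909, d = -1.5492,
        p = 0.0710 (standard pooled-variance formulas, df = 6)."""
        df, labels = self._table(np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6]))
        res = compare_groups(df, labels)[0]
        assert res.test == "pooled t"
        assert res.t == pytest.approx(-2.1908902, abs=1e-6)
        assert res.cohens_d == pytest.approx(-1.5491933, abs=1e-6)
        assert res.p == pytest.approx(0.0709877, abs=1e-6)

    def test_welch_selected_under_variance_heterogeneity(self):
        """Groups drawn with the envelope-skewness moments of the two age
        cohorts (SD ratio ~2, n = 123/112): Levene rejects and Welch is
        chosen in >= 9/10 seeds."""
        chosen = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g1 = rng.normal(0.231, 0.689, 123)
            g2 = rng.normal(-0.802, 1.371, 112)
            df, labels = self._table(g1, g2)
            chosen += compare_groups(df, labels)[0].test == "Welch t"
        assert chosen >= 9

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(0, 1, 20), rng.normal(0.5, 1.3, 25)
        df1, l1 = self._table(g1, g2)
        fwd = compare_groups(df1, l1)[0]
        df2 = pd.DataFrame({"f": np.concatenate([g2, g1])})
        rev = compare_groups(df2, ["b"] * 25 + ["a"] * 20)[0]
        assert rev.t == pytest.approx(-fwd.t, rel=1e-9)
        assert rev.cohens_d == pytest.approx(-fwd.cohens_d, rel=1e-9)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"u": rng.normal(size=30), "v": rng.normal(1, 2, 30)})
        labels = ["a"] * 15 + ["b"] * 15
        res1 = {r.feature: r.p for r in compare_groups(df, labels)}
        res2 = {r.feature: r.p for r in compare_groups(df[["v", "u"]], labels)}
        assert res1 == res2

    def test_familywise_error_controlled_under_null(self):
        """10 identically-distributed features, Bonferroni at 0.05: the
        family-wise false-flag rate stays near/below 0.05."""
        reps, fwe = 400, 0
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            df = pd.DataFrame(rng.normal(size=(60, 10)))
            labels = ["a"] * 30 + ["b"] * 30
            fwe += any(r.significant for r in compare_groups(df, labels))
        rate = fwe / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestLogistic:
    def test_table_transform_arithmetic(self):
        """coef -0.879, SE 0.237: OR 0.415, CI [0.261, 0.660], Wald 13.76."""
        eff = logistic_derived(-0.879, 0.237)
        assert eff.odds_ratio == pytest.approx(0.415, abs=5e-4)
        assert eff.ci95[0] == pytest.approx(0.261, abs=5e-4)
        assert eff.ci95[1] == pytest.approx(0.660, abs=1e-3)
        assert eff.wald_chi2 == pytest.approx((0.879 / 0.237) ** 2, rel=1e-12)

    def test_saturated_2x2_matches_contingency_odds_ratio(self):
        """Balanced 2x2 with cross-product ratio 4: slope = ln 4."""
        x = np.repeat([0, 0, 1, 1], [40, 20, 20, 40]).reshape(-1, 1)
        y = np.concatenate([np.zeros(40), np.ones(20), np.zeros(20), np.ones(40)])
        fit = fit_logistic(pd.DataFrame({"x": x[:, 0]}), y)
        assert fit.predictors[0].coef == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.predictors[0].odds_ratio == pytest.approx(4.0, abs=1e-5)

    def test_label_flip_negates_coefficients(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        logit = 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(200) < 1 / (1 + np.exp(-logit))).astype(int)
        f1 = fit_logistic(X, y)
        f2 = fit_logistic(X, 1 - y)
        for p1, p2 in zip(f1.predictors, f2.predictors):
            assert p2.coef == pytest.approx(-p1.coef, abs=1e-6)
            assert p2.odds_ratio == pytest.approx(1 / p1.odds_ratio, rel=1e-5)

    def test_fit_invariants(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=300)})
        y = (rng.random(300) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        fit = fit_logistic(X, y)
        for p in fit.predictors:
            assert p.odds_ratio == pytest.approx(np.exp(p.coef), rel=1e-12)
            assert p.wald_chi2 == pytest.approx((p.coef / p.se) ** 2, rel=1e-12)
            assert p.ci95[0] < p.odds_ratio < p.ci95[1]
        assert 0 <= fit.accuracy <= 1

    def test_perfect_separation_raises(self):
        X = pd.DataFrame({"x": np.concatenate([np.arange(10), np.arange(20, 30)]).astype(float)})
        y = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(ValueError, match="separation|failed"):
            fit_logistic(X, y)


class TestHosmerLemeshow:
    def test_precondition_on_sample_size(self):
        with pytest.raises(ValueError, match="n >="):
            hosmer_lemeshow(np.full(15, 0.5), np.zeros(15), n_groups=10)

    def test_type_i_error_near_nominal(self):
        """Refit-per-replicate calibration: rejection rate in (0.03, 0.08)
        at alpha = 0.05 (200 replicates, n = 500)."""
        rejects = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(500, 2))
            logits = 0.8 * x[:, 0] - 0.6 * x[:, 1]
            y = (rng.random(500) < 1 / (1 + np.exp(-logits))).astype(int)
            fit = fit_logistic(pd.DataFrame(x, columns=["a", "b"]), y)
            rejects += fit.hosmer_lemeshow[1] < 0.05
        assert 0.03 * reps <= rejects <= 0.08 * reps + 2 * np.sqrt(reps * 0.05 * 0.95)

    def test_miscalibration_detected(self):
        """Swapping p for 1-p on a steep model is rejected almost surely."""
        rejects = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=1000)
            p = 1 / (1 + np.exp(-2.0 * x))
            y = (rng.random(1000) < p).astype(int)
            chi2, pval = hosmer_lemeshow(1 - p, y)
            rejects += pval < 0.05
        assert rejects >= 18


class TestPearsonWithPower:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = pearson_with_power(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_toy_vectors_oracle(self):
        """x=(1..5), y=(2,1,4,3,5): r = 0.8, p = 0.1041 by the t transform."""
        res = pearson_with_power(np.arange(1.0, 6.0), np.array([2.0, 1, 4, 3, 5]))
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.p == pytest.approx(0.1041, abs=1e-4)

    def test_fisher_z_power_closed_form(self):
        """r = 0.5, n = 84, alpha = 0.05 -> power ~ 0.9986."""
        rng = np.random.default_rng(0)
        # construct data with sample r exactly 0.5 by orthogonal projection
        x = rng.normal(size=84)
        xc = x - x.mean()
        e = rng.normal(size=84)
        ec = e - e.mean()
        ec -= xc * (ec @ xc) / (xc @ xc)
        y = 0.5 * xc / np.sqrt(xc @ xc) + np.sqrt(0.75) * ec / np.sqrt(ec @ ec)
        res = pearson_with_power(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-10)
        assert res.power == pytest.approx(0.9986, abs=2e-3)

    def test_null_p_values_uniform(self):
        """Under independence, p-values pass a KS uniformity check."""
        rng = np.random.default_rng(7)
        pvals = [
            pearson_with_power(rng.normal(size=30), rng.normal(size=30)).p
            for _ in range(2000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_power(np.ones(10), np.arange(10.0))


class TestFitAdjusted:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        data = pd.DataFrame(
            {
                "y": np.random.default_rng(0).normal(size=n),
                "f": np.cos(2 * np.pi * t / n),
                "age": np.cos(4 * np.pi * t / n),
                "diabetes": np.cos(6 * np.pi * t / n),
                "bmi": np.cos(8 * np.pi * t / n),
                "sbp": np.cos(10 * np.pi * t / n),
            }
        )
        fit = fit_adjusted(data, "y", "f", binary=())
        for v in fit.vif.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_collinearity_error(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {
                "y": rng.normal(size=50),
                "f": rng.normal(size=50),
                "age": rng.normal(size=50),
                "bmi": rng.normal(size=50),
                "sbp": rng.normal(size=50),
            }
        )
        data["diabetes"] = data["age"]
        with pytest.raises(ValueError, match="collinear"):
            fit_adjusted(data, "y", "f", binary=())

    def test_recovers_hospital_ground_truth(self):
        """Hospital-preset metadata at n = 400: adjusted model recovers the
        latent-driven association and keeps all VIF < 5."""
        from korosound.synth import PRESETS, generate_cohort

        _, subjects, params = generate_cohort("hospital", 400, seed=13)
        data = pd.DataFrame(
            {
                "bapwv": [s.bapwv for s in subjects],
                "latent": [p.latent_stiffness for p in params],
                "age": [s.age for s in subjects],
                "diabetes": [float(s.diabetes) for s in subjects],
                "bmi": [s.bmi for s in subjects],
                "sbp": [s.sbp for s in subjects],
            }
        )
        fit = fit_adjusted(data, "bapwv", "latent")
        assert all(v < 5 for v in fit.vif.values())
        assert fit.p["latent"] < 0.001
        assert fit.std_beta["latent"] > 0
        assert 0 < fit.adj_r2 <= 1
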