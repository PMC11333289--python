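"""Clock application, age regression, group tests and plateau fits."""

import numpy as np
import pandas as pd
import pytest

import eaclock as ea
from eaclock import clocks


def _bm(beta, samples=None, chrom="chr1"):
    beta = np.asarray(beta, dtype=float)
    samples = samples or [f"s{i}" for i in range(beta.shape[1])]
    sites = pd.DataFrame({"chrom": [chrom] * len(beta), "pos": range(len(beta))})
    return ea.BetaMatrix(sites, samples, beta)


class TestApplyClock:
    def test_weighted_linear_form(self):
        bm = _bm([[0.5], [0.5]])
        model = ea.ClockModel("weighted", ["chr1:0", "chr1:1"],
                              weights=[2.0, -1.0], intercept=10.0)
        out = ea.apply_clock(bm, model)
        assert out["score"].iloc[0] == pytest.approx(10.5)

    def test_mean_model(self):
        bm = _bm(np.full((35, 2), 0.3))
        model = ea.ClockModel("mean", [f"chr1:{i}" for i in range(35)])
        out = ea.apply_clock(bm, model)
        assert np.allclose(out["score"], 0.3)

    def test_algebraic_inversion_recovers_target_age(self, rng):
        """Random weights with betas constructed so the closed form gives 42."""
        n = 20
        w = rng.normal(size=n)
        beta0 = rng.uniform(0, 1, size=n)
        intercept = 42.0 - float(w @ beta0)
        model = ea.ClockModel("weighted", [f"chr1:{i}" for i in range(n)],
                              weights=w, intercept=intercept)
        out = ea.apply_clock(_bm(beta0[:, None]), model)
        assert out["score"].iloc[0] == pytest.approx(42.0, abs=1e-9)

    def test_scores_may_be_negative(self):
        bm = _bm([[1.0]])
        model = ea.ClockModel("weighted", ["chr1:0"], weights=[-50.0], intercept=10.0)
        out = ea.apply_clock(bm, model)
        assert out["score"].iloc[0] == pytest.approx(-40.0)

    def test_linearity_in_beta(self, rng):
        n = 10
        w = rng.normal(size=n)
        model = ea.ClockModel("weighted", [f"chr1:{i}" for i in range(n)],
                              weights=w, intercept=3.0)
        b1 = rng.uniform(0, 1, size=n)
        b2 = rng.uniform(0, 1, size=n)
        alpha = 0.3
        s = lambda b: ea.apply_clock(_bm(b[:, None]), model)["score"].iloc[0]
        mixed = s(alpha * b1 + (1 - alpha) * b2)
        assert mixed == pytest.approx(alpha * s(b1) + (1 - alpha) * s(b2), abs=1e-10)

    def test_impute_uses_reference_mean(self):
        bm = _bm([[0.5]])
        model = ea.ClockModel("weighted", ["chr1:0", "chrX:99"],
                              weights=[1.0, 1.0], intercept=0.0,
                              reference={"chrX:99": 0.25})
        out = ea.apply_clock(bm, model, missing_policy="impute", max_missing_frac=0.6)
        assert out["score"].iloc[0] == pytest.approx(0.75)
        assert out["n_sites_imputed"].iloc[0] == 1

    def test_impute_errors_beyond_max_missing(self):
        bm = _bm([[0.5]])
        model = ea.ClockModel("weighted", ["chr1:0", "chrX:99"],
                              weights=[1.0, 1.0], reference={"chrX:99": 0.25})
        with pytest.raises(ValueError, match="missing fraction"):
            ea.apply_clock(bm, model, missing_policy="impute", max_missing_frac=0.2)

    def test_drop_policy_uses_covered_sites_only(self):
        beta = np.array([[0.5], [np.nan]])
        bm = ea.BetaMatrix(pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [0, 1]}),
                           ["s0"], beta)
        model = ea.ClockModel("mean", ["chr1:0", "chr1:1"])
        out = ea.apply_clock(bm, model, missing_policy="drop")
        assert out["score"].iloc[0] == pytest.approx(0.5)
        assert out["n_sites_used"].iloc[0] == 1

    def test_error_policy_raises_on_missing(self):
        bm = _bm([[0.5]])
        model = ea.ClockModel("mean", ["chr1:0", "chr9:5"])
        with pytest.raises(ValueError, match="missing"):
            ea.apply_clock(bm, model, missing_policy="error")

    def test_clock_tsv_roundtrip(self, tmp_path, rng):
        model = ea.ClockModel("weighted", [f"chr{i}:{i * 7}" for i in range(5)],
                              weights=rng.normal(size=5), intercept=-1.25, name="toy")
        p = tmp_path / "toy.tsv"
        clocks.write_clock(model, p)
        back = clocks.read_clock(p)
        assert back.kind == "weighted" and back.name == "toy"
        assert back.sites == model.sites
        assert np.array_equal(back.weights, model.weights)
        assert back.intercept == model.intercept


class TestAgeRegression:
    def test_exact_line(self):
        ages = pd.Series({f"s{i}": float(i) for i in range(6)})
        scores = pd.Series({k: 0.1 * v + 0.2 for k, v in ages.items()})
        fit = ea.fit_age_regression(scores, ages)
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(0.2)
        assert fit.r == pytest.approx(1.0)

    def test_shuffled_ages_destroy_correlation(self, rng):
        x = np.arange(40, dtype=float)
        y = 0.1 * x + 0.2
        ids = [f"s{i}" for i in range(40)]
        perm = rng.permutation(40)
        fit = ea.fit_age_regression(pd.Series(y, index=ids),
                                    pd.Series(x[perm], index=ids))
        assert abs(fit.r) < 0.4
        assert np.isfinite(fit.slope)

    def test_r_squared_consistency_and_order_invariance(self, rng):
        ids = [f"s{i}" for i in range(20)]
        x = pd.Series(rng.uniform(0, 10, 20), index=ids)
        y = pd.Series(0.5 * x + rng.normal(0, 1, 20), index=ids)
        f1 = ea.fit_age_regression(y, x)
        shuffled = list(rng.permutation(ids))
        f2 = ea.fit_age_regression(y.loc[shuffled], x)
        assert f1.r**2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)

    def test_se_band_matches_closed_form(self):
        ids = list("abcdefgh")
        x = pd.Series(np.arange(8.0), index=ids)
        y = pd.Series([0.1, 0.3, 0.2, 0.5, 0.4, 0.7, 0.6, 0.9], index=ids)
        fit = ea.fit_age_regression(y, x)
        xv, yv = x.to_numpy(), y.to_numpy()
        resid = yv - fit.predict(xv)
        s2 = (resid**2).sum() / (len(xv) - 2)
        expect = np.sqrt(s2 * (1 / len(xv) + (xv - xv.mean()) ** 2
                               / ((xv - xv.mean()) ** 2).sum()))
        assert np.allclose(fit.se_fit(xv), expect)

    def test_degenerate_inputs_raise(self):
        ages = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        scores = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        with pytest.raises(ValueError, match="zero age variance"):
            ea.fit_age_regression(scores, ages)
        with pytest.raises(ValueError, match="at least 3"):
            ea.fit_age_regression(scores.iloc[:2], pd.Series({"a": 1.0, "b": 2.0}))


class TestCompareGroups:
    def test_identical_groups(self):
        s = pd.Series({"a0": 1.0, "a1": 2.0, "b0": 1.0, "b1": 2.0})
        g = pd.Series({"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        out = ea.compare_groups(s, g)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(11)
        s = pd.Series(np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)]),
                      index=[f"x{i}" for i in range(20)])
        g = pd.Series(["A"] * 10 + ["B"] * 10, index=s.index)
        out = ea.compare_groups(s, g)
        assert out["p"].iloc[0] < 1e-6
        assert out["t"].iloc[0] > 0  # B minus A orientation

    def test_welch_vs_pooled_differ_under_variance_imbalance(self):
        s = pd.Series([0.0, 1.0, 2.0, 10.0, 30.0, -10.0, 21.0],
                      index=[f"x{i}" for i in range(7)])
        g = pd.Series(["A"] * 3 + ["B"] * 4, index=s.index)
        welch = ea.compare_groups(s, g)["p"].iloc[0]
        pooled = ea.compare_groups(s, g, pooled=True)["p"].iloc[0]
        assert welch != pooled

    def test_small_group_rejected(self):
        s = pd.Series({"a0": 1.0, "b0": 1.0, "b1": 2.0})
        g = pd.Series({"a0": "A", "b0": "B", "b1": "B"})
        with pytest.raises(ValueError):
            ea.compare_groups(s, g)


class TestPlateau:
    def test_linear_data_prefers_line_within_two_aic(self):
        ids = [f"s{i}" for i in range(10)]
        x = pd.Series(np.linspace(0, 10, 10), index=ids)
        y = 0.3 * x + 1.0
        fit = ea.fit_plateau(y, x)
        assert 0.0 <= fit.delta_aic <= 2.0 + 1e-9

    def test_recovers_true_saturation_rate(self):
        ids = [f"s{i}" for i in range(30)]
        x = pd.Series(np.linspace(0, 3, 30), index=ids)
        c_true = 3.0  # saturates within one age unit
        y = 0.1 + 0.5 * (1 - np.exp(-c_true * x))
        fit = ea.fit_plateau(pd.Series(y.to_numpy(), index=ids), x)
        assert fit.converged
        assert fit.c == pytest.approx(c_true, abs=1e-3)
        assert fit.delta_aic < -4
        assert fit.saturation_age == pytest.approx(-np.log(0.05) / c_true, rel=1e-3)

    def test_too_few_points_rejected(self):
        ids = list("abcd")
        x = pd.Series([0.0, 1, 2, 3], index=ids)
        with pytest.raises(ValueError):
            ea.fit_plateau(pd.Series([0.0, 1, 2, 3], index=ids), x)
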