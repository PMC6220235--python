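"""OLS fitting, AICc ranking, exhaustive selection and the Monte Carlo stage."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import fishrisk as fr
from fishrisk.errors import InputError, UndefinedResultError
from fishrisk.regression import point_estimate_r2


def make_xy(n=30, seed=0, slope=(0.2, -1.0), noise=0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "x1": rng.uniform(0, 50, n),
            "x2": rng.uniform(0.5, 3.0, n),
            "x3": rng.uniform(0, 10, n),
        },
        index=[f"C{i:03d}" for i in range(n)],
    )
    y = 1.0 + slope[0] * X["x1"] + slope[1] * X["x2"] + rng.normal(0, noise, n)
    return X, pd.Series(y, index=X.index)


class TestAicc:
    def test_hand_evaluated_formula(self):
        # RSS=10, n=20, p=3 coefficients -> k=4:
        # 20*ln(0.5) + 8 + 2*4*5/15
        expected = 20 * math.log(0.5) + 8 + 40 / 15
        assert fr.aicc(10.0, 20, 3) == pytest.approx(expected, rel=1e-12)

    def test_penalty_monotone_in_parameters(self):
        assert fr.aicc(10.0, 20, 2) < fr.aicc(10.0, 20, 3)

    def test_correction_vanishes_at_large_n(self):
        n = 10_000_000
        aic = n * math.log(5.0 / n) + 2 * 3
        assert fr.aicc(5.0, n, 2) == pytest.approx(aic, abs=1e-4)

    def test_too_few_observations_undefined(self):
        with pytest.raises(UndefinedResultError):
            fr.aicc(1.0, 5, 3)

    def test_perfect_fit_dominates(self):
        assert fr.aicc(0.0, 20, 2) == -math.inf


class TestFitOls:
    def test_exact_linear_response_gives_r2_one(self):
        X, _ = make_xy(20, seed=1)
        y = 2.0 + 3.0 * X["x1"]
        fit = fr.fit_ols(y, X[["x1"]])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients["x1"] == pytest.approx(3.0)

    def test_constant_response_flagged_not_nan(self):
        X, _ = make_xy(20, seed=2)
        y = pd.Series(1.5, index=X.index)
        fit = fr.fit_ols(y, X[["x1"]])
        assert fit.zero_tss and fit.r2 == 0.0

    def test_collinear_design_names_columns(self):
        X, y = make_xy(20, seed=3)
        X = X.assign(dup=2.0 * X["x1"])
        with pytest.raises(InputError, match="dup"):
            fr.fit_ols(y, X[["x1", "dup"]])

    def test_missing_values_rejected(self):
        X, y = make_xy(10, seed=4)
        y.iloc[0] = np.nan
        with pytest.raises(InputError):
            fr.fit_ols(y, X[["x1"]])

    def test_aicc_invariant_to_predictor_rescaling(self):
        X, y = make_xy(25, seed=5)
        f1 = fr.fit_ols(y, X[["x1", "x2"]])
        X2 = X.assign(x1=X["x1"] * 1000.0 + 7.0)
        f2 = fr.fit_ols(y, X2[["x1", "x2"]])
        assert f2.aicc == pytest.approx(f1.aicc)
        assert f2.r2 == pytest.approx(f1.r2)


class TestSelectModel:
    @staticmethod
    def tables(n=20, seed=0):
        X, y = make_xy(n, seed=seed)
        slavery = pd.DataFrame(
            {"prevalence_per_1000": y, "ci95_low": y * 0.8, "ci95_high": y * 1.2}
        )
        return X, slavery

    def test_single_candidate_returned(self):
        X, slavery = self.tables()
        best, table = fr.select_model(X, slavery, candidates=("x1",), exclusions=())
        assert best.predictors == ("x1",)
        assert len(table) == 1

    def test_ranking_enumerates_all_subsets(self):
        X, slavery = self.tables()
        _, table = fr.select_model(X, slavery, candidates=("x1", "x2", "x3"), exclusions=())
        assert len(table) == 7  # 2^3 - 1

    def test_matches_brute_force_oracle(self):
        X, slavery = self.tables(seed=6)
        best, table = fr.select_model(X, slavery, candidates=("x1", "x2", "x3"), exclusions=())
        # independent enumeration with numpy lstsq + literal AICc formula
        y = slavery["prevalence_per_1000"].to_numpy()
        scores = {}
        for r in (1, 2, 3):
            for subset in combinations(("x1", "x2", "x3"), r):
                A = np.column_stack([np.ones(len(X)), X[list(subset)].to_numpy()])
                coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                rss = float(np.sum((y - A @ coef) ** 2))
                n, k = len(y), len(subset) + 2
                scores["+".join(subset)] = (
                    n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
                )
        oracle_order = sorted(scores, key=scores.get)
        assert list(table["predictors"]) == oracle_order
        assert best.predictors == tuple(oracle_order[0].split("+"))
        for name, got in zip(table["predictors"], table["aicc"]):
            assert got == pytest.approx(scores[name], rel=1e-10)

    def test_exclusion_list_removes_countries(self):
        X, slavery = self.tables()
        best_all, _ = fr.select_model(X, slavery, candidates=("x1",), exclusions=())
        best_ex, _ = fr.select_model(
            X, slavery, candidates=("x1",), exclusions=("C000", "C001")
        )
        assert best_ex.n == best_all.n - 2

    def test_irrelevant_predictor_rejected_at_large_n(self):
        X, y = make_xy(200, seed=8, noise=0.3)
        slavery = pd.DataFrame({"prevalence_per_1000": y, "ci95_low": y, "ci95_high": y})
        best, _ = fr.select_model(X, slavery, candidates=("x1", "x2", "x3"), exclusions=())
        assert best.predictors == ("x1", "x2")


class TestMonteCarlo:
    @staticmethod
    def tables(n=20, seed=0, sd_scale=1.0):
        X, y = make_xy(n, seed=seed)
        y = y - y.min() + 0.5  # prevalence is nonnegative by construction
        m = X.assign(
            sd_x1=sd_scale * 1.0, sd_x2=sd_scale * 0.1, sd_x3=sd_scale * 0.5
        )
        half = 0.3 * np.abs(y) * sd_scale
        slavery = pd.DataFrame(
            {
                "prevalence_per_1000": y,
                "ci95_low": y - half,
                "ci95_high": y + half,
            }
        )
        return m, slavery

    def test_zero_sds_reproduce_point_estimate_exactly(self):
        m, slavery = self.tables(sd_scale=0.0)
        mc = fr.monte_carlo_sensitivity(
            m, slavery, ("x1", "x2"), n_runs=50, scenario="all", seed=1, exclusions=()
        )
        point = point_estimate_r2(m, slavery, ("x1", "x2"), exclusions=())
        assert mc.n_skipped == 0
        assert np.all(mc.r2 == point)

    def test_same_seed_identical_samples(self):
        m, slavery = self.tables()
        a = fr.monte_carlo_sensitivity(m, slavery, ("x1", "x2"), 200, "all", seed=3, exclusions=())
        b = fr.monte_carlo_sensitivity(m, slavery, ("x1", "x2"), 200, "all", seed=3, exclusions=())
        assert np.array_equal(a.r2, b.r2)
        assert a.median_r2 == b.median_r2

    def test_scenarios_perturb_only_their_quantities(self):
        m, slavery = self.tables()
        point = point_estimate_r2(m, slavery, ("x1", "x2"), exclusions=())
        fish = fr.monte_carlo_sensitivity(
            m.assign(sd_x1=0.0, sd_x2=0.0), slavery, ("x1", "x2"), 50,
            "fisheries_only", seed=4, exclusions=(),
        )
        # fisheries-only with zero fisheries SDs is degenerate at the point
        assert np.all(fish.r2 == point)
        slav0 = slavery.assign(ci95_low=slavery["prevalence_per_1000"],
                               ci95_high=slavery["prevalence_per_1000"])
        slav = fr.monte_carlo_sensitivity(
            m, slav0, ("x1", "x2"), 50, "slavery_only", seed=4, exclusions=()
        )
        assert np.all(slav.r2 == point)

    def test_median_attenuates_relative_to_point_estimate(self):
        m, slavery = self.tables(n=40, seed=9)
        mc = fr.monte_carlo_sensitivity(m, slavery, ("x1", "x2"), 2000, "all", seed=5, exclusions=())
        point = point_estimate_r2(m, slavery, ("x1", "x2"), exclusions=())
        assert mc.median_r2 <= point + 0.02
        assert np.all((mc.r2 >= 0) & (mc.r2 <= 1))
        assert mc.median_r2 == pytest.approx(float(np.median(mc.r2)))

    def test_negative_sd_rejected(self):
        m, slavery = self.tables()
        with pytest.raises(InputError):
            fr.monte_carlo_sensitivity(
                m.assign(sd_x1=-1.0), slavery, ("x1",), 10, "all", seed=0, exclusions=()
            )

    def test_inverted_ci_rejected(self):
        m, slavery = self.tables()
        bad = slavery.assign(ci95_low=slavery["ci95_high"] + 1.0)
        with pytest.raises(InputError):
            fr.monte_carlo_sensitivity(m, bad, ("x1",), 10, "all", seed=0, exclusions=())


def test_planted_sign_recovery_rate():
    """Fitted signs match the planted effect directions in most replicates."""
    from conftest import planted_regression_data

    ok = 0
    reps = 20
    for seed in range(reps):
        m, slavery, prov = planted_regression_data(seed=1000 + seed)
        fit = fr.fit_ols(
            slavery["prevalence_per_1000"],
            m[["pct_unreported", "landed_value_per_kg"]],
        )
        if (
            np.sign(fit.coefficients["pct_unreported"]) == np.sign(prov["effect_unreported"])
            and np.sign(fit.coefficients["landed_value_per_kg"]) == np.sign(prov["effect_value"])
        ):
            ok += 1
    assert ok >= 0.95 * reps
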