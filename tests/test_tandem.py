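"""Least squares, stage-1 screening/dominance, stage-2 context equations."""

import numpy as np
import pandas as pd
import pytest

from tandemro.tandem import (
    CollinearityError,
    ContextEquationModel,
    DegenerateResponseError,
    DominanceScreen,
    fit_least_squares,
    load_activities,
    monitor_table,
    screen_single_descriptors,
    subset_by_property,
)


def normal_equations(X, y):
    """Independent oracle: solve (X'X) b = X'y directly."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    resid = y - Z @ beta
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    return beta, r2


class TestLeastSquares:
    def test_exact_line(self):
        x = np.arange(10.0)
        beta, r2 = fit_least_squares(x[:, None], 3 + 2 * x)
        assert beta == pytest.approx([3.0, 2.0])
        assert r2 == pytest.approx(1.0)

    def test_constant_response_rejected(self):
        with pytest.raises(DegenerateResponseError):
            fit_least_squares(np.arange(5.0)[:, None], np.ones(5))

    def test_collinearity_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=20)})
        with pytest.raises(CollinearityError) as err:
            fit_least_squares(X, rng.normal(size=20))
        assert {"a", "b"} & set(err.value.columns)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n, p = 50, int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            beta, r2 = fit_least_squares(X, y)
            beta_ref, r2_ref = normal_equations(X, y)
            assert beta == pytest.approx(beta_ref, abs=1e-8)
            assert r2 == pytest.approx(r2_ref, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        y = 1 + X @ [0.5, -1.2] + rng.normal(size=40)
        beta, r2 = fit_least_squares(X, y)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert beta == pytest.approx(fit.params, abs=1e-10)
        assert r2 == pytest.approx(fit.rsquared, abs=1e-12)


def toy_matrix(n=40, seed=1):
    rng = np.random.default_rng(seed)
    D = pd.DataFrame(
        {
            "Jurs_RNCG": rng.uniform(0.1, 0.9, n),
            "ES_Count_ssO": rng.integers(0, 4, n).astype(float),
            "ES_Sum_ssO": np.nan,
            "ES_Count_sssN": rng.integers(0, 2, n).astype(float),
            "Constant": np.ones(n),
            "Noise": rng.normal(size=n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    D["ES_Sum_ssO"] = 1.9 * D["ES_Count_ssO"] + rng.normal(0, 0.3, n)
    return D, rng


class TestScreen:
    def test_descriptor_equal_to_response_ranks_first(self):
        D, rng = toy_matrix()
        y = D["ES_Count_ssO"].rename("pEC50")
        res = screen_single_descriptors(D, y)
        assert res.index[0] == "ES_Count_ssO"
        assert res["r2"].iloc[0] == pytest.approx(1.0)
        assert res.loc["ES_Count_ssO", "rank"] == 1

    def test_constant_excluded_and_ranks_form_permutation(self):
        D, rng = toy_matrix()
        y = pd.Series(rng.normal(size=len(D)), index=D.index, name="pEC50")
        res = screen_single_descriptors(D, y)
        assert "Constant" not in res.index
        assert "Constant" in res.attrs["excluded"]
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))

    def test_independent_descriptor_near_zero_r2(self):
        rng = np.random.default_rng(42)
        n = 4000
        D = pd.DataFrame({"x": rng.normal(size=n)},
                         index=[f"c{i}" for i in range(n)])
        y = pd.Series(rng.normal(size=n), index=D.index, name="pEC50")
        res = screen_single_descriptors(D, y)
        assert res["r2"].iloc[0] < 0.01

    def test_r2_equals_squared_pearson(self):
        D, rng = toy_matrix()
        y = pd.Series(
            D["ES_Count_ssO"] * -1.5 + rng.normal(0, 1, len(D)),
            index=D.index, name="pEC50",
        )
        res = screen_single_descriptors(D, y)
        for col in res.index:
            r = np.corrcoef(D[col], y)[0, 1]
            assert res.loc[col, "r2"] == pytest.approx(r**2, abs=1e-12)


class TestSubsets:
    def test_identity_subset(self):
        D, rng = toy_matrix()
        y = pd.Series(rng.normal(size=len(D)), index=D.index)
        Dsub, ysub = subset_by_property(D, y, "Noise", len(D))
        assert set(Dsub.index) == set(D.index)

    def test_top_n_largest(self):
        D, rng = toy_matrix()
        y = pd.Series(rng.normal(size=len(D)), index=D.index)
        Dsub, _ = subset_by_property(D, y, "Jurs_RNCG", 10)
        cutoff = D["Jurs_RNCG"].sort_values(ascending=False).iloc[9]
        assert (Dsub["Jurs_RNCG"] >= cutoff).all()

    def test_ties_preserve_input_order(self):
        D = pd.DataFrame(
            {"p": [1.0, 1.0, 1.0, 0.5], "q": [0.0, 1.0, 2.0, 3.0]},
            index=list("abcd"),
        )
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        Dsub, _ = subset_by_property(D, y, "p", 3)
        assert list(Dsub.index) == ["a", "b", "c"]

    def test_too_small_rejected(self):
        D, rng = toy_matrix()
        y = pd.Series(rng.normal(size=len(D)), index=D.index)
        with pytest.raises(ValueError):
            subset_by_property(D, y, "Noise", 2)


class TestDominance:
    def test_perfect_descriptor_dominates_every_subset(self):
        D, rng = toy_matrix(n=60, seed=3)
        y = (2.0 - 3.0 * D["Jurs_RNCG"]).rename("pEC50")
        tally = DominanceScreen(D, y, sizes=[10, 30, 60]).fit()
        t = tally.table
        assert (t["focal_dominant"] == t["total_subsets"]).all()
        assert (t["modal_dominant"] == "Jurs_RNCG").all()
        assert (t["focal_near_dominant"] >= t["focal_dominant"]).all()

    def test_tally_counts_are_consistent(self, analog_matrix, analog_set):
        tally = DominanceScreen(
            analog_matrix, analog_set.activities, sizes=[20, 80, 150]
        ).fit()
        t = tally.table
        assert (t["focal_dominant"] <= t["family_dominant"]).all()
        assert (t["family_dominant"] <= t["total_subsets"]).all()


class TestContextEquations:
    def test_duplicate_of_filter_excluded(self):
        D, rng = toy_matrix()
        D["ES_Count_dup"] = D["Jurs_RNCG"]
        y = pd.Series(rng.normal(size=len(D)), index=D.index, name="pEC50")
        res = ContextEquationModel(D, y).fit()
        assert "ES_Count_dup" not in res.equations.index
        assert "collinear" in res.excluded["ES_Count_dup"]

    def test_affine_rescaling_invariance(self):
        """R^2 and rank are invariant to positive affine rescaling of an ES
        column; negation flips the reported sign."""
        D, rng = toy_matrix()
        y = pd.Series(
            5 - 1.5 * D["ES_Count_ssO"] + 2 * D["Jurs_RNCG"]
            + rng.normal(0, 0.3, len(D)),
            index=D.index, name="pEC50",
        )
        base = ContextEquationModel(D, y).fit()
        D2 = D.copy()
        D2["ES_Count_ssO"] = 10 * D2["ES_Count_ssO"] + 3
        scaled = ContextEquationModel(D2, y).fit()
        assert scaled.equations.loc["ES_Count_ssO", "r2"] == pytest.approx(
            base.equations.loc["ES_Count_ssO", "r2"], abs=1e-12
        )
        assert scaled.sign("ES_Count_ssO") == base.sign("ES_Count_ssO")
        D3 = D.copy()
        D3["ES_Count_ssO"] = -D3["ES_Count_ssO"]
        neg = ContextEquationModel(D3, y).fit()
        assert neg.sign("ES_Count_ssO") != base.sign("ES_Count_ssO")

    def test_constant_shift_of_y_changes_only_intercept(self):
        D, rng = toy_matrix()
        y = pd.Series(
            -D["ES_Count_ssO"] + rng.normal(0, 0.5, len(D)),
            index=D.index, name="pEC50",
        )
        a = ContextEquationModel(D, y).fit().equations
        b = ContextEquationModel(D, y + 7).fit().equations
        assert b["beta0"].to_numpy() == pytest.approx(a["beta0"].to_numpy() + 7)
        assert b["beta_filter"].to_numpy() == pytest.approx(
            a["beta_filter"].to_numpy()
        )
        assert b["beta_es"].to_numpy() == pytest.approx(a["beta_es"].to_numpy())
        assert (b["rank"] == a["rank"]).all()

    def test_constant_filter_rejected(self):
        D, rng = toy_matrix()
        D["Jurs_RNCG"] = 0.5
        y = pd.Series(rng.normal(size=len(D)), index=D.index, name="pEC50")
        with pytest.raises(ValueError, match="constant"):
            ContextEquationModel(D, y)

    def test_monitor_table_shape_and_determinism(self, analog_matrix, analog_set):
        res = ContextEquationModel(analog_matrix, analog_set.activities).fit()
        mon = res.summary(k=12)
        assert len(mon) == 12
        assert list(mon["rank"]) == list(range(1, 13))
        assert set(mon["sign"]) <= {"+", "-"}
        res2 = ContextEquationModel(analog_matrix, analog_set.activities).fit()
        pd.testing.assert_frame_equal(res.summary(k=12), res2.summary(k=12))

    def test_monitor_table_k_larger_than_list(self):
        D, rng = toy_matrix()
        y = pd.Series(
            -D["ES_Count_ssO"] + rng.normal(0, 0.5, len(D)),
            index=D.index, name="pEC50",
        )
        eq = ContextEquationModel(D, y).fit().equations
        assert len(monitor_table(eq, k=100)) == len(eq)


def flip_fixture(n=60, seed=9, rho_noise=0.2):
    """Count/Sum pair correlated at r >= 0.95 built so the joint fit must
    flip one sign: y depends on the pair as (-2, +0.4), so both single-ES
    slopes are negative while the joint coefficient of the second is +0.4."""
    rng = np.random.default_rng(seed)
    count = rng.integers(0, 5, n).astype(float)
    summ = count + rng.normal(0, rho_noise, n)
    filt = rng.uniform(0, 1, n)
    y = 4 + 1.0 * filt - 2.0 * count + 0.4 * summ + rng.normal(0, 0.05, n)
    D = pd.DataFrame(
        {
            "Jurs_RNCG": filt,
            "ES_Count_tt": count,
            "ES_Sum_tt": summ,
            "ES_Count_rare": np.where(np.arange(n) < 2, 1.0, 0.0),
        },
        index=[f"c{i}" for i in range(n)],
    )
    ys = pd.Series(y, index=D.index, name="pEC50")
    return D, ys


class TestDependencyDiagnostics:
    def test_count_sum_pair_flagged(self):
        D, y = flip_fixture()
        assert np.corrcoef(D["ES_Count_tt"], D["ES_Sum_tt"])[0, 1] >= 0.95
        rep = ContextEquationModel(D, y).fit().dependency_diagnostics(k=3)
        assert ("ES_Count_tt", "ES_Sum_tt") in rep.count_sum_pairs

    def test_collinear_pair_forces_sign_flip(self):
        """Joint fit of two r>0.95 columns contradicts a single-equation sign;
        the joint coefficients match the least-squares oracle."""
        D, y = flip_fixture()
        res = ContextEquationModel(D, y).fit()
        assert res.sign("ES_Count_tt") == "-"
        assert res.sign("ES_Sum_tt") == "-"
        rep = res.dependency_diagnostics(k=3)
        assert "ES_Sum_tt" in rep.sign_flips
        cols = ["Jurs_RNCG"] + res.top(3)
        beta_ref, _ = normal_equations(D[cols].to_numpy(), y.to_numpy())
        combined = rep.combined_coefficients
        for k, name in enumerate(res.top(3)):
            assert combined[name] == pytest.approx(beta_ref[2 + k], abs=1e-8)

    def test_rare_moiety_support_flag(self):
        D, y = flip_fixture()
        rep = ContextEquationModel(D, y).fit().dependency_diagnostics(k=3)
        assert rep.support["ES_Count_rare"] == 2
        assert "ES_Count_rare" in rep.rare_descriptors

    def test_singular_combined_design_reported_not_raised(self):
        D, y = flip_fixture()
        D["ES_Sum_tt"] = 2.0 * D["ES_Count_tt"]  # exact dependency
        res = ContextEquationModel(D, y).fit()
        rep = res.dependency_diagnostics(k=3)
        assert rep.combined_singular


class TestActivityIngestion:
    def test_pec50_and_exclusions(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "id,ec50_molar,uncertain\n"
            "a,1e-9,\nb,1e-6,\nc,-1,\nd,,\ne,1e-7,yes\n"
        )
        t = load_activities(path)
        assert list(t.index) == ["a", "b"]
        assert t.loc["a", "pEC50"] == pytest.approx(9.0)
        assert t.attrs["n_excluded"] == 3

    def test_roundtrip_with_generator(self, analog_set):
        t = load_activities(analog_set.activities.reset_index()[["id", "ec50_molar"]])
        assert t["pEC50"].to_numpy() == pytest.approx(
            analog_set.activities["pEC50"].to_numpy(), abs=1e-12
        )
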