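"""Factorial inference: SS decompositions, adjusted means, Tukey, exponents."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acclim.errors import (DataError, DesignError, DomainError, TransformError)
from acclim.inference import (adjusted_means, condition_factor,
                              homogeneity_of_slopes, mass_exponent, tukey_hsd,
                              two_way_ancova, two_way_anova)


def balanced_dataset(rng, n_per_cell=4, a_levels=("p1", "p2", "p3"),
                     b_levels=(8.0, 19.0), effects=None, sigma=1.0):
    rows = []
    effects = effects or {}
    for a in a_levels:
        for b in b_levels:
            mu = 10.0 + effects.get((a, b), 0.0)
            for _ in range(n_per_cell):
                rows.append({"population": a, "acclimation_temp": b,
                             "y": mu + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


def cell_mean_ss_oracle(df):
    """Explicit balanced two-way decomposition from cell means."""
    y = df["y"].to_numpy()
    grand = y.mean()
    ss_a = sum(g["y"].size * (g["y"].mean() - grand) ** 2
               for _, g in df.groupby("population"))
    ss_b = sum(g["y"].size * (g["y"].mean() - grand) ** 2
               for _, g in df.groupby("acclimation_temp"))
    means_a = df.groupby("population")["y"].mean()
    means_b = df.groupby("acclimation_temp")["y"].mean()
    ss_ab = sum(
        g["y"].size * (g["y"].mean() - means_a[a] - means_b[b] + grand) ** 2
        for (a, b), g in df.groupby(["population", "acclimation_temp"]))
    ss_total = ((y - grand) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_total


class TestConditionFactor:
    @pytest.mark.parametrize("mass,length,expected", [
        (116.9, 20.7, 1.3),  # heavy 8 degC-acclimated fish
        (84.1, 19.1, 1.2),  # lighter 19 degC-acclimated fish
    ])
    def test_reproduces_cohort_table_values(self, mass, length, expected):
        assert round(condition_factor(mass, length), 1) == expected

    def test_unit_cube_scaling(self):
        assert condition_factor(100.0, 10.0) == pytest.approx(10.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            condition_factor(0.0, 20.0)
        with pytest.raises(DomainError):
            condition_factor(100.0, -1.0)


class TestAnova:
    def test_minimal_balanced_residual_df(self, rng):
        df = balanced_dataset(rng, n_per_cell=2, a_levels=("p1", "p2"))
        fit = two_way_anova(df, "y")
        assert fit.residual_df == 4  # 8 - 4 estimated cell means

    def test_sequential_ss_match_cell_mean_oracle(self, rng):
        df = balanced_dataset(rng, n_per_cell=4,
                              effects={("p1", 8.0): 2.0, ("p3", 19.0): -1.0})
        fit = two_way_anova(df, "y")
        tbl = fit.anova_table
        ss_a, ss_b, ss_ab, ss_total = cell_mean_ss_oracle(df)
        assert tbl.loc["population", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert tbl.loc["acclimation_temp", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert tbl.loc["population:acclimation_temp", "sum_sq"] == pytest.approx(
            ss_ab, abs=1e-9)
        assert tbl["sum_sq"].sum() == pytest.approx(ss_total, abs=1e-9)

    def test_type_three_close_on_balanced_data(self, rng):
        df = balanced_dataset(rng, effects={("p1", 8.0): 1.5})
        t1 = two_way_anova(df, "y", ss_type=1).anova_table
        t3 = two_way_anova(df, "y", ss_type=3).anova_table
        for term in ("population", "acclimation_temp", "population:acclimation_temp"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t3.loc[term, "sum_sq"], rel=1e-8)

    def test_missing_cell_named_in_error(self, rng):
        df = balanced_dataset(rng)
        df = df[~((df.population == "p2") & (df.acclimation_temp == 19.0))]
        with pytest.raises(DesignError, match="p2"):
            two_way_anova(df, "y")

    def test_single_level_factor_rejected(self, rng):
        df = balanced_dataset(rng, a_levels=("p1",))
        with pytest.raises(DesignError):
            two_way_anova(df, "y")

    def test_duplicate_fish_id_rejected(self, rng):
        df = balanced_dataset(rng, n_per_cell=2, a_levels=("p1", "p2"))
        df["fish_id"] = ["a"] * 4 + ["b"] * 4
        with pytest.raises(DataError, match="duplicate"):
            two_way_anova(df, "y")

    def test_nonpositive_values_block_log_transform(self, rng):
        df = balanced_dataset(rng)
        df.loc[df.index[0], "y"] = -1.0
        with pytest.raises(TransformError):
            two_way_anova(df, "y", log10_response=True)


class TestAncova:
    def test_pure_allometry_absorbed_by_covariate(self, rng):
        df = balanced_dataset(rng, n_per_cell=6, sigma=0.0)
        df["mass"] = rng.lognormal(np.log(100), 0.2, len(df))
        df["y"] = 3.0 * df["mass"] ** 0.82
        fit = two_way_ancova(df, "y")
        tbl = fit.anova_table
        total = tbl["sum_sq"].sum()
        assert tbl.loc["log10(mass)", "sum_sq"] == pytest.approx(total, rel=1e-9)
        for term in ("population", "acclimation_temp",
                     "population:acclimation_temp", "Residual"):
            assert tbl.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-9 * total)

    def test_within_cell_centred_covariate_leaves_factor_ss(self, rng):
        df = balanced_dataset(rng, effects={("p1", 8.0): 2.0})
        df["mass"] = rng.normal(0, 1, len(df))
        df["mass"] -= df.groupby(["population", "acclimation_temp"])[
            "mass"].transform("mean")
        anova_tbl = two_way_anova(df, "y").anova_table
        ancova_tbl = two_way_ancova(df, "y", log10_response=False,
                                    log10_covariate=False).anova_table
        for term in ("population", "acclimation_temp", "population:acclimation_temp"):
            assert ancova_tbl.loc[term, "sum_sq"] == pytest.approx(
                anova_tbl.loc[term, "sum_sq"], rel=1e-8)

    def test_constant_covariate_rejected(self, rng):
        df = balanced_dataset(rng)
        df["mass"] = 100.0
        with pytest.raises(DesignError, match="constant"):
            two_way_ancova(df, "y", log10_response=False)


class TestMassExponent:
    def test_identity_scaling(self, rng):
        df = balanced_dataset(rng, sigma=0.0)
        df["mass"] = rng.lognormal(np.log(100), 0.15, len(df))
        df["y"] = df["mass"]
        b, _ = mass_exponent(df, "y")
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_exact_power_law(self, rng):
        df = balanced_dataset(rng, sigma=0.0)
        df["mass"] = rng.lognormal(np.log(100), 0.15, len(df))
        df["y"] = 0.05 * df["mass"] ** 0.82
        b, se = mass_exponent(df, "y")
        assert b == pytest.approx(0.82, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)
        b_pooled, _ = mass_exponent(df, "y", pooled=True)
        assert b_pooled == pytest.approx(0.82, abs=1e-12)

    def test_nonpositive_response_rejected(self, rng):
        df = balanced_dataset(rng)
        df["mass"] = 100.0 + rng.normal(0, 5, len(df))
        df["y"] = -df["y"]
        with pytest.raises(TransformError):
            mass_exponent(df, "y")


class TestHomogeneityOfSlopes:
    def test_doubled_slope_detected_at_large_n(self, rng):
        df = balanced_dataset(rng, n_per_cell=60, a_levels=("p1", "p2"), sigma=0.0)
        df["mass"] = rng.lognormal(np.log(100), 0.2, len(df))
        expo = np.where(df["population"] == "p1", 1.0, 2.0)
        df["y"] = 2.0 * df["mass"] ** expo * np.exp(rng.normal(0, 0.05, len(df)))
        _, p = homogeneity_of_slopes(df, "y")
        assert p < 1e-3

    def test_single_cell_data_rejected(self, rng):
        df = balanced_dataset(rng, a_levels=("p1",), b_levels=(8.0,))
        df["mass"] = rng.lognormal(np.log(100), 0.2, len(df))
        with pytest.raises(DesignError):
            homogeneity_of_slopes(df, "y")


class TestAdjustedMeans:
    def test_cell_centred_covariate_returns_raw_means(self, rng):
        df = balanced_dataset(rng, effects={("p1", 8.0): 3.0})
        # force each cell's mean mass to exactly the reference value
        df["mass"] = 108.6 + rng.normal(0, 5, len(df))
        df["mass"] -= df.groupby(["population", "acclimation_temp"])[
            "mass"].transform("mean") - 108.6
        fit = two_way_ancova(df, "y", log10_response=False, log10_covariate=False)
        out = adjusted_means(fit, "population", reference_mass=108.6)
        raw = df.groupby("population")["y"].mean()
        for _, row in out.iterrows():
            assert row["ls_mean"] == pytest.approx(raw[row["population"]], abs=1e-9)

    def test_two_group_closed_form_oracle(self, rng):
        # one factor, one covariate: solve the normal equations directly
        n = 12
        df = pd.DataFrame({
            "population": ["a"] * n + ["b"] * n,
            "acclimation_temp": 8.0,
            "mass": rng.normal(100, 10, 2 * n),
        })
        df["y"] = (np.where(df.population == "a", 5.0, 9.0)
                   + 0.04 * df["mass"] + rng.normal(0, 0.5, 2 * n))
        fit = two_way_ancova(df, "y", factor_b=None, log10_response=False,
                             log10_covariate=False)
        ref = 105.0
        # oracle: X = [1, I(b), mass]
        X = np.column_stack([np.ones(2 * n), (df.population == "b").astype(float),
                             df["mass"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
        expect_a = beta[0] + beta[2] * ref
        expect_b = beta[0] + beta[1] + beta[2] * ref
        out = adjusted_means(fit, "population", reference_mass=ref).set_index(
            "population")
        assert out.loc["a", "ls_mean"] == pytest.approx(expect_a, abs=1e-9)
        assert out.loc["b", "ls_mean"] == pytest.approx(expect_b, abs=1e-9)
        # SEM oracle from the coefficient covariance
        resid = df["y"] - X @ beta
        s2 = (resid @ resid) / (2 * n - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        row_a = np.array([1.0, 0.0, ref])
        assert out.loc["a", "sem"] == pytest.approx(
            np.sqrt(row_a @ cov @ row_a), abs=1e-9)

    def test_invariant_to_recentering_covariate(self, rng):
        df = balanced_dataset(rng)
        df["mass"] = rng.normal(100, 10, len(df))
        df["y"] = df["y"] + 0.02 * df["mass"]
        fit1 = two_way_ancova(df, "y", log10_response=False, log10_covariate=False)
        df2 = df.assign(mass=df["mass"] + 250.0)
        fit2 = two_way_ancova(df2, "y", log10_response=False, log10_covariate=False)
        m1 = adjusted_means(fit1, "acclimation_temp", reference_mass=100.0)
        m2 = adjusted_means(fit2, "acclimation_temp", reference_mass=350.0)
        assert np.allclose(m1["ls_mean"], m2["ls_mean"], atol=1e-9)
        assert np.allclose(m1["sem"], m2["sem"], atol=1e-9)

    def test_back_transform_uses_delta_method(self, rng):
        df = balanced_dataset(rng)
        df["y"] = 10.0 ** (df["y"] / 10.0)
        df["mass"] = rng.lognormal(np.log(100), 0.1, len(df))
        fit = two_way_ancova(df, "y", log10_response=True)
        log_means = adjusted_means(fit, "population", reference_mass=100.0,
                                   back_transform=False)
        bt = adjusted_means(fit, "population", reference_mass=100.0,
                            back_transform=True)
        assert np.allclose(bt["ls_mean"], 10.0 ** log_means["ls_mean"])
        assert np.allclose(bt["sem"],
                           np.log(10) * bt["ls_mean"] * log_means["sem"])

    def test_nonpositive_reference_mass_rejected(self, rng):
        df = balanced_dataset(rng)
        df["mass"] = rng.normal(100, 10, len(df))
        fit = two_way_ancova(df, "y", log10_response=False, log10_covariate=False)
        with pytest.raises(DomainError):
            adjusted_means(fit, "population", reference_mass=-5.0)

    def test_out_of_range_reference_mass_warns(self, rng):
        df = balanced_dataset(rng)
        df["mass"] = rng.normal(100, 5, len(df))
        fit = two_way_ancova(df, "y", log10_response=False, log10_covariate=False)
        with pytest.warns(UserWarning, match="outside"):
            adjusted_means(fit, "population", reference_mass=1000.0)


class TestTukey:
    def test_two_groups_equal_pooled_t_test(self, rng):
        a = rng.normal(0.0, 1.0, 14)
        b = rng.normal(0.8, 1.0, 9)  # unbalanced on purpose (Tukey-Kramer)
        df = pd.DataFrame({"population": ["a"] * 14 + ["b"] * 9,
                           "y": np.concatenate([a, b])})
        fit = two_way_anova(df, "y", factor_b=None)
        tk = tukey_hsd(fit, "population")
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert tk.loc[0, "adjusted_p"] == pytest.approx(t_p, abs=1e-10)
        t_stat = abs(stats.ttest_ind(a, b, equal_var=True).statistic)
        assert tk.loc[0, "q_statistic"] == pytest.approx(t_stat * np.sqrt(2), abs=1e-10)

    def test_identical_group_means_give_p_one(self):
        block = [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame({"population": np.repeat(["a", "b", "c"], 4),
                           "y": block * 3})
        fit = two_way_anova(df, "y", factor_b=None)
        tk = tukey_hsd(fit, "population")
        assert (tk["adjusted_p"] > 0.999).all()

    def test_shifted_group_separates(self, rng):
        df = pd.DataFrame({
            "population": np.repeat(["a", "b", "c", "d"], 10),
            "y": rng.normal(0, 1, 40)})
        df.loc[df.population == "d", "y"] += 10.0  # ten residual SDs
        fit = two_way_anova(df, "y", factor_b=None)
        tk = tukey_hsd(fit, "population")
        with_d = tk[(tk.group_a == "d") | (tk.group_b == "d")]
        without_d = tk[(tk.group_a != "d") & (tk.group_b != "d")]
        assert (with_d["adjusted_p"] < 1e-3).all()
        assert (without_d["adjusted_p"] > 0.05).all()

    def test_p_monotone_in_mean_difference(self, rng):
        noise = rng.normal(0, 1, 10)
        ps = []
        for shift in (0.3, 0.8, 1.5, 3.0):
            df = pd.DataFrame({"population": ["a"] * 10 + ["b"] * 10,
                               "y": np.concatenate([noise, noise + shift])})
            fit = two_way_anova(df, "y", factor_b=None)
            ps.append(tukey_hsd(fit, "population").loc[0, "adjusted_p"])
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_single_group_rejected(self, rng):
        df = pd.DataFrame({"population": ["a"] * 6, "acclimation_temp": 8.0,
                           "y": rng.normal(0, 1, 6)})
        with pytest.raises(DesignError):
            two_way_anova(df, "y", factor_b=None)

    def test_differences_are_antisymmetric_mean_contrasts(self, rng):
        df = balanced_dataset(rng, effects={("p1", 8.0): 2.0})
        fit = two_way_anova(df, "y")
        tk = tukey_hsd(fit, "population").set_index(["group_a", "group_b"])
        means = adjusted_means(fit, "population").set_index("population")["ls_mean"]
        for (a, b), row in tk.iterrows():
            assert row["difference"] == pytest.approx(means[a] - means[b], abs=1e-9)
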