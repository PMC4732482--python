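"""Factorial inference layer: two-way ANOVA/ANCOVA with a body-mass covariate,
least-squares (adjusted) means at a reference mass, homogeneity-of-slopes
screening, allometric mass exponents, Tukey HSD pairwise comparisons and
Fulton's condition factor.

Model conventions
-----------------
The full factorial model is ``response ~ covariate + A + B + A:B`` with the
covariate entered first; sums of squares are sequential (Type I) by default,
matching the order covariate, population, acclimation temperature,
interaction. A partial (Type III, sum-to-zero contrasts) option exists for
the nearly balanced designs this package targets, where the two nearly agree.

When the response is log10-transformed the covariate enters as log10(mass),
which makes the fitted common slope the allometric mass exponent b in
``rate = a * mass^b``. Adjusted group means are model predictions at
``mass = reference_mass`` (averaged over the levels of the other factor with
equal weight) with SEMs from the coefficient covariance; back-transformed
means use the delta method for the SEM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.stats import studentized_range
from statsmodels.stats.anova import anova_lm

from .errors import DataError, DesignError, DomainError, TransformError

__all__ = [
    "condition_factor", "FactorialFit", "two_way_anova", "two_way_ancova",
    "homogeneity_of_slopes", "adjusted_means", "mass_exponent", "tukey_hsd",
]


def condition_factor(mass, fork_length):
    """Fulton's condition factor K = 100 * mass / length^3 (mass g, length cm)."""
    m = np.asarray(mass, dtype=float)
    length = np.asarray(fork_length, dtype=float)
    if np.any(m <= 0) or np.any(length <= 0):
        raise DomainError("condition_factor: mass and fork_length must be > 0")
    k = 100.0 * m / length**3
    return float(k) if k.ndim == 0 else k


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class FactorialFit:
    """A fitted factorial (AN(C)OVA) model plus the metadata needed to read it.

    ``frame`` holds the internal modelling columns: ``y`` (possibly log10),
    ``A``/``B`` (factors) and ``x`` (possibly log10 covariate).
    """

    result: object  # statsmodels RegressionResultsWrapper
    frame: pd.DataFrame
    response: str
    factor_a: str
    factor_b: str | None
    covariate: str | None
    log10_response: bool
    log10_covariate: bool
    ss_type: int

    @property
    def residual_df(self) -> int:
        return int(self.result.df_resid)

    @property
    def covariate_slope(self) -> float:
        if self.covariate is None:
            raise DataError("model has no covariate")
        return float(self.result.params["x"])

    @property
    def covariate_slope_se(self) -> float:
        if self.covariate is None:
            raise DataError("model has no covariate")
        return float(self.result.bse["x"])

    @property
    def _cov_label(self) -> str:
        return f"log10({self.covariate})" if self.log10_covariate else self.covariate

    @property
    def anova_table(self) -> pd.DataFrame:
        """Terms x (df, sum_sq, F, p) with the user's variable names.

        Sequential (Type I) sums of squares are built by explicit nested
        model comparison in the fixed order covariate, A, B, A:B (patsy
        reorders numeric terms after categoricals, so ``anova_lm(typ=1)`` on
        the fitted model would enter the covariate last). Type III uses
        ``anova_lm`` on the sum-to-zero parameterisation.
        """
        if self.ss_type == 1:
            return self._sequential_table()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # anova_lm emits F-dist nan warnings on typ=3
            tbl = anova_lm(self.result, typ=self.ss_type)
        rename = {}
        for idx in tbl.index:
            name = idx.replace("C(A, Sum)", self.factor_a).replace("C(A)", self.factor_a)
            if self.factor_b is not None:
                name = name.replace("C(B, Sum)", self.factor_b).replace("C(B)", self.factor_b)
            if self.covariate is not None and name == "x":
                name = self._cov_label
            rename[idx] = name
        tbl = tbl.rename(index=rename)
        if "Intercept" in tbl.index:
            tbl = tbl.drop(index="Intercept")
        return tbl

    def _sequential_table(self) -> pd.DataFrame:
        from scipy.stats import f as f_dist

        terms: list[tuple[str, str]] = []
        if self.covariate is not None:
            terms.append(("x", self._cov_label))
        terms.append(("C(A)", self.factor_a))
        if self.factor_b is not None:
            terms.append(("C(B)", self.factor_b))
            terms.append(("C(A):C(B)", f"{self.factor_a}:{self.factor_b}"))

        ssr_prev = float(np.sum((self.frame["y"] - self.frame["y"].mean()) ** 2))
        df_prev = len(self.frame) - 1
        mse = self.result.ssr / self.result.df_resid
        rows = []
        rhs: list[str] = []
        for patsy_term, label in terms:
            rhs.append(patsy_term)
            res = smf.ols("y ~ " + " + ".join(rhs), data=self.frame).fit()
            ss = ssr_prev - float(res.ssr)
            df = df_prev - float(res.df_resid)
            ssr_prev, df_prev = float(res.ssr), float(res.df_resid)
            F = (ss / df) / mse if df > 0 else np.nan
            p = float(f_dist.sf(F, df, self.result.df_resid)) if df > 0 else np.nan
            rows.append({"term": label, "df": df, "sum_sq": ss,
                         "mean_sq": ss / df if df > 0 else np.nan, "F": F, "PR(>F)": p})
        rows.append({"term": "Residual", "df": float(self.result.df_resid),
                     "sum_sq": float(self.result.ssr),
                     "mean_sq": mse, "F": np.nan, "PR(>F)": np.nan})
        return pd.DataFrame(rows).set_index("term").rename_axis(None)

    def term_p(self, term: str) -> float:
        return float(self.anova_table.loc[term, "PR(>F)"])

    def _factor_col(self, group_factor: str) -> str:
        if group_factor == self.factor_a:
            return "A"
        if self.factor_b is not None and group_factor == self.factor_b:
            return "B"
        raise DesignError(f"{group_factor!r} is not a factor of this model "
                          f"({self.factor_a}, {self.factor_b})")


def _prepare_frame(data: pd.DataFrame, response: str, factor_a: str,
                   factor_b: str | None, covariate: str | None,
                   log10_response: bool, log10_covariate: bool) -> pd.DataFrame:
    for col in filter(None, (response, factor_a, factor_b, covariate)):
        if col not in data.columns:
            raise DataError(f"column {col!r} missing from analysis dataset")
    if "fish_id" in data.columns and data["fish_id"].duplicated().any():
        dup = data.loc[data["fish_id"].duplicated(), "fish_id"].iloc[0]
        raise DataError(f"duplicate fish_id {dup!r} in analysis dataset")
    frame = pd.DataFrame({
        "y": pd.to_numeric(data[response], errors="coerce"),
        "A": data[factor_a].astype(str),
    })
    if factor_b is not None:
        frame["B"] = data[factor_b].astype(str)
    if covariate is not None:
        frame["x"] = pd.to_numeric(data[covariate], errors="coerce")
    frame = frame.dropna()
    if log10_response:
        if (frame["y"] <= 0).any():
            raise TransformError(
                f"log10 transform of {response!r} undefined: nonpositive values present")
        frame["y"] = np.log10(frame["y"])
    if covariate is not None and log10_covariate:
        if (frame["x"] <= 0).any():
            raise TransformError(
                f"log10 transform of {covariate!r} undefined: nonpositive values present")
        frame["x"] = np.log10(frame["x"])

    if frame["A"].nunique() < 2:
        raise DesignError(f"factor {factor_a!r} needs >= 2 observed levels")
    if factor_b is not None:
        if frame["B"].nunique() < 2:
            raise DesignError(f"factor {factor_b!r} needs >= 2 observed levels")
        counts = frame.groupby(["A", "B"], observed=True).size()
        full = itertools.product(frame["A"].unique(), frame["B"].unique())
        for cell in full:
            if cell not in counts.index:
                raise DesignError(
                    f"empty design cell ({factor_a}={cell[0]}, {factor_b}={cell[1]})")
    if covariate is not None and np.ptp(frame["x"].to_numpy()) == 0:
        raise DesignError(f"covariate {covariate!r} is constant; model is rank deficient")
    return frame


def _formula(factor_b: str | None, covariate: str | None, ss_type: int,
             slope_interactions: bool = False) -> str:
    c = "C(A, Sum)" if ss_type == 3 else "C(A)"
    terms = []
    if covariate is not None:
        terms.append("x")
    terms.append(c)
    if factor_b is not None:
        cb = "C(B, Sum)" if ss_type == 3 else "C(B)"
        terms += [cb, f"{c}:{cb}"]
    if slope_interactions:
        if covariate is None:
            raise DesignError("slope interactions need a covariate")
        terms.append(f"x:{c}")
        if factor_b is not None:
            cb = "C(B, Sum)" if ss_type == 3 else "C(B)"
            terms += [f"x:{cb}", f"x:{c}:{cb}"]
    return "y ~ " + " + ".join(terms)


def _fit(data: pd.DataFrame, response: str, factor_a: str, factor_b: str | None,
         covariate: str | None, log10_response: bool, log10_covariate: bool,
         ss_type: int, slope_interactions: bool = False) -> FactorialFit:
    frame = _prepare_frame(data, response, factor_a, factor_b, covariate,
                           log10_response, log10_covariate)
    formula = _formula(factor_b, covariate, ss_type, slope_interactions)
    result = smf.ols(formula, data=frame).fit()
    if result.df_resid < 1:
        raise DesignError("insufficient residual degrees of freedom")
    return FactorialFit(result=result, frame=frame, response=response,
                        factor_a=factor_a, factor_b=factor_b, covariate=covariate,
                        log10_response=log10_response,
                        log10_covariate=log10_covariate, ss_type=ss_type)


def two_way_anova(data: pd.DataFrame, response: str,
                  factor_a: str = "population",
                  factor_b: str | None = "acclimation_temp",
                  log10_response: bool = False, ss_type: int = 1) -> FactorialFit:
    """Full factorial ANOVA ``response ~ A + B + A:B`` (sequential SS, A first)."""
    return _fit(data, response, factor_a, factor_b, None, log10_response,
                False, ss_type)


def two_way_ancova(data: pd.DataFrame, response: str,
                   factor_a: str = "population",
                   factor_b: str | None = "acclimation_temp",
                   covariate: str = "mass", log10_response: bool = True,
                   log10_covariate: bool | None = None,
                   ss_type: int = 1) -> FactorialFit:
    """Factorial ANCOVA ``response ~ covariate + A + B + A:B``.

    The covariate is log10-transformed whenever the response is (so that the
    common slope is the allometric mass exponent) unless overridden.
    """
    if log10_covariate is None:
        log10_covariate = log10_response
    return _fit(data, response, factor_a, factor_b, covariate, log10_response,
                log10_covariate, ss_type)


def homogeneity_of_slopes(data: pd.DataFrame, response: str,
                          factor_a: str = "population",
                          factor_b: str | None = "acclimation_temp",
                          covariate: str = "mass", log10_response: bool = True,
                          log10_covariate: bool | None = None) -> tuple[float, float]:
    """Extra-sum-of-squares F test of covariate x factor slope interactions.

    Compares the common-slope ANCOVA against the model with cell-specific
    covariate slopes; a small p-value means the covariate slope is not shared
    across groups and mass-adjusted means would be covariate-dependent.
    """
    if log10_covariate is None:
        log10_covariate = log10_response
    base = _fit(data, response, factor_a, factor_b, covariate, log10_response,
                log10_covariate, ss_type=1)
    ext = _fit(data, response, factor_a, factor_b, covariate, log10_response,
               log10_covariate, ss_type=1, slope_interactions=True)
    if ext.result.df_resid < 1:
        raise DesignError("no residual degrees of freedom for the slopes test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_tbl = anova_lm(base.result, ext.result)
    return float(cmp_tbl["F"].iloc[1]), float(cmp_tbl["Pr(>F)"].iloc[1])


# ---------------------------------------------------------------------------
# least-squares means and contrasts
# ---------------------------------------------------------------------------

def _ls_mean_rows(fit: FactorialFit, group_factor: str,
                  covariate_value: float | None) -> tuple[list[str], np.ndarray]:
    """Design-matrix rows whose product with beta gives the LS mean of each
    level of ``group_factor``, averaging over the other factor's levels."""
    col = fit._factor_col(group_factor)
    other = "B" if col == "A" else "A"
    levels = sorted(fit.frame[col].unique())
    grid_cols = {}
    if fit.factor_b is not None:
        other_levels = sorted(fit.frame[other].unique())
    else:
        other_levels = [None]
    design_info = fit.result.model.data.design_info
    rows = []
    for lev in levels:
        grid = pd.DataFrame({col: [lev] * len(other_levels)})
        if other_levels != [None]:
            grid[other] = other_levels
        if fit.covariate is not None:
            if covariate_value is None:
                covariate_value = float(fit.frame["x"].mean())
            grid["x"] = covariate_value
        (mat,) = build_design_matrices([design_info], grid)
        rows.append(np.asarray(mat).mean(axis=0))
    return levels, np.vstack(rows)


def adjusted_means(fit: FactorialFit, group_factor: str,
                   reference_mass: float | None = None,
                   back_transform: bool | None = None) -> pd.DataFrame:
    """Least-squares means of ``group_factor`` at ``reference_mass``.

    For covariate models the prediction is made at the (transformed)
    reference mass; without a covariate this reduces to ordinary LS means.
    ``back_transform`` (default: whether the response was log10-transformed)
    returns means on the original response scale with delta-method SEMs.
    """
    if back_transform is None:
        back_transform = fit.log10_response
    cov_value = None
    if fit.covariate is not None:
        if reference_mass is None:
            reference_mass = float(fit.frame["x"].mean())
            if fit.log10_covariate:
                reference_mass = 10.0 ** reference_mass
        if reference_mass <= 0:
            raise DomainError(f"reference mass must be > 0 g, got {reference_mass}")
        cov_value = np.log10(reference_mass) if fit.log10_covariate else float(reference_mass)
        lo, hi = fit.frame["x"].min(), fit.frame["x"].max()
        if not lo <= cov_value <= hi:
            warnings.warn(
                f"reference mass {reference_mass} g lies outside the observed "
                f"covariate range; adjusted means are extrapolations",
                stacklevel=2)
    levels, rows = _ls_mean_rows(fit, group_factor, cov_value)
    beta = fit.result.params.to_numpy()
    cov = fit.result.cov_params().to_numpy()
    est = rows @ beta
    sem = np.sqrt(np.einsum("ij,jk,ik->i", rows, cov, rows))
    out = pd.DataFrame({group_factor: levels, "ls_mean": est, "sem": sem})
    out["back_transformed"] = False
    if back_transform and fit.log10_response:
        point = 10.0 ** out["ls_mean"]
        out["sem"] = np.log(10.0) * point * out["sem"]
        out["ls_mean"] = point
        out["back_transformed"] = True
    out["reference_mass"] = reference_mass if fit.covariate is not None else np.nan
    return out


def mass_exponent(data: pd.DataFrame, response: str,
                  factor_a: str = "population",
                  factor_b: str | None = "acclimation_temp",
                  covariate: str = "mass",
                  pooled: bool = False) -> tuple[float, float]:
    """Allometric scaling exponent b of ``response ~ mass^b``.

    By default b is the common within-cell slope of log10(response) on
    log10(mass) from the factorial ANCOVA; ``pooled=True`` instead fits the
    simple pooled log-log regression ignoring the design factors.
    """
    if len(data) < 3:
        raise DataError("mass_exponent: needs at least 3 fish")
    if pooled:
        y = pd.to_numeric(data[response], errors="coerce")
        x = pd.to_numeric(data[covariate], errors="coerce")
        keep = y.notna() & x.notna()
        y, x = y[keep], x[keep]
        if (y <= 0).any() or (x <= 0).any():
            raise TransformError("mass_exponent: responses and masses must be > 0")
        from scipy.stats import linregress
        res = linregress(np.log10(x), np.log10(y))
        return float(res.slope), float(res.stderr)
    fit = two_way_ancova(data, response, factor_a, factor_b, covariate,
                         log10_response=True, log10_covariate=True)
    return fit.covariate_slope, fit.covariate_slope_se


def tukey_hsd(fit: FactorialFit, group_factor: str, alpha: float = 0.05,
              reference_mass: float | None = None) -> pd.DataFrame:
    """All pairwise comparisons of (adjusted) group means via the studentized
    range with the model's residual df (Tukey-Kramer under imbalance).

    Differences are on the model (possibly log10) scale. With two groups the
    adjusted p equals the pooled-variance two-sample t-test p.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    cov_value = None
    if fit.covariate is not None:
        if reference_mass is not None:
            cov_value = (np.log10(reference_mass) if fit.log10_covariate
                         else float(reference_mass))
        else:
            cov_value = float(fit.frame["x"].mean())
    levels, rows = _ls_mean_rows(fit, group_factor, cov_value)
    k = len(levels)
    if k < 2:
        raise DesignError(f"Tukey HSD needs >= 2 groups for {group_factor!r}")
    beta = fit.result.params.to_numpy()
    cov = fit.result.cov_params().to_numpy()
    est = rows @ beta
    df = fit.residual_df
    recs = []
    for i, j in itertools.combinations(range(k), 2):
        contrast = rows[i] - rows[j]
        diff = float(est[i] - est[j])
        se = float(np.sqrt(contrast @ cov @ contrast))
        q = abs(diff) / (se / np.sqrt(2.0)) if se > 0 else np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        recs.append({"group_a": levels[i], "group_b": levels[j],
                     "difference": diff, "q_statistic": q, "adjusted_p": p,
                     "significant": p < alpha})
    return pd.DataFrame(recs)
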