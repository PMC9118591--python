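"""Sex-stratified regression of 24-h behaviour compositions on walkability.

Two parallel model families, fitted on the same covariate design:

* **Compositional (pivot-coordinate) regression** — for each behaviour part
  *j*, the composition is expressed in pivot (orthogonal logratio)
  coordinates with *j* first, and the first coordinate

  ``z1 = sqrt((D-1)/D) * ln(x_j / gm(x_rest))``

  is regressed on the covariates by OLS.  A covariate coefficient ``theta`` on
  the coordinate scale maps to the clr scale as
  ``b_clr = sqrt((D-1)/D) * theta`` and is reported as the percent difference
  ``100 * (exp(b_clr) - 1)`` in part *j* per unit covariate, relative to the
  geometric mean of all behaviours.  Because the clr components of the fitted
  coefficients sum to zero, the reported percent differences of each covariate
  satisfy ``prod_j (1 + p_j/100) = 1`` exactly.

* **Per-behaviour linear models** — each behaviour in hours/day (composition
  closed to 24 h) regressed on the same design; the per-covariate
  coefficients sum to zero across behaviours and the intercepts sum to 24.

Confidence intervals use t quantiles (df = n - p); percent-scale CIs are the
coordinate-scale CI endpoints pushed through the same monotone map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .composition import (
    DEFAULT_PARTS,
    PivotBasis,
    close_rows,
    pivot_coordinates_matrix,
)

__all__ = [
    "DESIGN_COLUMNS",
    "build_design",
    "dichotomize_safety",
    "ols_fit",
    "OlsFit",
    "CodaRegression",
    "CodaRegressionResults",
    "BehaviourLinearModel",
    "BehaviourLinearResults",
    "fit_stratified",
    "percent_from_clr",
    "clr_from_percent",
    "implied_fourth_part",
    "hours_to_minutes",
    "compositional_mean",
    "descriptives",
    "residual_diagnostics",
]

EDU_LEVELS = ("secondary", "technical", "university")
DESIGN_COLUMNS = ("const", "age", "bmi_z", "summer", "puberty",
                  "edu_technical", "edu_university", "walkability")


def dichotomize_safety(responses) -> np.ndarray:
    """Perceived-danger item on a 1-4 Likert scale: 1 or 2 -> 0, 3 or 4 -> 1."""
    r = np.asarray(responses)
    if not np.isin(r, [1, 2, 3, 4]).all():
        raise ValueError("safety responses must be 1, 2, 3 or 4")
    return (r >= 3).astype(int)


def build_design(cohort: pd.DataFrame, include_safety: bool = False
                 ) -> pd.DataFrame:
    """Covariate design matrix: intercept, age, BMI z, season, puberty,
    parental education dummies (reference: secondary) and walkability."""
    required = ["age", "bmi_z", "summer", "puberty", "parent_edu",
                "walkability"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    edu = cohort["parent_edu"].astype(str)
    unknown = sorted(set(edu) - set(EDU_LEVELS))
    if unknown:
        raise ValueError(f"unknown parental education level(s): {unknown}")
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    X["age"] = cohort["age"].astype(float)
    X["bmi_z"] = cohort["bmi_z"].astype(float)
    X["summer"] = cohort["summer"].astype(int)
    X["puberty"] = cohort["puberty"].astype(int)
    X["edu_technical"] = (edu == "technical").astype(int)
    X["edu_university"] = (edu == "university").astype(int)
    X["walkability"] = cohort["walkability"].astype(float)
    if include_safety:
        if "safety" not in cohort.columns:
            raise ValueError("include_safety=True but no 'safety' column")
        X["safety"] = cohort["safety"].astype(int)
    return X


@dataclass
class OlsFit:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame   # columns: ci_low, ci_high
    resid: np.ndarray
    nobs: int
    df_resid: int


def ols_fit(y, X: pd.DataFrame, alpha: float = 0.05) -> OlsFit:
    """OLS with t-based CIs; errors on rank deficiency naming the columns."""
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # name a minimal set of columns whose removal restores full rank
        bad = []
        for j in range(p):
            keep = [k for k in range(p) if k != j and k not in bad]
            if np.linalg.matrix_rank(Xm[:, keep]) == rank:
                bad.append(j)
        names = [X.columns[j] for j in bad]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"column(s): {names}")
    fit = sm.OLS(y, Xm).fit()
    ci = fit.conf_int(alpha=alpha)
    idx = pd.Index(X.columns)
    return OlsFit(
        params=pd.Series(fit.params, index=idx),
        bse=pd.Series(fit.bse, index=idx),
        conf_int=pd.DataFrame(ci, index=idx, columns=["ci_low", "ci_high"]),
        resid=np.asarray(fit.resid),
        nobs=int(fit.nobs),
        df_resid=int(fit.df_resid),
    )


def percent_from_clr(b_clr) -> np.ndarray | float:
    """clr-scale coefficient -> percent difference, 100*(exp(b)-1)."""
    out = 100.0 * (np.exp(np.asarray(b_clr, dtype=float)) - 1.0)
    return float(out) if out.ndim == 0 else out


def clr_from_percent(percent) -> np.ndarray | float:
    """Inverse of :func:`percent_from_clr`: ln(1 + p/100)."""
    p = np.asarray(percent, dtype=float)
    if np.any(p <= -100):
        raise ValueError("percent difference must exceed -100")
    out = np.log1p(p / 100.0)
    return float(out) if out.ndim == 0 else out


def implied_fourth_part(three_percents) -> float:
    """Percent difference of the remaining part implied by the clr
    sum-to-zero constraint, given the other three."""
    b = np.asarray(clr_from_percent(np.asarray(three_percents, dtype=float)))
    return percent_from_clr(-b.sum())


def hours_to_minutes(x) -> np.ndarray | float:
    """Convert an effect expressed in hours/day to minutes/day."""
    out = np.asarray(x, dtype=float) * 60.0
    return float(out) if out.ndim == 0 else out


class CodaRegression:
    """Compositional regression of a 4-part time-use composition on covariates.

    Parameters
    ----------
    compositions : (n, D) array of strictly positive part values
        Need not be closed; only ratios matter.
    design : DataFrame
        Covariate matrix including an intercept column (see
        :func:`build_design`).
    parts : tuple of str
        Part labels for the composition columns.
    """

    def __init__(self, compositions, design: pd.DataFrame,
                 parts: tuple[str, ...] = DEFAULT_PARTS) -> None:
        comps = np.asarray(compositions, dtype=float)
        if comps.ndim != 2 or comps.shape[1] != len(parts):
            raise ValueError(f"compositions must be (n, {len(parts)})")
        if np.any(comps <= 0):
            raise ValueError("compositions must be strictly positive")
        if len(design) != comps.shape[0]:
            raise ValueError("design and compositions row counts differ")
        self.compositions = comps
        self.design = design
        self.parts = tuple(parts)

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame,
                       parts: tuple[str, ...] = DEFAULT_PARTS,
                       include_safety: bool = False) -> "CodaRegression":
        comps = cohort[list(parts)].to_numpy(dtype=float)
        return cls(comps, build_design(cohort, include_safety), parts)

    def fit(self, alpha: float = 0.05) -> "CodaRegressionResults":
        D = len(self.parts)
        scale = np.sqrt((D - 1) / D)
        theta, clr_b, pct, lo, hi, fits = {}, {}, {}, {}, {}, {}
        for part in self.parts:
            basis = PivotBasis(pivot_part=part, parts=self.parts)
            z1 = pivot_coordinates_matrix(self.compositions, basis)[:, 0]
            f = ols_fit(z1, self.design, alpha=alpha)
            fits[part] = f
            idx = f.params.index
            theta[part] = f.params
            clr_b[part] = f.params * scale
            pct[part] = pd.Series(
                percent_from_clr(f.params * scale), index=idx)
            lo[part] = pd.Series(
                percent_from_clr(f.conf_int["ci_low"] * scale), index=idx)
            hi[part] = pd.Series(
                percent_from_clr(f.conf_int["ci_high"] * scale), index=idx)
        return CodaRegressionResults(
            model=self,
            coordinate_params=pd.DataFrame(theta),
            clr_coefficients=pd.DataFrame(clr_b),
            percent=pd.DataFrame(pct),
            percent_ci_low=pd.DataFrame(lo),
            percent_ci_high=pd.DataFrame(hi),
            fits=fits,
            alpha=alpha,
        )


@dataclass
class CodaRegressionResults:
    """Percent-difference effect table (covariates x parts) with CIs."""

    model: CodaRegression
    coordinate_params: pd.DataFrame   # theta, coordinate scale
    clr_coefficients: pd.DataFrame    # sqrt((D-1)/D) * theta
    percent: pd.DataFrame             # 100*(exp(clr)-1)
    percent_ci_low: pd.DataFrame
    percent_ci_high: pd.DataFrame
    fits: dict[str, OlsFit]
    alpha: float

    @property
    def nobs(self) -> int:
        return next(iter(self.fits.values())).nobs

    def effect_table(self, include_intercept: bool = False) -> pd.DataFrame:
        """Tidy table: covariate, part, estimate (%), ci_low, ci_high."""
        rows = []
        for cov in self.percent.index:
            if cov == "const" and not include_intercept:
                continue
            for part in self.model.parts:
                rows.append({
                    "covariate": cov, "part": part,
                    "estimate": self.percent.loc[cov, part],
                    "ci_low": self.percent_ci_low.loc[cov, part],
                    "ci_high": self.percent_ci_high.loc[cov, part],
                })
        return pd.DataFrame(rows)

    def product_to_one_error(self) -> pd.Series:
        """|prod_j (1 + p_j/100) - 1| per covariate row (should be ~0)."""
        factor = 1.0 + self.percent / 100.0
        return (factor.prod(axis=1) - 1.0).abs()

    def diagnostics(self) -> pd.DataFrame:
        recs = {p: residual_diagnostics(f.resid)
                for p, f in self.fits.items()}
        return pd.DataFrame(recs).T

    def summary(self) -> str:
        lines = [
            "Compositional (pivot-coordinate) regression",
            f"  n = {self.nobs}, parts = {self.model.parts}, "
            f"alpha = {self.alpha}",
            "  percent difference per unit covariate "
            "(relative to the whole composition):",
        ]
        tbl = self.effect_table()
        for cov, grp in tbl.groupby("covariate", sort=False):
            lines.append(f"  {cov}:")
            for _, r in grp.iterrows():
                lines.append(
                    f"    {r['part']:>6}: {r['estimate']:7.2f}% "
                    f"({r['ci_low']:.2f}, {r['ci_high']:.2f})"
                )
        return "\n".join(lines)


class BehaviourLinearModel:
    """Per-behaviour linear models on the hours/day scale (closed to 24 h)."""

    def __init__(self, compositions, design: pd.DataFrame,
                 parts: tuple[str, ...] = DEFAULT_PARTS) -> None:
        comps = np.asarray(compositions, dtype=float)
        if comps.ndim != 2 or comps.shape[1] != len(parts):
            raise ValueError(f"compositions must be (n, {len(parts)})")
        self.hours = close_rows(comps, total=24.0)
        self.design = design
        self.parts = tuple(parts)

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame,
                       parts: tuple[str, ...] = DEFAULT_PARTS,
                       include_safety: bool = False) -> "BehaviourLinearModel":
        comps = cohort[list(parts)].to_numpy(dtype=float)
        return cls(comps, build_design(cohort, include_safety), parts)

    def fit(self, alpha: float = 0.05) -> "BehaviourLinearResults":
        params, lo, hi, fits = {}, {}, {}, {}
        for j, part in enumerate(self.parts):
            f = ols_fit(self.hours[:, j], self.design, alpha=alpha)
            fits[part] = f
            params[part] = f.params
            lo[part] = f.conf_int["ci_low"]
            hi[part] = f.conf_int["ci_high"]
        return BehaviourLinearResults(
            model=self,
            params=pd.DataFrame(params),
            ci_low=pd.DataFrame(lo),
            ci_high=pd.DataFrame(hi),
            fits=fits,
            alpha=alpha,
        )


@dataclass
class BehaviourLinearResults:
    """Hours/day effect tables for the four separate linear models."""

    model: BehaviourLinearModel
    params: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    fits: dict[str, OlsFit]
    alpha: float

    @property
    def nobs(self) -> int:
        return next(iter(self.fits.values())).nobs

    def effect_table(self) -> pd.DataFrame:
        rows = []
        for cov in self.params.index:
            for part in self.model.parts:
                rows.append({
                    "covariate": cov, "part": part,
                    "estimate": self.params.loc[cov, part],
                    "ci_low": self.ci_low.loc[cov, part],
                    "ci_high": self.ci_high.loc[cov, part],
                })
        return pd.DataFrame(rows)

    def coefficient_sums(self) -> pd.Series:
        """Across-behaviour sums: 24 for the intercept, 0 for covariates."""
        return self.params.sum(axis=1)

    def diagnostics(self) -> pd.DataFrame:
        recs = {p: residual_diagnostics(f.resid)
                for p, f in self.fits.items()}
        return pd.DataFrame(recs).T

    def summary(self) -> str:
        lines = [
            "Per-behaviour linear models (hours/day, closed to 24 h)",
            f"  n = {self.nobs}, alpha = {self.alpha}",
        ]
        for cov in self.params.index:
            vals = ", ".join(
                f"{p}={self.params.loc[cov, p]:.2f}" for p in self.model.parts
            )
            lines.append(f"  {cov}: {vals}")
        return "\n".join(lines)


def fit_stratified(cohort: pd.DataFrame, model_cls=CodaRegression,
                   by: str = "sex",
                   parts: tuple[str, ...] = DEFAULT_PARTS,
                   include_safety: bool = False, alpha: float = 0.05) -> dict:
    """Fit a model family separately within each stratum of ``by``."""
    out = {}
    for level, grp in cohort.groupby(by, sort=True):
        if len(grp) == 0:
            continue
        out[level] = model_cls.from_dataframe(
            grp, parts=parts, include_safety=include_safety).fit(alpha=alpha)
    return out


def compositional_mean(compositions, total: float = 1440.0,
                       parts: tuple[str, ...] = DEFAULT_PARTS):
    """Center of a compositional sample: closed per-part geometric means."""
    from .composition import closure

    comps = np.asarray(compositions, dtype=float)
    if comps.ndim == 1:
        comps = comps[None, :]
    if np.any(comps <= 0):
        raise ValueError("compositions must be strictly positive")
    gm = np.exp(np.log(comps).mean(axis=0))
    return closure(gm, total=total, parts=parts)


def residual_diagnostics(resid: np.ndarray) -> dict:
    """Residual summary: skew, excess kurtosis, omnibus normality test.

    ``flagged`` is True when normality is rejected at the 5% level;
    ``degenerate`` marks an (exact-fit) all-zero residual vector, for which
    the test statistic is undefined.
    """
    r = np.asarray(resid, dtype=float)
    if np.allclose(r, 0.0):
        return {"skew": 0.0, "kurtosis": 0.0, "statistic": np.nan,
                "pvalue": np.nan, "flagged": False, "degenerate": True}
    stat, p = stats.normaltest(r)
    return {
        "skew": float(stats.skew(r)),
        "kurtosis": float(stats.kurtosis(r)),
        "statistic": float(stat),
        "pvalue": float(p),
        "flagged": bool(p < 0.05),
        "degenerate": False,
    }


def plot_residuals(fits: dict[str, OlsFit], path) -> None:
    """QQ- and fitted-vs-residual panels, one row per behaviour part."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fits)
    fig, axes = plt.subplots(n, 2, figsize=(8, 2.6 * n), squeeze=False)
    for i, (part, f) in enumerate(fits.items()):
        sm.qqplot(f.resid, line="s", ax=axes[i][0])
        axes[i][0].set_title(f"{part}: residual QQ")
        axes[i][1].hist(f.resid, bins=30)
        axes[i][1].set_title(f"{part}: residual histogram")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, True, False}


def descriptives(included: pd.DataFrame, excluded: pd.DataFrame,
                 continuous: list[str] | None = None,
                 categorical: list[str] | None = None) -> pd.DataFrame:
    """Included-vs-excluded comparison table.

    Continuous variables: mean (sd) per group, Welch two-sample t p-value.
    Binary/categorical variables: % (n) per group, chi-squared p-value on the
    contingency table (no continuity correction).  Empty groups yield missing
    p-values.
    """
    if continuous is None:
        continuous = [c for c in included.columns
                      if c in excluded.columns
                      and pd.api.types.is_numeric_dtype(included[c])
                      and not _is_binary(included[c])]
    if categorical is None:
        categorical = [c for c in included.columns
                       if c in excluded.columns and c not in continuous
                       and c != "subject_id"]
    rows = []
    for c in continuous:
        a = included[c].dropna().to_numpy(dtype=float)
        b = excluded[c].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            p = np.nan
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "variable": c, "type": "continuous",
            "included": f"{a.mean():.2f} ({a.std(ddof=1):.2f})" if len(a) else "",
            "excluded": f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) else "",
            "n_included": len(a), "n_excluded": len(b), "pvalue": p,
        })
    for c in categorical:
        a = included[c].dropna()
        b = excluded[c].dropna()
        levels = sorted(set(a) | set(b))
        if len(a) == 0 or len(b) == 0 or len(levels) < 2:
            p = np.nan
        else:
            tab = np.array([[int((a == lv).sum()) for lv in levels],
                            [int((b == lv).sum()) for lv in levels]])
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
        if _is_binary(included[c]):
            na, nb = int(a.sum()), int(b.sum())
            inc = f"{100 * na / len(a):.0f} ({na})" if len(a) else ""
            exc = f"{100 * nb / len(b):.0f} ({nb})" if len(b) else ""
        else:
            inc = "; ".join(f"{lv}: {int((a == lv).sum())}" for lv in levels)
            exc = "; ".join(f"{lv}: {int((b == lv).sum())}" for lv in levels)
        rows.append({
            "variable": c, "type": "categorical",
            "included": inc, "excluded": exc,
            "n_included": len(a), "n_excluded": len(b), "pvalue": p,
        })
    return pd.DataFrame(rows)
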