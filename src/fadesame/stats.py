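"""Group comparisons, correlations, standardized regression and mediation.

All regression-based estimates are reported on z-scored variables
("fully standardized"): every variable in a model — including 0/1-coded
gender and education — is standardized to unit variance before the
ordinary-least-squares fit, so coefficients are comparable across
predictors and across models.

The mediation decomposition uses the two-regression
product-of-coefficients estimator: the a path from ``m ~ x``, the b and
direct (c') paths from ``y ~ x + m`` and the total effect c from
``y ~ x``.  On a single sample these satisfy ``c = c' + a*b`` exactly.
Standard errors for the indirect effect come from the delta method
(Sobel) by default, with a percentile bootstrap as an option.  For this
saturated three-variable linear model the point estimates coincide with
a fully standardized structural-equation fit; only the standard-error
conventions can differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "MediationFit",
    "group_compare",
    "chi_square_independence",
    "correlate",
    "standardized_regression",
    "residualize",
    "mediation_fit",
    "proportion_mediated",
    "build_table1",
    "build_table2",
    "build_table3",
    "build_table4",
]

_COND_LIMIT = 1e8


def _as_clean_array(x, name="variable"):
    x = np.asarray(x, dtype=float).ravel()
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _zscore(x, name="variable"):
    x = _as_clean_array(x, name)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (x - x.mean()) / sd


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    cohens_d: float


def group_compare(x, y, equal_var: bool = True) -> GroupComparison:
    """Two-sample t test (pooled variance by default) plus Cohen's d.

    Cohen's d uses the pooled standard deviation regardless of the
    variance assumption of the t test.  Swapping the groups negates
    both t and d.
    """
    x = _as_clean_array(x, "group x")
    y = _as_clean_array(y, "group y")
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return GroupComparison(t=float(res.statistic), df=float(res.df),
                           p=float(res.pvalue), cohens_d=float(d))


def chi_square_independence(table):
    """Pearson chi-square test of independence on a 2x2 table (df = 1).

    No continuity correction.  Returns ``(chi2, p)``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def correlate(x, y, kind: str = "pearson"):
    """Pearson or point-biserial correlation with two-sided p value.

    The point-biserial coefficient is Pearson's r computed on the
    0/1-coded binary variable — the ``kind`` argument only validates the
    coding.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if kind not in ("pearson", "point_biserial"):
        raise ValueError(f"unknown correlation kind {kind!r}")
    if kind == "point_biserial":
        binary = x if set(np.unique(x)) <= {0.0, 1.0} else y
        if not set(np.unique(binary)) <= {0.0, 1.0}:
            raise ValueError("point-biserial needs one 0/1-coded variable")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RegressionResult:
    beta: pd.Series
    pvalues: pd.Series
    se: pd.Series
    r_squared: float
    n: int


def _design_frame(predictors) -> pd.DataFrame:
    if isinstance(predictors, pd.DataFrame):
        return predictors.astype(float)
    return pd.DataFrame({k: np.asarray(v, dtype=float)
                         for k, v in predictors.items()})


def standardized_regression(y, predictors) -> RegressionResult:
    """OLS with every variable z-scored; betas are standardized slopes.

    ``predictors`` is a DataFrame or a mapping name -> array.  Binary
    covariates are z-scored like any other variable, matching the fully
    standardized reporting convention.  Raises on zero-variance
    predictors and near-collinear designs.
    """
    X = _design_frame(predictors)
    n = len(X)
    if n <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Z = pd.DataFrame({c: _zscore(X[c].to_numpy(), c) for c in X.columns})
    if np.linalg.cond(Z.to_numpy()) > _COND_LIMIT:
        raise ValueError("predictors are collinear (condition number guard)")
    yz = _zscore(y, "response")
    fit = sm.OLS(yz, sm.add_constant(Z)).fit()
    keep = list(X.columns)
    return RegressionResult(beta=fit.params[keep], pvalues=fit.pvalues[keep],
                            se=fit.bse[keep], r_squared=float(fit.rsquared),
                            n=n)


def residualize(variable, covariates=None) -> np.ndarray:
    """OLS residuals of ``variable`` on the covariates (plus intercept).

    With no covariates this is mean-centring.  Residuals have mean zero
    and are orthogonal to every covariate.
    """
    y = _as_clean_array(variable, "variable")
    if covariates is None or (hasattr(covariates, "__len__")
                              and len(covariates) == 0):
        return y - y.mean()
    X = _design_frame(covariates)
    fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
    return np.asarray(fit.resid)


@dataclass
class MediationFit:
    """Fully standardized mediation paths and uncertainty estimates.

    Paths: ``a`` (X -> M), ``b`` (M -> Y | X), ``c`` (total X -> Y),
    ``c_prime`` (direct X -> Y | M), ``indirect = a * b``.  On one
    sample ``c = c_prime + indirect`` holds exactly.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    se: dict
    p: dict
    n: int
    method: str = "delta"
    n_boot: int = 0
    seed: int = None
    boot_ci: tuple = None


def _boot_indirect(x, m, y, rng):
    idx = rng.integers(0, x.size, x.size)
    xs, ms, ys = x[idx], m[idx], y[idx]
    # fully standardized paths from the correlation structure
    r_xm = np.corrcoef(xs, ms)[0, 1]
    r_xy = np.corrcoef(xs, ys)[0, 1]
    r_my = np.corrcoef(ms, ys)[0, 1]
    denom = 1.0 - r_xm ** 2
    if denom <= 0:
        return np.nan
    b = (r_my - r_xy * r_xm) / denom
    return r_xm * b


def mediation_fit(x, m, y, method: str = "delta", n_boot: int = 5000,
                  seed: int = None) -> MediationFit:
    """Product-of-coefficients mediation on z-scored x, m, y.

    ``method="delta"`` gives Sobel standard errors and two-sided normal
    p values for the indirect effect; ``method="bootstrap"`` adds a
    percentile bootstrap (fixed ``seed``) for the indirect effect's
    standard error, CI and p value.  Path-level SEs and p values always
    come from the two OLS fits.
    """
    if method not in ("delta", "bootstrap"):
        raise ValueError(f"unknown mediation method {method!r}")
    arrs = [np.asarray(v, dtype=float).ravel() for v in (x, m, y)]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("x, m, y must have equal length")
    complete = np.all(np.isfinite(np.column_stack(arrs)), axis=1)
    x, m, y = (a[complete] for a in arrs)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 complete (x, m, y) triples")
    xz, mz, yz = _zscore(x, "x"), _zscore(m, "m"), _zscore(y, "y")

    fit_a = sm.OLS(mz, sm.add_constant(xz)).fit()
    fit_b = sm.OLS(yz, sm.add_constant(np.column_stack([xz, mz]))).fit()
    fit_c = sm.OLS(yz, sm.add_constant(xz)).fit()
    a, sa = fit_a.params[1], fit_a.bse[1]
    c_prime, b = fit_b.params[1], fit_b.params[2]
    sc_prime, sb = fit_b.bse[1], fit_b.bse[2]
    c, sc = fit_c.params[1], fit_c.bse[1]
    indirect = a * b
    se_ind = np.sqrt(a ** 2 * sb ** 2 + b ** 2 * sa ** 2)  # Sobel

    def norm_p(est, se):
        if se == 0:
            return 0.0 if est != 0 else 1.0
        return float(2 * sps.norm.sf(abs(est) / se))

    se = {"a": float(sa), "b": float(sb), "c": float(sc),
          "c_prime": float(sc_prime), "indirect": float(se_ind)}
    p = {"a": float(fit_a.pvalues[1]), "b": float(fit_b.pvalues[2]),
         "c": float(fit_c.pvalues[1]), "c_prime": float(fit_b.pvalues[1]),
         "indirect": norm_p(indirect, se_ind)}
    boot_ci = None
    used_boot = 0
    if method == "bootstrap":
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        rng = np.random.default_rng(seed)
        draws = np.array([_boot_indirect(xz, mz, yz, rng)
                          for _ in range(n_boot)])
        draws = draws[np.isfinite(draws)]
        used_boot = n_boot
        se["indirect"] = float(draws.std(ddof=1))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        boot_ci = (float(lo), float(hi))
        frac_le = np.mean(draws <= 0)
        frac_ge = np.mean(draws >= 0)
        p["indirect"] = float(min(1.0, 2 * min(frac_le, frac_ge)))

    return MediationFit(a=float(a), b=float(b), c=float(c),
                        c_prime=float(c_prime), indirect=float(indirect),
                        se=se, p=p, n=n, method=method, n_boot=used_boot,
                        seed=seed, boot_ci=boot_ci)


def proportion_mediated(fit: MediationFit) -> float:
    """Indirect effect as a percentage of the total effect, 100*(a*b)/c."""
    if abs(fit.c) < 1e-10:
        raise ValueError("proportion mediated undefined: total effect is zero")
    return 100.0 * fit.indirect / fit.c


# ---------------------------------------------------------------------------
# Report tables on a scored subject table
# ---------------------------------------------------------------------------

TRAITS = ["neuroticism", "extraversion", "openness",
          "agreeableness", "conscientiousness"]
FMRI_SCORES = ["a_prime", "fade_memory", "same_memory",
               "fade_novelty", "same_novelty"]
COVARIATES = ["age", "gender", "education", "mwtb"]


def _groups(subjects: pd.DataFrame):
    return (subjects[subjects["group"] == "young"],
            subjects[subjects["group"] == "older"])


def build_table1(subjects: pd.DataFrame) -> pd.DataFrame:
    """Group descriptives: mean (s.d.) per group with t or chi-square tests."""
    young, older = _groups(subjects)
    rows = []
    continuous = (["age", "mwtb"] + FMRI_SCORES + TRAITS)
    for var in ["age", "gender", "education", "mwtb"] + FMRI_SCORES + TRAITS:
        if var not in subjects.columns:
            continue
        if var in continuous:
            yv = young[var].dropna().to_numpy()
            ov = older[var].dropna().to_numpy()
            cmp_ = group_compare(ov, yv)  # older - young difference
            rows.append({
                "variable": var,
                "young_mean": yv.mean(), "young_sd": yv.std(ddof=1),
                "older_mean": ov.mean(), "older_sd": ov.std(ddof=1),
                "test": "t", "statistic": cmp_.t, "p": cmp_.p,
                "effect_size": cmp_.cohens_d,
            })
        else:  # binary: chi-square on the 2x2 group x level table
            table = [[(young[var] == lv).sum() for lv in (0, 1)],
                     [(older[var] == lv).sum() for lv in (0, 1)]]
            chi2, p = chi_square_independence(table)
            rows.append({
                "variable": var,
                "young_mean": young[var].mean(), "young_sd": np.nan,
                "older_mean": older[var].mean(), "older_sd": np.nan,
                "test": "chi2", "statistic": chi2, "p": p,
                "effect_size": np.nan,
            })
    return pd.DataFrame(rows)


def build_table2(subjects: pd.DataFrame) -> pd.DataFrame:
    """Trait-score correlations per group, long format (group, measure,
    trait, r, p), including each score's correlation with A'."""
    rows = []
    for gname, g in zip(("young", "older"), _groups(subjects)):
        for measure in FMRI_SCORES:
            for trait in TRAITS + ["a_prime"]:
                if trait == measure:
                    continue
                sub = g[[measure, trait]].dropna()
                r, p = correlate(sub[measure], sub[trait])
                rows.append({"group": gname, "measure": measure,
                             "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def build_table3(subjects: pd.DataFrame, group: str = "older") -> pd.DataFrame:
    """Standardized regressions of A' and the memory scores on Openness
    plus demographic and crystallized-intelligence covariates."""
    g = subjects[subjects["group"] == group]
    rows = []
    predictors = ["openness"] + COVARIATES
    for outcome in ("a_prime", "fade_memory", "same_memory"):
        sub = g[[outcome] + predictors].dropna()
        res = standardized_regression(sub[outcome], sub[predictors])
        for pred in predictors:
            rows.append({"outcome": outcome, "predictor": pred,
                         "beta": res.beta[pred], "p": res.pvalues[pred],
                         "n": res.n, "r_squared": res.r_squared})
    return pd.DataFrame(rows)


def build_table4(subjects: pd.DataFrame, mediators=("fade_memory",
                                                    "same_memory"),
                 method: str = "delta", n_boot: int = 5000,
                 seed: int = None, group: str = "older") -> pd.DataFrame:
    """Mediation of the Openness -> A' effect through each fMRI score."""
    g = subjects[subjects["group"] == group]
    rows = []
    for mediator in mediators:
        sub = g[["openness", mediator, "a_prime"]].dropna()
        fit = mediation_fit(sub["openness"], sub[mediator], sub["a_prime"],
                            method=method, n_boot=n_boot, seed=seed)
        prop = proportion_mediated(fit) if abs(fit.c) > 1e-10 else np.nan
        for path, est, p in (
                ("total", fit.c, fit.p["c"]),
                ("direct_mediator_to_y", fit.b, fit.p["b"]),
                ("direct_x_to_y", fit.c_prime, fit.p["c_prime"]),
                ("indirect", fit.indirect, fit.p["indirect"])):
            rows.append({"mediator": mediator, "path": path, "beta": est,
                         "p": p, "proportion_mediated":
                             prop if path == "indirect" else np.nan,
                         "n": fit.n})
    return pd.DataFrame(rows)
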