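"""Mixed-effects models of climate sensitivity.

The response is a site's climate-growth correlation coefficient r (one
row per site x period x season for a given climate variable).  Fixed
effects: SDM group, period (early/late), their interaction, the site's
bioclimatic normals (BIO9, BIO10, BIO11, BIO18) and stand age; crossed
random intercepts for season and site; estimation by REML.  Marginal
effects at the mean (MEM) are model predictions on the group x period
grid with continuous covariates at their means and random effects at
zero; period/group contrasts use Tukey's studentized-range adjustment
with a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTINUOUS = ("bio9", "bio10", "bio11", "bio18", "stand_age")
REQUIRED = ("r", "sdm_group", "period", "season", "site_id") + CONTINUOUS


@dataclass
class SensitivityFit:
    """A fitted sensitivity model plus what is needed for predictions."""

    result: object                      # statsmodels MixedLMResults
    data: pd.DataFrame                  # model frame with z-scored covariates
    formula: str
    centers: dict[str, float]
    scales: dict[str, float]
    converged: bool
    singular: list[str] = field(default_factory=list)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def vcomp(self) -> dict[str, float]:
        names = self.result.model.exog_vc.names
        return {n: float(v) for n, v in zip(names, self.result.vcomp)}

    @property
    def sigma2_resid(self) -> float:
        return float(self.result.scale)


@dataclass
class MarginalEffect:
    sdm_group: str
    period: str
    estimate: float
    se: float
    letter: str = ""


@dataclass
class ModelDiagnostics:
    r2_marginal: float
    r2_conditional: float
    shapiro_w: float
    shapiro_p: float
    vif: dict[str, float]
    resid_fitted_slope: float


def fit_sensitivity_lmm(
    data: pd.DataFrame,
    interaction: bool = True,
    season_fixed: bool = False,
) -> SensitivityFit:
    """Fit the climate-sensitivity mixed model by REML.

    Continuous covariates are centered and scaled internally (reported
    MEMs are invariant to this).  ``season_fixed=True`` moves season from
    the random to the fixed part (robustness variant for the three-level
    factor).  Variance components that collapse to zero are reported in
    ``singular`` with a warning rather than an error.
    """
    import statsmodels.formula.api as smf

    missing = [c for c in REQUIRED if c not in data.columns]
    if missing:
        raise ValueError(f"sensitivity table missing columns {missing}")
    d = data.dropna(subset=["r"]).copy()
    if len(d) < 30:
        raise ValueError(f"only {len(d)} rows; need >= 30")
    if d["period"].nunique() < 2:
        raise ValueError("both periods must be present")

    centers, scales = {}, {}
    for c in CONTINUOUS:
        mu, sd = float(d[c].mean()), float(d[c].std(ddof=0))
        centers[c], scales[c] = mu, sd if sd > 0 else 1.0
        d[f"{c}_z"] = (d[c] - centers[c]) / scales[c]

    op = "*" if interaction else "+"
    fixed = f"r ~ sdm_group {op} period + " + " + ".join(
        f"{c}_z" for c in CONTINUOUS)
    if season_fixed:
        fixed += " + C(season)"
        vc = {"site": "0 + C(site_id)"}
    else:
        vc = {"season": "0 + C(season)", "site": "0 + C(site_id)"}
    d["_all"] = 1

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(fixed, d, groups="_all", vc_formula=vc,
                            re_formula="0")
        result = model.fit(reml=True, method=["lbfgs", "powell"])
    singular = []
    for name, v in zip(model.exog_vc.names, result.vcomp):
        if v < 1e-8:
            singular.append(name)
    if singular:
        warnings.warn(f"variance component(s) {singular} estimated at zero "
                      "(singular fit)", stacklevel=2)
    del caught
    return SensitivityFit(result=result, data=d, formula=fixed,
                          centers=centers, scales=scales,
                          converged=bool(result.converged),
                          singular=singular)


def _grid_design(fit: SensitivityFit) -> tuple[pd.DataFrame, np.ndarray]:
    from patsy import dmatrix

    groups = sorted(fit.data["sdm_group"].unique())
    periods = sorted(fit.data["period"].unique())
    rows = []
    for g in groups:
        for p in periods:
            row = {"sdm_group": g, "period": p}
            for c in CONTINUOUS:
                row[f"{c}_z"] = 0.0  # covariates at their means
            if "C(season)" in fit.formula:
                row["season"] = sorted(fit.data["season"].unique())[0]
            rows.append(row)
    grid = pd.DataFrame(rows)
    design_info = fit.result.model.data.design_info
    X = np.asarray(dmatrix(design_info, grid, return_type="matrix"))
    return grid, X


def marginal_effects(fit: SensitivityFit) -> list[MarginalEffect]:
    """Marginal effects at the mean on the SDM-group x period grid.

    Predictions use the fixed effects only (random effects at zero) with
    continuous covariates fixed at their sample means; standard errors
    come from the fixed-effects covariance.
    """
    grid, X = _grid_design(fit)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    est = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    mems = [
        MarginalEffect(r.sdm_group, r.period, float(e), float(s))
        for r, e, s in zip(grid.itertuples(index=False), est, se)
    ]
    letters = tukey_letters(mems, X, cov, df=_residual_df(fit))
    for m, letter in zip(mems, letters):
        m.letter = letter
    return mems


def _residual_df(fit: SensitivityFit) -> float:
    n = len(fit.data)
    p = len(fit.fe_params)
    return max(n - p, 2)


def tukey_contrasts(
    mems: list[MarginalEffect], X: np.ndarray, cov: np.ndarray, df: float
) -> pd.DataFrame:
    """All pairwise MEM contrasts with studentized-range (Tukey) adjusted
    p-values."""
    k = len(mems)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = X[i] - X[j]
            var = float(c @ cov @ c)
            diff = mems[i].estimate - mems[j].estimate
            se = np.sqrt(var)
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p = 1.0 - stats.studentized_range.cdf(abs(t) * np.sqrt(2.0), k, df)
            rows.append({
                "level_a": f"{mems[i].sdm_group}:{mems[i].period}",
                "level_b": f"{mems[j].sdm_group}:{mems[j].period}",
                "estimate": diff, "se": se, "t": t,
                "p_adjusted": float(np.clip(p, 0.0, 1.0)),
            })
    return pd.DataFrame(rows)


def compact_letters(significant: np.ndarray, order: np.ndarray) -> list[str]:
    """Compact letter display by insert-and-absorb.

    ``significant[i, j]`` marks pairs that differ; levels sharing a letter
    are never significantly different.  ``order`` ranks levels (best
    first) for letter assignment, making the display deterministic.
    """
    k = significant.shape[0]
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    a, b = col - {i}, col - {j}
                    for new in (a, b):
                        if new and not any(new <= other for other in columns):
                            columns.append(new)
            columns = [c for c in columns
                       if not any(c < other for other in columns)]
    # assign letters in estimate order for stability
    ranked = sorted(columns, key=lambda c: min(int(np.where(order == m)[0][0])
                                               for m in c))
    letters = ["" for _ in range(k)]
    for idx, col in enumerate(ranked):
        ch = chr(ord("a") + idx)
        for m in col:
            letters[m] += ch
    return letters


def tukey_letters(
    mems: list[MarginalEffect], X: np.ndarray, cov: np.ndarray,
    df: float, alpha: float = 0.05,
) -> list[str]:
    table = tukey_contrasts(mems, X, cov, df)
    k = len(mems)
    sig = np.zeros((k, k), dtype=bool)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            sig[i, j] = sig[j, i] = table.iloc[idx]["p_adjusted"] < alpha
            idx += 1
    order = np.argsort([-m.estimate for m in mems])
    return compact_letters(sig, order)


def mem_table(mems: list[MarginalEffect]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in mems])


def diagnostics(fit: SensitivityFit) -> ModelDiagnostics:
    """Nakagawa-style R2, residual normality, residual-vs-fitted slope
    and variance inflation factors of the fixed-effects design."""
    result = fit.result
    X = np.asarray(result.model.exog)
    beta = np.asarray(fit.fe_params)
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    var_re = float(np.sum(result.vcomp))
    var_resid = fit.sigma2_resid
    denom = var_fixed + var_re + var_resid
    resid = np.asarray(result.resid)
    fitted = np.asarray(result.fittedvalues)
    slope = float(np.polyfit(fitted, resid, 1)[0]) if np.var(fitted) > 0 else 0.0
    if len(resid) <= 5000:
        w, p = stats.shapiro(resid)
    else:
        w, p = np.nan, np.nan

    names = result.model.exog_names
    vif: dict[str, float] = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        others = [jj for jj in range(X.shape[1]) if jj != j]
        Xo = X[:, others]
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(Xo, y, rcond=None)
        resid_j = y - Xo @ coef
        ss_res = float((resid_j**2).sum())
        ss_tot = float(((y - y.mean())**2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        vif[name] = 1.0 / (1.0 - min(r2, 1.0 - 1e-12))
    return ModelDiagnostics(
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + var_re) / denom,
        shapiro_w=float(w), shapiro_p=float(p),
        vif=vif,
        resid_fitted_slope=slope,
    )
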