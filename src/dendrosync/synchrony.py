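"""Growth synchrony: running rbar and variance-components synchrony (a_C).

Within-population synchrony is the mean pairwise Pearson correlation of a
site's RWI series (rbar), computed in a 20-year moving window.  Regional
synchrony a_C is estimated from pre-whitened site chronologies with a
homoscedastic variance-components mixed model

    rwi[s, t] = mu[g(s)] + Y[g(s), t] + eps[s, t]

with independent group-specific random year effects Y (variance
sigma2_year[g]) and a common residual variance sigma2_resid, fitted by
restricted maximum likelihood (REML).  The synchrony of group g is

    a_C[g] = sigma2_year[g] / (sigma2_year[g] + sigma2_resid)

ranging from 0 (no shared year-to-year signal between site chronologies)
to 1 (fully regional synchronization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from dendrosync.chronology import SiteChronology

DEFAULT_RBAR_WINDOW = 20
DEFAULT_MIN_TREES = 6

_LOGV_MIN, _LOGV_MAX = -20.0, 5.0


@dataclass
class SynchronyFit:
    group: str
    period: str
    sigma2_year: float
    sigma2_resid: float
    a_hat: float
    se_a_hat: float
    n_chronologies: int
    n_years: int
    converged: bool = True


# ---------------------------------------------------------------------------
# rbar
# ---------------------------------------------------------------------------

def rwi_matrix(detrended, years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Stack detrended series of one site into a trees x years DataFrame."""
    cols = {}
    for d in detrended:
        cols[d.tree_id] = pd.Series(d.rwi, index=d.years)
    df = pd.DataFrame(cols).T
    df = df.reindex(sorted(df.columns), axis=1)
    if years is not None:
        df = df.loc[:, (df.columns >= years[0]) & (df.columns <= years[1])]
    return df


def mean_pairwise_correlation(block: np.ndarray) -> tuple[float, int]:
    """Mean Pearson correlation over all tree pairs of a complete
    trees x years block; returns (rbar, n_pairs)."""
    n = block.shape[0]
    if n < 2:
        return np.nan, 0
    cm = np.corrcoef(block)
    iu = np.triu_indices(n, k=1)
    vals = cm[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan, len(iu[0])


def moving_rbar(
    matrix: pd.DataFrame,
    window: int = DEFAULT_RBAR_WINDOW,
    step: int = 1,
    min_trees: int = DEFAULT_MIN_TREES,
) -> pd.DataFrame:
    """Running rbar over a trees x years matrix.

    For each window only trees with complete coverage enter; windows with
    fewer than ``min_trees`` such trees are skipped.  Returns a frame
    with ``window_end_year, rbar, n_trees, n_pairs``.
    """
    years = np.asarray(matrix.columns, dtype=int)
    vals = matrix.to_numpy(dtype=float)
    rows = []
    for end_idx in range(window - 1, len(years), step):
        sl = vals[:, end_idx - window + 1 : end_idx + 1]
        complete = ~np.isnan(sl).any(axis=1)
        if complete.sum() < min_trees:
            continue
        block = sl[complete]
        rbar, n_pairs = mean_pairwise_correlation(block)
        rows.append({
            "window_end_year": int(years[end_idx]),
            "rbar": rbar,
            "n_trees": int(complete.sum()),
            "n_pairs": n_pairs,
        })
    if not rows:
        import warnings
        warnings.warn("no rbar window satisfies the minimum tree count",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["window_end_year", "rbar",
                                       "n_trees", "n_pairs"])


def group_rbar_curve(
    site_rbar: Mapping[str, pd.DataFrame], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Cross-site mean and standard error of rbar per group and window end
    year (the synchrony curve plotted against the window end)."""
    rows = []
    for site_id, df in site_rbar.items():
        for rec in df.itertuples(index=False):
            rows.append({"group": groups[site_id],
                         "window_end_year": rec.window_end_year,
                         "rbar": rec.rbar})
    long = pd.DataFrame(rows)
    if long.empty:
        return pd.DataFrame(columns=["group", "window_end_year",
                                     "mean_rbar", "se", "n_sites"])
    out = []
    for (group, end), grp in long.groupby(["group", "window_end_year"]):
        vals = grp["rbar"].to_numpy()
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        out.append({"group": group, "window_end_year": int(end),
                    "mean_rbar": float(vals.mean()), "se": se,
                    "n_sites": len(vals)})
    return pd.DataFrame(out)


def write_rbar_csv(site_rbar: Mapping[str, pd.DataFrame], path) -> None:
    frames = []
    for site_id, df in site_rbar.items():
        d = df.copy()
        d.insert(0, "site_id", site_id)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# variance-components synchrony (REML)
# ---------------------------------------------------------------------------

def _prepare_long(
    chronologies: Sequence[SiteChronology],
    groups: Mapping[str, str],
    years: tuple[int, int] | None,
) -> pd.DataFrame:
    rows = []
    for ch in chronologies:
        g = groups[ch.site_id]
        for year, v in zip(ch.years, ch.rwi):
            if not np.isfinite(v):
                continue
            if years is not None and not years[0] <= year <= years[1]:
                continue
            rows.append((ch.site_id, g, int(year), float(v)))
    return pd.DataFrame(rows, columns=["site_id", "group", "year", "rwi"])


def _reml_neg2ll(theta: np.ndarray, clusters: list, group_index: dict) -> float:
    """-2 restricted log-likelihood of the grouped year-effect model.

    ``clusters`` holds (group, n, sum_y, sum_y2, y) per (group, year)
    cell; theta = log variances (one per group, then residual).
    """
    s_yr = np.exp(theta[:-1])
    s_e = np.exp(theta[-1])
    G = len(group_index)
    xtvx = np.zeros(G)
    xtvy = np.zeros(G)
    logdet = 0.0
    for g_idx, n, sy, *_ in clusters:
        d = s_e + n * s_yr[g_idx]
        logdet += (n - 1) * np.log(s_e) + np.log(d)
        xtvx[g_idx] += n / d
        xtvy[g_idx] += sy / d
    mu = xtvy / xtvx
    quad = 0.0
    for g_idx, n, sy, sy2, _ in clusters:
        m = mu[g_idx]
        rs = sy - n * m            # sum of residuals
        rs2 = sy2 - 2 * m * sy + n * m * m  # sum of squared residuals
        d = s_e + n * s_yr[g_idx]
        quad += (rs2 - (s_yr[g_idx] / d) * rs * rs) / s_e
    return logdet + np.log(xtvx).sum() + quad


def fit_synchrony(
    chronologies: Sequence[SiteChronology],
    groups: Mapping[str, str],
    years: tuple[int, int] | None = None,
    period: str = "full",
    min_chronologies: int = 5,
    n_restarts: int = 3,
) -> dict[str, SynchronyFit]:
    """REML fit of the grouped variance-components synchrony model.

    Returns one :class:`SynchronyFit` per group with the shared-year
    variance, residual variance, a_C and its delta-method standard error.
    Variances are parameterized on the log scale (hence non-negative);
    non-convergence triggers random restarts before raising.
    """
    long = _prepare_long(chronologies, groups, years)
    if long.empty:
        raise ValueError("no chronology data in the requested period")
    group_names = sorted(long["group"].unique())
    group_index = {g: i for i, g in enumerate(group_names)}
    for g in group_names:
        n_ch = long.loc[long["group"] == g, "site_id"].nunique()
        if n_ch < min_chronologies:
            raise ValueError(f"group {g!r}: {n_ch} chronologies "
                             f"(need >= {min_chronologies})")
        n_yr = long.loc[long["group"] == g, "year"].nunique()
        if n_yr < 20:
            raise ValueError(f"group {g!r}: only {n_yr} years (need >= 20)")

    clusters = []
    for (g, _), grp in long.groupby(["group", "year"]):
        y = grp["rwi"].to_numpy()
        clusters.append((group_index[g], len(y), float(y.sum()),
                         float((y**2).sum()), y))

    var0 = float(long["rwi"].var())
    x0 = np.log(np.r_[np.full(len(group_names), var0 / 2), var0 / 2])
    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 1.5, size=x0.size)
        res = minimize(_reml_neg2ll, start, args=(clusters, group_index),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10,
                                "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("synchrony REML failed to converge; "
                           f"last result: {best}")
    theta = np.clip(best.x, _LOGV_MIN, _LOGV_MAX)

    # observed-information covariance of theta by central differences
    h = 1e-4
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = _reml_neg2ll(theta + ei + ej, clusters, group_index)
            fpm = _reml_neg2ll(theta + ei - ej, clusters, group_index)
            fmp = _reml_neg2ll(theta - ei + ej, clusters, group_index)
            fmm = _reml_neg2ll(theta - ei - ej, clusters, group_index)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov_theta = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_theta = np.full((k, k), np.nan)

    s_e = float(np.exp(theta[-1]))
    fits: dict[str, SynchronyFit] = {}
    for g, gi in group_index.items():
        s_yr = float(np.exp(theta[gi]))
        a = s_yr / (s_yr + s_e)
        # delta method: da/dlog(s_yr) = a(1-a), da/dlog(s_e) = -a(1-a)
        grad = np.zeros(k)
        grad[gi] = a * (1 - a)
        grad[-1] = -a * (1 - a)
        var_a = float(grad @ cov_theta @ grad)
        sub = long[long["group"] == g]
        fits[g] = SynchronyFit(
            group=g, period=period,
            sigma2_year=s_yr, sigma2_resid=s_e,
            a_hat=a,
            se_a_hat=float(np.sqrt(var_a)) if var_a >= 0 else np.nan,
            n_chronologies=sub["site_id"].nunique(),
            n_years=sub["year"].nunique(),
            converged=bool(best.success),
        )
    return fits
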