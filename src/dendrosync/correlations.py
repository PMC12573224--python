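"""Seasonal climate-growth correlations with bootstrap significance.

For each site the pre-whitened chronology is correlated (Pearson) with
monthly and multi-month (2-5 month) aggregates of mean temperature,
climatic water balance and VPD inside three fixed seasons on the
ring-year axis: the previous growing season (Jun-Oct of the prior year),
dormancy (Nov-Mar) and the current growing season (Apr-Sep).
Significance and 95% intervals come from a pairs bootstrap (1000
replications, percentile method); network summaries report the share of
significant sites and sign-separated median correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dendrosync import climate as clim
from dendrosync.chronology import SiteChronology

VARIABLES = ("tmean", "cwb", "vpd")

#: Minimum overlapping years for any correlation.
MIN_OVERLAP = 20

_MONTH_ABBR = ["", "Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass(frozen=True)
class PeriodSplit:
    """Early/late sub-periods of the record (both at least 20 years)."""

    early: tuple[int, int] = (1950, 1985)
    late: tuple[int, int] = (1986, 2023)

    def __post_init__(self) -> None:
        e0, e1 = self.early
        l0, l1 = self.late
        if not (e0 <= e1 < l0 <= l1):
            raise ValueError("periods must be ordered and disjoint")
        if e1 - e0 + 1 < MIN_OVERLAP or l1 - l0 + 1 < MIN_OVERLAP:
            raise ValueError(f"each period needs >= {MIN_OVERLAP} years")

    def bounds(self, period: str) -> tuple[int, int]:
        if period == "full":
            return (self.early[0], self.late[1])
        if period == "early":
            return self.early
        if period == "late":
            return self.late
        raise ValueError(f"unknown period {period!r}")


@dataclass(frozen=True)
class Window:
    """A contiguous run of months inside one season."""

    season: str
    months: tuple[tuple[int, int], ...]  # (year offset, month) pairs

    @property
    def length(self) -> int:
        return len(self.months)

    @property
    def start(self) -> tuple[int, int]:
        return self.months[0]

    @property
    def label(self) -> str:
        def tag(off_m):
            off, m = off_m
            return _MONTH_ABBR[m] + ("*" if off == -1 else "")
        if self.length == 1:
            return tag(self.months[0])
        return f"{tag(self.months[0])}-{tag(self.months[-1])}"

    @property
    def key(self) -> str:
        """Serializable window identity, e.g. ``-1:11;0:1``."""
        return ";".join(f"{off}:{m}" for off, m in self.months)


@dataclass
class CorrelationResult:
    site_id: str
    variable: str
    season: str
    window: Window
    period: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_years: int
    valid: bool = True


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    variable: str
    season: str
    klass: str  # positive | negative | insignificant


def enumerate_windows(season: str, max_length: int = 5) -> list[Window]:
    """All contiguous 1..max_length-month windows inside a season.

    The 6-month current growing season yields 20 windows, the two 5-month
    seasons 15 each; windows never cross season boundaries.
    """
    months = clim.SEASONS[season]
    out = []
    for length in range(1, min(max_length, len(months)) + 1):
        for start in range(len(months) - length + 1):
            out.append(Window(season, tuple(months[start : start + length])))
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _bootstrap_r(x: np.ndarray, y: np.ndarray, n_boot: int,
                 rng: np.random.Generator) -> np.ndarray:
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def correlate(
    chron: SiteChronology,
    monthly: pd.DataFrame,
    variable: str,
    window: Window,
    period: str = "full",
    split: PeriodSplit = PeriodSplit(),
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Pearson correlation of the chronology with one climate window,
    with a pairs bootstrap (percentile CI; two-sided p as twice the
    smaller sign-crossing fraction)."""
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = split.bounds(period)
    years = chron.years[(chron.years >= lo) & (chron.years <= hi)]
    climate_vals = clim.window_series(monthly, window.months, variable, years)
    rwi = chron.to_series().reindex(climate_vals.index)
    paired = pd.DataFrame({"x": climate_vals, "y": rwi}).dropna()
    n = len(paired)
    if n < MIN_OVERLAP:
        return CorrelationResult(chron.site_id, variable, window.season, window,
                                 period, np.nan, np.nan, np.nan, np.nan, n,
                                 valid=False)
    x = paired["x"].to_numpy()
    y = paired["y"].to_numpy()
    r = _pearson(x, y)
    rb = _bootstrap_r(x, y, n_boot, rng)
    rb = rb[np.isfinite(rb)]
    ci_low, ci_high = np.percentile(rb, [2.5, 97.5])
    p = 2.0 * min((rb <= 0).mean(), (rb >= 0).mean())
    return CorrelationResult(chron.site_id, variable, window.season, window,
                             period, r, float(ci_low), float(ci_high),
                             float(min(p, 1.0)), n)


def site_correlations(
    chron: SiteChronology,
    monthly: pd.DataFrame,
    variables: Sequence[str] = VARIABLES,
    periods: Sequence[str] = ("full", "early", "late"),
    split: PeriodSplit = PeriodSplit(),
    n_boot: int = 1000,
    seed: int = 0,
) -> list[CorrelationResult]:
    """All window correlations of one site (every variable, season, window
    and period), with one reproducible bootstrap stream per
    site/variable/season/period cell."""
    import hashlib

    out: list[CorrelationResult] = []
    for variable in variables:
        for season in clim.SEASON_NAMES:
            windows = enumerate_windows(season)
            for period in periods:
                key = f"{chron.site_id}/{variable}/{season}/{period}"
                digest = int.from_bytes(
                    hashlib.sha256(key.encode()).digest()[:8], "little")
                rng = np.random.default_rng(np.random.SeedSequence([seed, digest]))
                for window in windows:
                    out.append(correlate(chron, monthly, variable, window,
                                         period, split, n_boot, rng))
    return out


def best_seasonal(results: Iterable[CorrelationResult]) -> CorrelationResult | None:
    """The window with the largest absolute correlation (sign retained)
    within one site x variable x season cell; ties go to the longer
    window, then the earlier start."""
    valid = [r for r in results if r.valid and np.isfinite(r.r)]
    if not valid:
        return None
    return min(valid, key=lambda c: (-abs(c.r), -c.window.length, c.window.start))


def best_by_cell(
    results: Iterable[CorrelationResult],
) -> dict[tuple[str, str, str, str], CorrelationResult]:
    """Best window per (site, variable, season, period) cell."""
    cells: dict[tuple[str, str, str, str], list[CorrelationResult]] = {}
    for r in results:
        cells.setdefault((r.site_id, r.variable, r.season, r.period), []).append(r)
    out = {}
    for key, rs in cells.items():
        best = best_seasonal(rs)
        if best is not None:
            out[key] = best
    return out


def classify_sites(
    best: Iterable[CorrelationResult], alpha: float = 0.05
) -> tuple[list[SiteClassification], pd.DataFrame]:
    """Classify each best correlation as positive/negative/insignificant
    and summarise the share of significant sites per variable x season."""
    classes = []
    for r in best:
        if np.isfinite(r.p) and r.p < alpha:
            klass = "positive" if r.r > 0 else "negative"
        else:
            klass = "insignificant"
        classes.append(SiteClassification(r.site_id, r.variable, r.season, klass))
    rows = []
    df = pd.DataFrame([c.__dict__ for c in classes])
    if df.empty:
        return classes, pd.DataFrame(
            columns=["variable", "season", "pct_positive", "pct_negative",
                     "pct_significant", "n_sites"])
    for (variable, season), grp in df.groupby(["variable", "season"]):
        n = len(grp)
        pos = (grp["klass"] == "positive").sum()
        neg = (grp["klass"] == "negative").sum()
        rows.append({
            "variable": variable, "season": season,
            "pct_positive": 100.0 * pos / n,
            "pct_negative": 100.0 * neg / n,
            "pct_significant": 100.0 * (pos + neg) / n,
            "n_sites": n,
        })
    return classes, pd.DataFrame(rows)


def median_correlations(best: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Sign-separated medians of the best correlations, regardless of
    significance, per variable x season."""
    rows = []
    df = pd.DataFrame([
        {"variable": r.variable, "season": r.season, "r": r.r}
        for r in best if r.valid and np.isfinite(r.r)
    ])
    if df.empty:
        return pd.DataFrame(columns=["variable", "season", "sign", "median_r", "n"])
    for (variable, season), grp in df.groupby(["variable", "season"]):
        for sign, sel in (("positive", grp[grp["r"] > 0]),
                          ("negative", grp[grp["r"] < 0])):
            if len(sel):
                rows.append({"variable": variable, "season": season,
                             "sign": sign, "median_r": float(sel["r"].median()),
                             "n": len(sel)})
    return pd.DataFrame(rows)


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "site_id": r.site_id, "variable": r.variable, "season": r.season,
            "window": r.window.label, "window_months": r.window.key,
            "window_length": r.window.length,
            "start_offset": r.window.start[0], "start_month": r.window.start[1],
            "period": r.period, "r": r.r, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "p": r.p, "n_years": r.n_years,
            "valid": r.valid,
        })
    return pd.DataFrame(rows)


def best_by_cell_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Frame-based version of :func:`best_by_cell`: the best window row
    per (site, variable, season, period) cell, same tie-break order."""
    sel = df[df["valid"] & df["r"].notna()].copy()
    if sel.empty:
        return sel
    sel["_abs_r"] = sel["r"].abs()
    sel = sel.sort_values(
        ["site_id", "variable", "season", "period",
         "_abs_r", "window_length", "start_offset", "start_month"],
        ascending=[True, True, True, True, False, False, True, True],
    )
    out = sel.groupby(["site_id", "variable", "season", "period"],
                      as_index=False).head(1)
    return out.drop(columns="_abs_r").reset_index(drop=True)
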