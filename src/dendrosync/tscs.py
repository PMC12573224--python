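"""Temporal shifts in climate sensitivity (TSCS).

A site's sensitivity shift for one climate window is

    delta_r = |r_late| - |r_early|

the change in absolute correlation between the late (1986 onward) and
early (1950-1985) periods.  Only windows whose full-period correlation is
significant are carried into the comparison.  Distributions of
correlations are compared between SDM groups with the two-sample
Kolmogorov-Smirnov test, and delta-r distributions with the two-sample
Wilcoxon rank-sum (Mann-Whitney) test, Holm-adjusted when more than two
groups are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dendrosync.correlations import CorrelationResult


@dataclass(frozen=True)
class DeltaR:
    site_id: str
    variable: str
    season: str
    window_label: str
    r_early: float
    r_late: float

    @property
    def delta(self) -> float:
        return abs(self.r_late) - abs(self.r_early)


def delta_r(early: CorrelationResult, late: CorrelationResult) -> DeltaR | None:
    """Sensitivity shift for one site/variable/window; None when either
    period lacks a valid correlation."""
    if not (early.valid and late.valid):
        return None
    if (early.site_id, early.variable, early.window) != (
            late.site_id, late.variable, late.window):
        raise ValueError("early/late results refer to different cells")
    return DeltaR(early.site_id, early.variable, early.season,
                  early.window.label, early.r, late.r)


def select_tscs_windows(
    full_results: Iterable[CorrelationResult], alpha: float = 0.05
) -> set[tuple[str, str, tuple]]:
    """Keys (site, variable, window months) of windows whose full-period
    correlation is significant; only these enter the early/late contrast."""
    return {
        (r.site_id, r.variable, r.window.months)
        for r in full_results
        if r.valid and np.isfinite(r.p) and r.p < alpha
    }


def compute_deltas(
    results: Iterable[CorrelationResult], alpha: float = 0.05
) -> list[DeltaR]:
    """Pair early/late correlations for every window that is significant
    over the full period and compute delta-r."""
    by_period: dict[str, dict[tuple, CorrelationResult]] = {
        "full": {}, "early": {}, "late": {}}
    for r in results:
        if r.period in by_period:
            by_period[r.period][(r.site_id, r.variable, r.window.months)] = r
    selected = select_tscs_windows(by_period["full"].values(), alpha)
    out = []
    for key in sorted(selected):
        early = by_period["early"].get(key)
        late = by_period["late"].get(key)
        if early is None or late is None:
            continue
        d = delta_r(early, late)
        if d is not None:
            out.append(d)
    return out


def compute_deltas_frame(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Frame-based :func:`compute_deltas` for CSV round trips: pair early
    and late correlations of every window that is significant over the
    full period."""
    valid = results[results["valid"]]
    full = valid[valid["period"] == "full"]
    selected = full[full["p"] < alpha][["site_id", "variable", "window_months"]]
    key = ["site_id", "variable", "window_months"]
    early = valid[valid["period"] == "early"].set_index(key)
    late = valid[valid["period"] == "late"].set_index(key)
    rows = []
    for rec in selected.drop_duplicates().itertuples(index=False):
        idx = (rec.site_id, rec.variable, rec.window_months)
        if idx not in early.index or idx not in late.index:
            continue
        e = early.loc[idx]
        l8 = late.loc[idx]
        rows.append({
            "site_id": rec.site_id, "variable": rec.variable,
            "season": e["season"], "window": e["window"],
            "window_months": rec.window_months,
            "r_early": float(e["r"]), "r_late": float(l8["r"]),
            "delta": abs(float(l8["r"])) - abs(float(e["r"])),
        })
    return pd.DataFrame(rows, columns=["site_id", "variable", "season",
                                       "window", "window_months",
                                       "r_early", "r_late", "delta"])


def wilcoxon_delta_frame(
    deltas: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Frame-based :func:`wilcoxon_delta`."""
    objs = [DeltaR(r.site_id, r.variable, r.season, r.window,
                   r.r_early, r.r_late)
            for r in deltas.itertuples(index=False)]
    return wilcoxon_delta(objs, groups)


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test (asymptotic p); each sample
    needs at least 5 values."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs >= 5 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) with normal
    approximation and tie correction; all-tied samples give p = 1."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs >= 5 values")
    if np.all(np.r_[a, b] == np.r_[a, b][0]):
        import warnings
        warnings.warn("all values tied; rank-sum test degenerate", stacklevel=2)
        return float(a.size * b.size / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_delta(
    deltas: Iterable[DeltaR], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Pairwise rank-sum tests on delta-r between SDM groups, per climate
    variable (pooled over the selected windows); Holm adjustment applies
    when more than two groups are present."""
    df = pd.DataFrame([
        {"site_id": d.site_id, "variable": d.variable, "delta": d.delta}
        for d in deltas
    ])
    if df.empty:
        return pd.DataFrame(columns=["variable", "group_a", "group_b",
                                     "statistic", "p", "p_adjusted",
                                     "n_a", "n_b"])
    df["group"] = df["site_id"].map(groups)
    rows = []
    for variable, grp in df.groupby("variable"):
        names = sorted(grp["group"].unique())
        cell = []
        for ga, gb in combinations(names, 2):
            a = grp.loc[grp["group"] == ga, "delta"].to_numpy()
            b = grp.loc[grp["group"] == gb, "delta"].to_numpy()
            u, p = wilcoxon_rank_sum(a, b)
            cell.append({"variable": variable, "group_a": ga, "group_b": gb,
                         "statistic": u, "p": p, "n_a": len(a), "n_b": len(b)})
        # Holm step-down over the pairs of this variable
        ps = np.array([c["p"] for c in cell])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        for c, pa in zip(cell, adj):
            c["p_adjusted"] = float(pa)
        rows.extend(cell)
    return pd.DataFrame(rows, columns=["variable", "group_a", "group_b",
                                       "statistic", "p", "p_adjusted",
                                       "n_a", "n_b"])


def deltas_to_frame(deltas: Iterable[DeltaR],
                    groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for d in deltas:
        row = {"site_id": d.site_id, "variable": d.variable,
               "season": d.season, "window": d.window_label,
               "r_early": d.r_early, "r_late": d.r_late, "delta": d.delta}
        if groups is not None:
            row["group"] = groups[d.site_id]
        rows.append(row)
    return pd.DataFrame(rows)
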