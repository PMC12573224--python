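"""Synthetic multi-site tree-ring networks with known ground truth.

The generator emulates the statistical structure of a two-group oak
network (sites labelled by SDM projection: "contraction" vs
"persistence"): per-site daily climate, and per-tree ring widths driven by
standardized seasonal climate aggregates plus shared site- and
region-level year effects, tree-level noise, AR(1) growth persistence and
a negative-exponential age trend.  Growth is multiplicative (lognormal)
so widths stay positive, matching the ratio-detrending assumption.

Because climate forcing enters through standardized (z-score) seasonal
aggregates, the sensitivity coefficients ``beta`` are directly on the
correlation scale, which makes parameter recovery analytic: the expected
chronology-climate correlation is ``cov(z_v, signal) / sd(growth)`` and
the expected within-site rbar is

    (s2_climate + sigma2_site_year + sigma2_region_year)
    / (numerator + sigma2_tree).

Every random draw descends from a single seed through stable hashing of
site/tree identifiers, so output is reproducible and independent of
iteration order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from dendrosync import climate as clim
from dendrosync.ringio import Network, RingWidthSeries, SiteMeta

GROUPS = ("contraction", "persistence")

#: Forcing keys: "<variable>_<season>" with seasons current (Apr-Sep of the
#: ring year), previous (Jun-Oct of the prior year), dormancy (Nov-Mar).
_SEASON_ALIAS = {
    "current": "current_growing",
    "previous": "previous_growing",
    "dormancy": "dormancy",
}


def _default_beta() -> dict[str, dict[str, float]]:
    # Contraction sites are limited by current-season water balance;
    # persistence sites carry more previous-season (legacy) signal.
    # Coefficients are sized so site-chronology correlations land near
    # 0.5 (contraction CWB) and 0.25 (persistence CWB): the chronology
    # noise scale is sqrt(shared variance + sigma2_tree / n_trees).
    return {
        "contraction": {"cwb_current": 0.13, "tmean_current": -0.05},
        "persistence": {"cwb_current": 0.05, "cwb_previous": 0.065,
                        "tmean_previous": -0.04},
    }


@dataclass
class SimulationConfig:
    """Study conditions of a simulated network.

    Variances are on the log-growth scale; ``beta`` maps SDM group to
    ``{forcing_key: coefficient}`` on standardized seasonal climate.  If
    ``shift_year`` is set, ``beta_late`` replaces ``beta`` from that ring
    year on (a temporal shift in climate sensitivity).
    """

    n_sites_per_group: int = 6
    n_trees_min: int = 10
    n_trees_max: int = 75
    n_trees_mean: float = 22.0
    year_start: int = 1950
    year_end: int = 2023
    beta: dict[str, dict[str, float]] = field(default_factory=_default_beta)
    beta_late: dict[str, dict[str, float]] | None = None
    shift_year: int | None = None
    sigma2_site_year: dict[str, float] = field(
        default_factory=lambda: {"contraction": 0.022, "persistence": 0.026}
    )
    sigma2_region_year: dict[str, float] = field(
        default_factory=lambda: {"contraction": 0.014, "persistence": 0.005}
    )
    sigma2_tree: float = 0.05
    #: between-site spread of each sensitivity coefficient (spatial
    #: heterogeneity: some sites end up insignificant, as in real networks)
    beta_site_sd: float = 0.04
    phi: float = 0.25
    #: age trend (mm): width = a * exp(-b * age) + k
    trend_params: tuple[float, float, float] = (1.8, 0.03, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        a, _, k = self.trend_params
        if a <= 0 or k <= 0:
            raise ValueError("trend parameters a and k must be > 0")
        for m in (self.sigma2_site_year, self.sigma2_region_year):
            if any(v < 0 for v in m.values()):
                raise ValueError("variances must be >= 0")
        if self.sigma2_tree < 0:
            raise ValueError("variances must be >= 0")
        if not 2 <= self.n_trees_min <= self.n_trees_max:
            raise ValueError("need n_trees_min >= 2 (rbar undefined below)")


@dataclass
class TruthRecord:
    """Ground truth of one simulated network, for parameter-recovery tests."""

    beta: dict[str, dict[str, float]]
    beta_late: dict[str, dict[str, float]] | None
    shift_year: int | None
    #: per-site realized sensitivity coefficients (group mean + site jitter)
    site_beta: dict[str, dict[str, float]]
    site_beta_late: dict[str, dict[str, float]]
    sigma2_site_year: dict[str, float]
    sigma2_region_year: dict[str, float]
    sigma2_tree: float
    phi: float
    #: realized variance of the climate-driven signal per site
    s2_climate: dict[str, float]
    #: analytic expected within-site rbar per site
    target_rbar: dict[str, float]
    #: analytic expected regional synchrony per group
    target_a_hat: dict[str, float]
    #: analytic expected chronology-climate correlation per site and forcing
    target_r: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _stable_hash(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "little")


def _rng_for(seed: int, *names: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed] + [_stable_hash(n) for n in names])
    )


# ---------------------------------------------------------------------------
# Daily climate
# ---------------------------------------------------------------------------

def simulate_daily_climate(
    site: SiteMeta,
    years: tuple[int, int],
    seed: int,
    warming_trend: float = 0.02,
    weather_ar: float = 0.7,
    weather_sd: float = 2.2,
) -> pd.DataFrame:
    """Simulate daily climate for one site.

    Mean temperature = latitude-dependent level + seasonal sinusoid +
    linear warming trend (degC/year) + AR(1) weather noise; the diurnal
    range is drawn positive so tmin <= tmean <= tmax always holds.
    Precipitation is a Bernoulli wet-day process with gamma amounts;
    relative humidity has a seasonal cycle and decreases with warm
    anomalies (hot-dry coupling).
    """
    y0, y1 = years
    if y0 > y1 or y0 < 1800 or y1 > 2100:
        raise ValueError(f"year span {years} outside 1800-2100")
    rng = _rng_for(seed, "climate", site.site_id)
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    yearf = dates.year.to_numpy() + (doy - 1) / 365.25
    n = len(dates)

    base = 11.0 - 0.45 * (site.latitude - 45.0)
    amp = 9.0 + 0.15 * (site.latitude - 45.0)
    season = np.sin(2.0 * np.pi * (doy - 105.0) / 365.25)
    anom = np.empty(n)
    innov = rng.normal(0.0, weather_sd * np.sqrt(1 - weather_ar**2), size=n)
    anom[0] = rng.normal(0.0, weather_sd)
    for i in range(1, n):
        anom[i] = weather_ar * anom[i - 1] + innov[i]
    tmean = base + amp * season + warming_trend * (yearf - y0) + anom

    half_up = rng.gamma(4.0, (6.0 + 2.0 * season.clip(min=0)) / 8.0, size=n)
    half_dn = rng.gamma(4.0, (6.0 + 2.0 * season.clip(min=0)) / 8.0, size=n)
    tmax = tmean + half_up
    tmin = tmean - half_dn

    rh = 0.78 - 0.10 * season - 0.012 * anom + rng.normal(0.0, 0.06, size=n)
    rh = np.clip(rh, 0.25, 1.0)

    wet = rng.random(n) < 0.40
    amounts = rng.gamma(0.8, 5.5, size=n)
    prcp = np.where(wet, amounts, 0.0)

    return pd.DataFrame({
        "date": dates, "tmean": tmean, "tmin": tmin, "tmax": tmax,
        "prcp": prcp, "rh": rh,
    })


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _forcing_z(monthly: pd.DataFrame, key: str, ring_years: np.ndarray) -> np.ndarray:
    variable, season = key.rsplit("_", 1)
    ser = clim.seasonal_series(monthly, _SEASON_ALIAS[season], variable, ring_years)
    ser = ser.reindex(ring_years)
    x = ser.to_numpy(dtype=float)
    return (x - np.nanmean(x)) / np.nanstd(x)


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    """Variance-preserving AR(1) recursion applied along the year axis."""
    if phi == 0.0:
        return x
    out = np.empty_like(x)
    out[..., 0] = x[..., 0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, x.shape[-1]):
        out[..., t] = phi * out[..., t - 1] + c * x[..., t]
    return out


def simulate_network(
    cfg: SimulationConfig,
) -> tuple[Network, dict[str, pd.DataFrame], TruthRecord]:
    """Simulate a two-group network: metadata, daily climate per site and
    ring widths per tree, plus the analytic ground truth.

    Ring width of tree i in year t is ``trend(age) * exp(g_t)`` with
    ``g = AR1(climate signal + site year effect + region year effect +
    tree noise)``.  Trees share a site planting era with a +-10-year
    jitter so sample depth ramps up realistically.
    """
    y0, y1 = cfg.year_start, cfg.year_end
    ring_years = np.arange(y0, y1 + 1)
    n_years = ring_years.size

    sites: dict[str, SiteMeta] = {}
    series: list[RingWidthSeries] = []
    daily_by_site: dict[str, pd.DataFrame] = {}
    s2_climate: dict[str, float] = {}
    target_rbar: dict[str, float] = {}
    target_r: dict[str, dict[str, float]] = {}
    site_beta: dict[str, dict[str, float]] = {}
    site_beta_late: dict[str, dict[str, float]] = {}
    group_s2clim: dict[str, list[float]] = {g: [] for g in GROUPS}
    group_ntrees: dict[str, list[int]] = {g: [] for g in GROUPS}

    beta_late = cfg.beta_late if cfg.shift_year is not None else None

    # region-level year effects, one stream per group
    u_region: dict[str, np.ndarray] = {}
    for g in GROUPS:
        rng_g = _rng_for(cfg.seed, "region", g)
        u_region[g] = rng_g.normal(
            0.0, np.sqrt(cfg.sigma2_region_year[g]), size=n_years
        )

    a, b, k = cfg.trend_params
    for g in GROUPS:
        lat_lo, lat_hi = (41.0, 47.0) if g == "contraction" else (47.0, 55.0)
        for j in range(cfg.n_sites_per_group):
            site_id = f"{'C' if g == 'contraction' else 'P'}{j + 1:02d}"
            rng_s = _rng_for(cfg.seed, "site", site_id)
            meta_lat = float(rng_s.uniform(lat_lo, lat_hi))
            meta_lon = float(rng_s.uniform(-5.0, 30.0))
            n_trees = int(np.clip(
                cfg.n_trees_min + rng_s.poisson(cfg.n_trees_mean - cfg.n_trees_min),
                cfg.n_trees_min, cfg.n_trees_max,
            ))
            if n_trees < 2:
                raise ValueError(f"site {site_id}: n_trees < 2, rbar undefined")
            estab = int(rng_s.integers(1890, 1941))

            meta = SiteMeta(site_id, meta_lat, meta_lon, g,
                            stand_age=float(y1 - estab), n_trees=n_trees)
            daily = simulate_daily_climate(meta, (y0 - 1, y1), cfg.seed)
            daily_by_site[site_id] = daily
            monthly = clim.monthly_aggregate(daily, meta.latitude)

            keys = sorted(set(cfg.beta[g]) | set((beta_late or cfg.beta)[g]))
            z = {key: _forcing_z(monthly, key, ring_years) for key in keys}
            jitter = {key: float(rng_s.normal(0.0, cfg.beta_site_sd))
                      for key in keys}
            sb = {key: cfg.beta[g].get(key, 0.0) + jitter[key] for key in keys}
            sb_late = {key: (beta_late or cfg.beta)[g].get(key, 0.0) + jitter[key]
                       for key in keys}
            site_beta[site_id] = sb
            site_beta_late[site_id] = sb_late
            sig = np.zeros(n_years)
            for t_idx, t in enumerate(ring_years):
                period_beta = sb
                if beta_late is not None and t >= cfg.shift_year:
                    period_beta = sb_late
                sig[t_idx] = sum(period_beta[key] * z[key][t_idx]
                                 for key in keys)
            s2c = float(np.var(sig))
            shared = s2c + cfg.sigma2_site_year[g] + cfg.sigma2_region_year[g]
            sigma_g = np.sqrt(shared + cfg.sigma2_tree)
            s2_climate[site_id] = s2c
            total = shared + cfg.sigma2_tree
            target_rbar[site_id] = shared / total if total > 0 else 0.0
            target_r[site_id] = {
                key: float(np.cov(z[key], sig)[0, 1] / sigma_g)
                if sigma_g > 0 else 0.0
                for key in keys
            }
            group_s2clim[g].append(s2c)
            group_ntrees[g].append(n_trees)

            u_site = rng_s.normal(0.0, np.sqrt(cfg.sigma2_site_year[g]),
                                  size=n_years)
            shared_year = sig + u_site + u_region[g]
            # pre-climate years share a site-level signal of matched variance
            n_pre = y0 - (estab - 10)
            pre_shared = rng_s.normal(0.0, np.sqrt(shared), size=max(n_pre, 0))

            for i in range(n_trees):
                rng_t = _rng_for(cfg.seed, "tree", f"{site_id}/{i}")
                start = int(estab + rng_t.integers(-10, 11))
                tree_years = np.arange(start, y1 + 1)
                g_raw = np.empty(tree_years.size)
                for t_idx, t in enumerate(tree_years):
                    if t >= y0:
                        base = shared_year[t - y0]
                    else:
                        base = pre_shared[t - (estab - 10)]
                    g_raw[t_idx] = base
                g_raw = g_raw + rng_t.normal(0.0, np.sqrt(cfg.sigma2_tree),
                                             size=tree_years.size)
                g_t = _ar1_filter(g_raw, cfg.phi)
                age = tree_years - start + 1
                widths = (a * np.exp(-b * age) + k) * np.exp(g_t)
                series.append(RingWidthSeries(
                    tree_id=f"{site_id}T{i + 1:02d}"[:8],
                    site_id=site_id,
                    first_year=start,
                    widths=widths,
                ))
            sites[site_id] = meta

    a_hat: dict[str, float] = {}
    for g in GROUPS:
        mean_s2c = float(np.mean(group_s2clim[g]))
        nbar = float(np.mean(group_ntrees[g]))
        denom = (cfg.sigma2_region_year[g] + cfg.sigma2_site_year[g]
                 + mean_s2c + cfg.sigma2_tree / nbar)
        a_hat[g] = cfg.sigma2_region_year[g] / denom if denom > 0 else 0.0

    truth = TruthRecord(
        beta=cfg.beta,
        beta_late=beta_late,
        shift_year=cfg.shift_year,
        site_beta=site_beta,
        site_beta_late=site_beta_late,
        sigma2_site_year=cfg.sigma2_site_year,
        sigma2_region_year=cfg.sigma2_region_year,
        sigma2_tree=cfg.sigma2_tree,
        phi=cfg.phi,
        s2_climate=s2_climate,
        target_rbar=target_rbar,
        target_a_hat=a_hat,
        target_r=target_r,
    )
    return Network(series=series, sites=sites), daily_by_site, truth
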