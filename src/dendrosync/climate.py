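"""Derived climate variables for climate-growth analysis.

From daily station/grid climate (tmean, tmin, tmax, precipitation,
relative humidity) this module derives

* daily vapor pressure deficit (VPD, kPa) from the Tetens saturation
  vapor-pressure curve,
* monthly potential evapotranspiration (PET, mm) with the temperature-based
  Hargreaves-Samani method, using FAO-56 extraterrestrial radiation,
* the climatic water balance CWB = precipitation - PET (mm),
* seasonal aggregates on the tree-ring year axis, and
* bioclimatic normals (BIO9, BIO10, BIO11, BIO18) from a monthly
  climatology.

Daily and monthly climate are carried as pandas DataFrames.  Daily frames
need columns ``date, tmean, tmin, tmax, prcp, rh``; monthly frames carry
``year, month, tmean, tmin, tmax, vpd, prcp, ra, pet, cwb, n_days``.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820

DAILY_COLUMNS = ["date", "tmean", "tmin", "tmax", "prcp", "rh"]

#: Season definitions on the ring-year axis: (year offset, month) pairs.
#: The ring formed in year t integrates the previous growing season
#: (Jun-Oct of t-1), the dormancy season (Nov t-1 through Mar t) and the
#: current growing season (Apr-Sep of t).
SEASONS: dict[str, tuple[tuple[int, int], ...]] = {
    "previous_growing": tuple((-1, m) for m in range(6, 11)),
    "dormancy": ((-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3)),
    "current_growing": tuple((0, m) for m in range(4, 10)),
}

SEASON_NAMES = tuple(SEASONS)

#: Aggregation rule per variable: intensive variables average over months,
#: water fluxes sum.
_SEASONAL_AGG = {"tmean": "mean", "vpd": "mean", "cwb": "sum", "prcp": "sum",
                 "pet": "sum", "tmin": "mean", "tmax": "mean"}


@dataclass(frozen=True)
class BioclimSet:
    """Quarter-based bioclimatic normals (quarters = best of the 12
    circular 3-consecutive-month windows of a monthly climatology)."""

    bio9: float   # mean temperature of the driest quarter, degC
    bio10: float  # mean temperature of the warmest quarter, degC
    bio11: float  # mean temperature of the coldest quarter, degC
    bio18: float  # mean monthly precipitation of the warmest quarter, mm

    def __post_init__(self) -> None:
        if self.bio10 < self.bio11:
            raise ValueError("bio10 (warmest quarter) below bio11 (coldest)")


def _normalize_rh(rh):
    """Accept relative humidity as fraction or percent (auto-detected:
    values > 1.5 are treated as percent)."""
    rh = np.asarray(rh, dtype=float)
    scaled = np.where(rh > 1.5, rh / 100.0, rh)
    if np.any((scaled < 0) | (scaled > 1.0000001)):
        raise ValueError("relative humidity outside [0, 1] after unit detection")
    return np.clip(scaled, 0.0, 1.0)


def saturation_vapor_pressure(tmean) -> np.ndarray | float:
    """Tetens saturation vapor pressure (kPa) at air temperature (degC)."""
    t = np.asarray(tmean, dtype=float)
    if np.any(t <= -237.3):
        raise ValueError("temperature at or below -237.3 degC is outside the "
                         "Tetens domain")
    out = 0.6108 * np.exp(17.269 * t / (t + 237.3))
    return float(out) if np.isscalar(tmean) else out


def daily_vpd(tmean, rh) -> np.ndarray | float:
    """Daily vapor pressure deficit (kPa).

    VPD = e_sat(tmean) * (1 - rh), with e_sat from the Tetens curve.
    ``rh`` may be a fraction in [0, 1] or percent (auto-detected).
    """
    scalar = np.isscalar(tmean) and np.isscalar(rh)
    out = saturation_vapor_pressure(tmean) * (1.0 - _normalize_rh(rh))
    return float(np.asarray(out)) if scalar else np.asarray(out)


def extraterrestrial_radiation(latitude, day_of_year) -> np.ndarray | float:
    """Daily extraterrestrial radiation RA (MJ m-2 day-1), FAO-56 eq. 21.

    The sunset-hour-angle argument is clamped so polar night yields 0 and
    polar day the full-rotation value.
    """
    scalar = np.isscalar(latitude) and np.isscalar(day_of_year)
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
        raise ValueError("latitude outside [-90, 90] degrees")
    doy = np.asarray(day_of_year, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    cos_ws = -np.tan(lat) * np.tan(decl)
    ws = np.arccos(np.clip(cos_ws, -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if scalar else ra


def _mid_month_doy(year: int, month: int) -> int:
    first = pd.Timestamp(year=year, month=month, day=1).dayofyear
    return first + calendar.monthrange(year, month)[1] // 2


def pet_hargreaves(
    year: int,
    month: int,
    tmean: float,
    tmin: float,
    tmax: float,
    ra: float | None = None,
    latitude: float | None = None,
    literal_form: bool = False,
) -> float:
    """Monthly potential evapotranspiration (mm) by Hargreaves-Samani.

    PET_day = 0.0023 * (0.408 * RA) * (tmean + 17.8) * sqrt(tmax - tmin),
    clamped at zero, times the days in the month.  RA is the mean daily
    extraterrestrial radiation (MJ m-2 day-1), evaluated at mid-month if a
    latitude is given instead; 0.408 converts MJ m-2 day-1 to mm day-1 of
    evaporation equivalent.

    ``literal_form=True`` switches to the reduced variant
    PET_day = 0.0023 * RA * tmean * (tmax - tmin), which omits the
    temperature offset, the square root and the radiation conversion.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    if ra is None:
        if latitude is None:
            raise ValueError("provide either ra or latitude")
        ra = extraterrestrial_radiation(latitude, _mid_month_doy(year, month))
    if literal_form:
        pet_day = 0.0023 * ra * tmean * (tmax - tmin)
    else:
        pet_day = 0.0023 * (0.408 * ra) * (tmean + 17.8) * np.sqrt(tmax - tmin)
    pet_day = max(pet_day, 0.0)
    return pet_day * calendar.monthrange(year, month)[1]


def check_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily climate frame and normalise dtypes in a copy."""
    missing = [c for c in DAILY_COLUMNS if c not in daily.columns]
    if missing:
        raise ValueError(f"daily climate missing columns {missing}")
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    bad = (df["tmin"] > df["tmean"] + 1e-9) | (df["tmean"] > df["tmax"] + 1e-9)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} days violate tmin <= tmean <= tmax")
    if (df["prcp"] < 0).any():
        raise ValueError("negative precipitation")
    df["rh"] = _normalize_rh(df["rh"].to_numpy())
    return df


def monthly_aggregate(
    daily: pd.DataFrame,
    latitude: float,
    max_missing_frac: float = 0.10,
    literal_pet: bool = False,
) -> pd.DataFrame:
    """Aggregate daily climate to monthly and attach VPD, RA, PET, CWB.

    Temperature and VPD are averaged; precipitation is summed.  PET is
    Hargreaves-Samani on the monthly values with mid-month RA; CWB is
    precipitation minus PET.  Months missing more than ``max_missing_frac``
    of their days are flagged ``incomplete`` (and should be excluded
    downstream).
    """
    df = check_daily(daily)
    df["vpd"] = daily_vpd(df["tmean"].to_numpy(), df["rh"].to_numpy())
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    grouped = df.groupby(["year", "month"], sort=True)
    agg = grouped.agg(
        tmean=("tmean", "mean"),
        tmin=("tmin", "mean"),
        tmax=("tmax", "mean"),
        vpd=("vpd", "mean"),
        prcp=("prcp", "sum"),
        n_days=("date", "size"),
    ).reset_index()
    rows = []
    for row in agg.itertuples(index=False):
        y, m = int(row.year), int(row.month)
        ra = extraterrestrial_radiation(latitude, _mid_month_doy(y, m))
        pet = pet_hargreaves(y, m, row.tmean, row.tmin, row.tmax, ra=ra,
                             literal_form=literal_pet)
        ndays_month = calendar.monthrange(y, m)[1]
        rows.append({
            "year": y, "month": m,
            "tmean": row.tmean, "tmin": row.tmin, "tmax": row.tmax,
            "vpd": row.vpd, "prcp": row.prcp, "ra": ra, "pet": pet,
            "cwb": row.prcp - pet, "n_days": int(row.n_days),
            "incomplete": row.n_days < (1.0 - max_missing_frac) * ndays_month,
        })
    return pd.DataFrame(rows)


def window_series(
    monthly: pd.DataFrame,
    months: Sequence[tuple[int, int]],
    variable: str,
    ring_years: Iterable[int],
) -> pd.Series:
    """Aggregate a monthly variable over an arbitrary (year-offset, month)
    window for each ring year.

    Intensive variables (``tmean``, ``vpd``) average over the window's
    months; water fluxes (``prcp``, ``pet``, ``cwb``) sum.  Ring years for
    which any window month is absent or flagged incomplete are dropped.
    """
    if variable not in _SEASONAL_AGG:
        raise ValueError(f"unknown variable {variable!r}")
    how = _SEASONAL_AGG[variable]
    if "incomplete" in monthly.columns:
        usable = monthly[~monthly["incomplete"].astype(bool)]
    else:
        usable = monthly
    lookup = {(int(r.year), int(r.month)): getattr(r, variable)
              for r in usable.itertuples(index=False)}
    idx, values = [], []
    for t in ring_years:
        vals = [lookup.get((t + off, m)) for off, m in months]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        idx.append(int(t))
        values.append(arr.mean() if how == "mean" else arr.sum())
    return pd.Series(values, index=pd.Index(idx, name="year"), name=variable)


def seasonal_series(
    monthly: pd.DataFrame,
    season: str,
    variable: str,
    ring_years: Iterable[int],
) -> pd.Series:
    """Seasonal aggregate of a monthly variable on the ring-year axis."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASON_NAMES}")
    return window_series(monthly, SEASONS[season], variable, ring_years)


def bioclim(monthly: pd.DataFrame, period: tuple[int, int] = (1981, 2010)) -> BioclimSet:
    """Quarter-based bioclimatic normals from a monthly climatology.

    A climatology of mean temperature and precipitation is built over
    ``period`` (inclusive years); quarters are the 12 circular windows of
    three consecutive months.  BIO10/BIO11 are the mean temperatures of the
    warmest/coldest quarter, BIO9 the mean temperature of the driest
    quarter (least total precipitation) and BIO18 the mean monthly
    precipitation of the warmest quarter.
    """
    y0, y1 = period
    sel = monthly[(monthly["year"] >= y0) & (monthly["year"] <= y1)]
    clim = sel.groupby("month")[["tmean", "prcp"]].mean()
    if len(clim) != 12:
        raise ValueError(
            f"climatology for {y0}-{y1} covers {len(clim)} months, need 12"
        )
    t = clim["tmean"].to_numpy()
    p = clim["prcp"].to_numpy()
    qt = np.array([t[[i, (i + 1) % 12, (i + 2) % 12]].mean() for i in range(12)])
    qp = np.array([p[[i, (i + 1) % 12, (i + 2) % 12]].sum() for i in range(12)])
    warmest = int(np.argmax(qt))
    coldest = int(np.argmin(qt))
    driest = int(np.argmin(qp))
    return BioclimSet(
        bio9=float(qt[driest]),
        bio10=float(qt[warmest]),
        bio11=float(qt[coldest]),
        bio18=float(qp[warmest] / 3.0),
    )


def read_daily_csv(path) -> pd.DataFrame:
    return check_daily(pd.read_csv(path))


def write_monthly_csv(monthly: pd.DataFrame, path) -> None:
    monthly.to_csv(path, index=False)
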