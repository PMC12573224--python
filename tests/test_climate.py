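"""Derived climate variables against independent formula evaluations."""

import calendar
import math

import numpy as np
import pandas as pd
import pytest

from dendrosync import climate as clim


def _tetens_reference(t):
    # independent evaluation of the Tetens curve, coded separately
    return 0.6108 * math.exp((17.269 * t) / (t + 237.3))


class TestVpd:
    def test_saturated_air_gives_zero(self):
        for t in (-10.0, 0.0, 15.0, 30.0):
            assert clim.daily_vpd(t, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_celsius_dry_air(self):
        assert clim.daily_vpd(0.0, 0.0) == pytest.approx(0.6108, abs=1e-12)

    @pytest.mark.parametrize("t,rh", [(20.0, 0.5), (5.0, 0.8), (32.0, 0.3)])
    def test_matches_independent_tetens_table(self, t, rh):
        expected = _tetens_reference(t) * (1 - rh)
        assert clim.daily_vpd(t, rh) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_rh_and_temperature(self):
        rh = np.linspace(0, 1, 11)
        v = clim.daily_vpd(np.full(11, 20.0), rh)
        assert np.all(np.diff(v) < 0)
        t = np.linspace(-5, 35, 20)
        v = clim.daily_vpd(t, np.full(20, 0.6))
        assert np.all(np.diff(v) > 0)

    def test_percent_humidity_autodetected(self):
        assert clim.daily_vpd(20.0, 50.0) == pytest.approx(
            clim.daily_vpd(20.0, 0.5), rel=1e-12)

    def test_domain_error_below_tetens_pole(self):
        with pytest.raises(ValueError):
            clim.daily_vpd(-240.0, 0.5)


def _fao56_ra_reference(lat_deg, doy):
    # brute-force FAO-56 eq. 21-25, written independently
    phi = math.radians(lat_deg)
    dr = 1 + 0.033 * math.cos(2 * math.pi * doy / 365)
    delta = 0.409 * math.sin(2 * math.pi * doy / 365 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (24 * 60 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))


class TestExtraterrestrialRadiation:
    def test_polar_night_is_zero(self):
        assert clim.extraterrestrial_radiation(80.0, 355) == 0.0

    def test_equinox_symmetry_across_hemispheres(self):
        # solar declination crosses zero at doy = 1.39 * 365 / (2 pi)
        equinox = 1.39 * 365.0 / (2.0 * math.pi)
        for lat in (10.0, 35.0, 60.0):
            a = clim.extraterrestrial_radiation(lat, equinox)
            b = clim.extraterrestrial_radiation(-lat, equinox)
            assert a == pytest.approx(b, abs=1e-9)

    def test_fao56_worked_example_20S_early_september(self):
        # 3 September is day 246; the handbook reports 32.2 MJ m-2 day-1
        doy = 246
        got = clim.extraterrestrial_radiation(-20.0, doy)
        assert got == pytest.approx(_fao56_ra_reference(-20.0, doy), rel=1e-9)
        assert got == pytest.approx(32.2, abs=0.1)

    def test_annual_amplitude_grows_with_latitude(self):
        doys = np.arange(1, 366)
        amps = []
        for lat in (0.0, 25.0, 50.0, 65.0):
            ra = clim.extraterrestrial_radiation(lat, doys)
            amps.append(ra.max() - ra.min())
        assert np.all(np.diff(amps) > 0)

    def test_latitude_out_of_range(self):
        with pytest.raises(ValueError):
            clim.extraterrestrial_radiation(91.0, 100)


def _hargreaves_monthly_reference(year, month, tmean, tmin, tmax, lat):
    # independent monthly Hargreaves-Samani: mid-month RA, 0.408 MJ->mm
    first = pd.Timestamp(year=year, month=month, day=1).dayofyear
    ndays = calendar.monthrange(year, month)[1]
    doy = first + ndays // 2
    ra = _fao56_ra_reference(lat, doy)
    per_day = 0.0023 * 0.408 * ra * (tmean + 17.8) * math.sqrt(tmax - tmin)
    return max(per_day, 0.0) * ndays


class TestPetHargreaves:
    def test_zero_diurnal_range_gives_zero(self):
        assert clim.pet_hargreaves(2000, 7, 20, 15, 15, ra=40.0) == 0.0

    def test_very_cold_month_clamped_to_zero(self):
        assert clim.pet_hargreaves(2000, 1, -30, -40, -20, ra=10.0) == 0.0

    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(ValueError):
            clim.pet_hargreaves(2000, 7, 20, 25, 15, ra=40.0)

    def test_matches_independent_monthly_implementation(self):
        got = clim.pet_hargreaves(2000, 7, 20.0, 12.0, 28.0, latitude=45.0)
        want = _hargreaves_monthly_reference(2000, 7, 20.0, 12.0, 28.0, 45.0)
        assert got == pytest.approx(want, abs=0.5)

    def test_literal_printed_variant_differs(self):
        std = clim.pet_hargreaves(2000, 7, 20, 12, 28, ra=40.0)
        lit = clim.pet_hargreaves(2000, 7, 20, 12, 28, ra=40.0,
                                  literal_form=True)
        assert std != pytest.approx(lit)


def _constant_daily(year=2000, months=(1, 13), tmean=10.0, spread=5.0,
                    prcp=2.0, rh=0.7):
    dates = pd.date_range(f"{year}-{months[0]:02d}-01",
                          f"{year}-{min(months[1], 12):02d}-28" if months[1] <= 12
                          else f"{year}-12-31", freq="D")
    return pd.DataFrame({
        "date": dates,
        "tmean": tmean, "tmin": tmean - spread, "tmax": tmean + spread,
        "prcp": prcp, "rh": rh,
    })


class TestMonthlyAggregate:
    def test_constant_climate_means_and_sums(self):
        daily = _constant_daily()
        monthly = clim.monthly_aggregate(daily, latitude=45.0)
        jan = monthly[(monthly.month == 1)].iloc[0]
        assert jan.tmean == pytest.approx(10.0)
        assert jan.prcp == pytest.approx(2.0 * 31)

    def test_cwb_identity_exact(self):
        daily = _constant_daily(tmean=15.0, prcp=1.5)
        monthly = clim.monthly_aggregate(daily, latitude=50.0)
        np.testing.assert_allclose(monthly.cwb + monthly.pet, monthly.prcp,
                                   rtol=0, atol=1e-12)

    def test_saturated_month_has_zero_vpd(self):
        daily = _constant_daily(rh=1.0)
        monthly = clim.monthly_aggregate(daily, latitude=45.0)
        assert np.allclose(monthly.vpd, 0.0)

    def test_incomplete_month_flagged(self):
        daily = _constant_daily()
        daily = daily[~((daily.date.dt.month == 3) & (daily.date.dt.day > 5))]
        monthly = clim.monthly_aggregate(daily, latitude=45.0)
        assert bool(monthly.loc[monthly.month == 3, "incomplete"].iloc[0])

    def test_inconsistent_temperature_order_rejected(self):
        daily = _constant_daily()
        daily.loc[3, "tmin"] = 50.0
        with pytest.raises(ValueError, match="tmin"):
            clim.monthly_aggregate(daily, latitude=45.0)


def _two_year_monthly():
    rows = []
    for year in (1989, 1990, 1991):
        for month in range(1, 13):
            rows.append({
                "year": year, "month": month,
                "tmean": float(10 * year + month),  # unique per (y, m)
                "vpd": 0.5, "prcp": float(month),
                "pet": 10.0, "cwb": float(month) - 10.0,
                "incomplete": False,
            })
    return pd.DataFrame(rows)


class TestSeasonalSeries:
    def test_dormancy_1990_uses_nov_dec_1989_and_jan_mar_1990(self):
        monthly = _two_year_monthly()
        got = clim.seasonal_series(monthly, "dormancy", "tmean", [1990])
        want = np.mean([19890 + 11, 19890 + 12, 19900 + 1, 19900 + 2,
                        19900 + 3])
        assert got.loc[1990] == pytest.approx(want)

    def test_single_month_window_is_that_month(self):
        monthly = _two_year_monthly()
        got = clim.window_series(monthly, [(0, 7)], "tmean", [1990])
        assert got.loc[1990] == pytest.approx(19900 + 7)

    def test_current_growing_cwb_equals_enumerated_sum(self):
        monthly = _two_year_monthly()
        got = clim.seasonal_series(monthly, "current_growing", "cwb", [1990])
        want = sum(m - 10.0 for m in range(4, 10))
        assert got.loc[1990] == pytest.approx(want)

    def test_ring_year_without_previous_months_dropped(self):
        monthly = _two_year_monthly()
        got = clim.seasonal_series(monthly, "previous_growing", "tmean",
                                   [1989, 1990])
        assert 1989 not in got.index and 1990 in got.index


class TestBioclim:
    def test_constant_climate_collapses_quarters(self):
        monthly = _two_year_monthly().assign(tmean=7.5)
        bio = clim.bioclim(monthly, period=(1989, 1991))
        assert bio.bio10 == pytest.approx(7.5)
        assert bio.bio11 == pytest.approx(7.5)

    def test_sinusoid_peaking_july_gives_jun_aug_warmest(self):
        monthly = _two_year_monthly()
        monthly["tmean"] = 10 - 10 * np.cos(2 * np.pi * (monthly.month - 1) / 12)
        monthly["prcp"] = 50.0
        bio = clim.bioclim(monthly, period=(1989, 1991))
        months = np.arange(1, 13)
        t = 10 - 10 * np.cos(2 * np.pi * (months - 1) / 12)
        # brute force over all 12 circular quarters
        best = max(range(12),
                   key=lambda i: t[[i, (i + 1) % 12, (i + 2) % 12]].mean())
        want = t[[best, (best + 1) % 12, (best + 2) % 12]].mean()
        assert bio.bio10 == pytest.approx(want)
        assert best == 5  # Jun-Jul-Aug

    def test_bio18_is_mean_monthly_precip_of_warmest_quarter(self):
        monthly = _two_year_monthly()
        monthly["tmean"] = 10 - 10 * np.cos(2 * np.pi * (monthly.month - 1) / 12)
        bio = clim.bioclim(monthly, period=(1989, 1991))
        assert bio.bio18 == pytest.approx(np.mean([6.0, 7.0, 8.0]))

    def test_incomplete_climatology_rejected(self):
        monthly = _two_year_monthly()
        monthly = monthly[monthly.month != 5]
        with pytest.raises(ValueError, match="12"):
            clim.bioclim(monthly, period=(1989, 1991))
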