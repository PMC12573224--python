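"""Window enumeration, bootstrap correlations and network summaries."""

import numpy as np
import pandas as pd
import pytest

from dendrosync import climate as clim
from dendrosync import correlations as corr
from dendrosync.chronology import SiteChronology
from dendrosync.correlations import (
    CorrelationResult,
    PeriodSplit,
    Window,
    best_seasonal,
    classify_sites,
    correlate,
    enumerate_windows,
    median_correlations,
)


class TestEnumerateWindows:
    def test_counts_per_season(self):
        # brute-force expectation: sum over lengths of (n - L + 1)
        for season, n_months, want in (("current_growing", 6, 20),
                                       ("previous_growing", 5, 15),
                                       ("dormancy", 5, 15)):
            expect = sum(n_months - L + 1 for L in range(1, min(5, n_months) + 1))
            assert expect == want
            assert len(enumerate_windows(season)) == want

    def test_windows_are_contiguous_subsets_of_season(self):
        months = clim.SEASONS["dormancy"]
        for w in enumerate_windows("dormancy"):
            i = months.index(w.months[0])
            assert w.months == months[i : i + w.length]

    def test_dormancy_offsets_straddle_the_year_boundary(self):
        full = [w for w in enumerate_windows("dormancy") if w.length == 5][0]
        assert full.months[0] == (-1, 11) and full.months[-1] == (0, 3)

    def test_labels_mark_previous_year(self):
        full = [w for w in enumerate_windows("dormancy") if w.length == 5][0]
        assert full.label == "Nov*-Mar"


def _monthly_from_values(values_by_year, variable="cwb"):
    """Monthly frame where the July value of `variable` is per-year data."""
    rows = []
    years = sorted(values_by_year)
    for y in years:
        for m in range(1, 13):
            rows.append({
                "year": y, "month": m, "tmean": 10.0, "vpd": 0.5,
                "prcp": 50.0, "pet": 40.0,
                "cwb": values_by_year[y] if m == 7 else 0.0,
                "incomplete": False,
            })
    return pd.DataFrame(rows)


def _july_window():
    return Window("current_growing", ((0, 7),))


def _chron(years, values):
    years = np.asarray(years)
    return SiteChronology("S1", years, np.asarray(values, float),
                          np.full(years.size, 10))


class TestCorrelate:
    def test_perfect_correlation(self, rng):
        years = np.arange(1950, 2024)
        x = rng.normal(0, 1, years.size)
        monthly = _monthly_from_values(dict(zip(years, x)))
        chron = _chron(years, 1 + 0.1 * x)
        res = correlate(chron, monthly, "cwb", _july_window(),
                        rng=np.random.default_rng(0))
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(0.0, abs=1e-6)
        assert res.ci_low <= res.r <= res.ci_high

    def test_r_matches_closed_form_pearson(self, rng):
        years = np.arange(1950, 2024)
        x = rng.normal(0, 1, years.size)
        y = 1 + rng.normal(0, 0.2, years.size)
        monthly = _monthly_from_values(dict(zip(years, x)))
        res = correlate(_chron(years, y), monthly, "cwb", _july_window(),
                        rng=np.random.default_rng(0))
        xc, yc = x - x.mean(), y - y.mean()
        want = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert res.r == pytest.approx(want, abs=1e-12)

    def test_bootstrap_reproducible_under_seed(self, rng):
        years = np.arange(1950, 2024)
        x = rng.normal(0, 1, years.size)
        y = 1 + 0.05 * x + rng.normal(0, 0.2, years.size)
        monthly = _monthly_from_values(dict(zip(years, x)))
        a = correlate(_chron(years, y), monthly, "cwb", _july_window(),
                      rng=np.random.default_rng(7))
        b = correlate(_chron(years, y), monthly, "cwb", _july_window(),
                      rng=np.random.default_rng(7))
        assert (a.p, a.ci_low, a.ci_high) == (b.p, b.ci_low, b.ci_high)

    def test_period_restriction_uses_only_those_years(self, rng):
        years = np.arange(1950, 2024)
        x = rng.normal(0, 1, years.size)
        # early years perfectly correlated, late years pure noise
        y = np.where(years <= 1985, 1 + 0.1 * x, 1 + rng.normal(0, 0.2, years.size))
        monthly = _monthly_from_values(dict(zip(years, x)))
        res = correlate(_chron(years, y), monthly, "cwb", _july_window(),
                        period="early", rng=np.random.default_rng(0))
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.n_years == 36

    def test_short_overlap_flagged_invalid(self, rng):
        years = np.arange(2010, 2024)
        x = rng.normal(0, 1, years.size)
        monthly = _monthly_from_values(dict(zip(years, x)))
        res = correlate(_chron(years, 1 + 0.1 * x), monthly, "cwb",
                        _july_window(), rng=np.random.default_rng(0))
        assert not res.valid and np.isnan(res.r)


def _result(r, p=0.01, length=1, start=(0, 4), site="S1", variable="cwb",
            season="current_growing", period="full", valid=True):
    months = tuple((start[0], start[1] + i) for i in range(length))
    return CorrelationResult(site, variable, season,
                             Window(season, months), period, r,
                             r - 0.1, r + 0.1, p, 50, valid)


class TestBestSeasonal:
    def test_single_result_is_best(self):
        r = _result(0.4)
        assert best_seasonal([r]) is r

    def test_largest_magnitude_wins_sign_retained(self):
        rs = [_result(0.3), _result(-0.5), _result(0.2)]
        assert best_seasonal(rs).r == -0.5

    def test_tie_goes_to_longer_window_then_earlier_start(self):
        short = _result(0.5, length=1, start=(0, 5))
        longer = _result(0.5, length=3, start=(0, 6))
        assert best_seasonal([short, longer]) is longer
        late = _result(-0.5, length=2, start=(0, 7))
        early = _result(0.5, length=2, start=(0, 5))
        assert best_seasonal([late, early]) is early

    def test_invalid_results_skipped(self):
        assert best_seasonal([_result(0.9, valid=False)]) is None

    def test_frame_selection_matches_object_selection(self, rng):
        results = []
        for site in ("A", "B"):
            for w in enumerate_windows("dormancy"):
                results.append(CorrelationResult(
                    site, "cwb", "dormancy", w, "full",
                    float(rng.uniform(-1, 1)), -1, 1,
                    float(rng.uniform(0, 1)), 50))
        by_obj = corr.best_by_cell(results)
        frame = corr.best_by_cell_frame(corr.results_to_frame(results))
        for (site, variable, season, period), res in by_obj.items():
            row = frame[(frame.site_id == site) & (frame.period == period)]
            assert row.iloc[0]["r"] == pytest.approx(res.r)
            assert row.iloc[0]["window_months"] == res.window.key


class TestSummaries:
    def test_no_significant_sites(self):
        best = [_result(0.4, p=0.5, site=f"S{i}") for i in range(4)]
        _, summary = classify_sites(best)
        assert summary.iloc[0]["pct_significant"] == 0.0

    def test_counting_shares(self):
        best = [_result(0.5, p=0.01, site="A"), _result(0.4, p=0.01, site="B"),
                _result(-0.6, p=0.01, site="C"), _result(0.1, p=0.8, site="D")]
        classes, summary = classify_sites(best)
        row = summary.iloc[0]
        assert row["pct_positive"] == 50.0
        assert row["pct_negative"] == 25.0
        assert [c.klass for c in classes] == ["positive", "positive",
                                              "negative", "insignificant"]

    def test_median_matches_sort_oracle(self, rng):
        rs = [_result(float(r), site=f"S{i}")
              for i, r in enumerate(rng.uniform(-1, 1, 15))]
        table = median_correlations(rs)
        pos = sorted(r.r for r in rs if r.r > 0)
        want = pos[len(pos) // 2] if len(pos) % 2 else (
            0.5 * (pos[len(pos) // 2 - 1] + pos[len(pos) // 2]))
        got = table[(table.sign == "positive")].iloc[0]["median_r"]
        assert got == pytest.approx(want)

    def test_simple_median(self):
        rs = [_result(0.2, site="A"), _result(0.4, site="B"),
              _result(0.6, site="C")]
        got = median_correlations(rs)
        assert got[got.sign == "positive"].iloc[0]["median_r"] == 0.4


def test_period_split_validation():
    with pytest.raises(ValueError):
        PeriodSplit(early=(1950, 1990), late=(1986, 2023))
    with pytest.raises(ValueError):
        PeriodSplit(early=(1950, 1960), late=(1970, 2023))
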