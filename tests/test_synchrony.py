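"""Running rbar and REML variance-components synchrony."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from dendrosync.chronology import DetrendedSeries, SiteChronology
from dendrosync.synchrony import (
    fit_synchrony,
    group_rbar_curve,
    mean_pairwise_correlation,
    moving_rbar,
    rwi_matrix,
)


def _matrix(values, first_year=1950):
    values = np.asarray(values, float)
    return pd.DataFrame(values,
                        index=[f"t{i}" for i in range(values.shape[0])],
                        columns=np.arange(first_year,
                                          first_year + values.shape[1]))


def _brute_force_rbar(block):
    # oracle: explicit double loop over pairs with textbook Pearson
    vals = []
    for i, j in combinations(range(block.shape[0]), 2):
        x, y = block[i], block[j]
        xc, yc = x - x.mean(), y - y.mean()
        vals.append((xc * yc).sum()
                    / np.sqrt((xc * xc).sum() * (yc * yc).sum()))
    return float(np.mean(vals))


class TestMovingRbar:
    def test_identical_trees_have_unit_rbar(self, rng):
        row = rng.normal(1, 0.1, 40)
        out = moving_rbar(_matrix(np.tile(row, (7, 1))), window=20)
        assert np.allclose(out.rbar, 1.0)
        assert (out.n_pairs == 21).all()

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            m = rng.normal(1, 0.2, size=(10, 40))
            out = moving_rbar(_matrix(m), window=40, min_trees=6)
            assert len(out) == 1
            assert out.iloc[0]["rbar"] == pytest.approx(
                _brute_force_rbar(m), abs=1e-12)

    def test_white_noise_rbar_near_zero(self, rng):
        means = []
        for _ in range(100):
            m = rng.normal(1, 0.2, size=(8, 25))
            out = moving_rbar(_matrix(m), window=25, min_trees=6)
            means.append(out.iloc[0]["rbar"])
        assert abs(np.mean(means)) < 0.05

    def test_linear_rescaling_invariance(self, rng):
        m = rng.normal(1, 0.2, size=(8, 30))
        scaled = m * np.linspace(2, 9, 8)[:, None] + np.arange(8)[:, None]
        a = moving_rbar(_matrix(m), window=20)
        b = moving_rbar(_matrix(scaled), window=20)
        np.testing.assert_allclose(a.rbar, b.rbar, atol=1e-12)

    def test_incomplete_trees_dropped_per_window(self, rng):
        m = rng.normal(1, 0.2, size=(8, 40))
        m[0, :15] = np.nan  # tree 0 only complete in late windows
        out = moving_rbar(_matrix(m), window=20, min_trees=6)
        assert out.iloc[0]["n_trees"] == 7
        assert out.iloc[-1]["n_trees"] == 8

    def test_no_usable_window_warns_and_returns_empty(self, rng):
        m = rng.normal(1, 0.2, size=(3, 30))
        with pytest.warns(UserWarning, match="minimum tree count"):
            out = moving_rbar(_matrix(m), window=20, min_trees=6)
        assert out.empty


class TestGroupCurve:
    def test_single_site_group_has_no_se(self):
        rbars = {"A": pd.DataFrame({"window_end_year": [1990], "rbar": [0.5],
                                    "n_trees": [8], "n_pairs": [28]})}
        out = group_rbar_curve(rbars, {"A": "contraction"})
        assert np.isnan(out.iloc[0]["se"])

    def test_two_equal_values_have_zero_se(self):
        df = pd.DataFrame({"window_end_year": [1990], "rbar": [0.5],
                           "n_trees": [8], "n_pairs": [28]})
        out = group_rbar_curve({"A": df, "B": df.copy()},
                               {"A": "g", "B": "g"})
        assert out.iloc[0]["se"] == 0.0
        assert out.iloc[0]["mean_rbar"] == 0.5

    def test_matches_textbook_mean_and_se(self, rng):
        vals = rng.uniform(0.2, 0.8, 6)
        rbars = {f"S{i}": pd.DataFrame({"window_end_year": [2000],
                                        "rbar": [v], "n_trees": [8],
                                        "n_pairs": [28]})
                 for i, v in enumerate(vals)}
        out = group_rbar_curve(rbars, {f"S{i}": "g" for i in range(6)})
        assert out.iloc[0]["mean_rbar"] == pytest.approx(vals.mean())
        assert out.iloc[0]["se"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(6))


def _chronset(rng, n_sites, n_years, sigma2_year, sigma2_resid, group="g",
              first_year=1900, mean=1.0):
    Y = rng.normal(0, np.sqrt(sigma2_year), n_years)
    chrons, groups = [], {}
    for s in range(n_sites):
        sid = f"{group}{s:02d}"
        y = mean + Y + rng.normal(0, np.sqrt(sigma2_resid), n_years)
        chrons.append(SiteChronology(sid, np.arange(first_year,
                                                    first_year + n_years),
                                     y, np.full(n_years, 10)))
        groups[sid] = group
    return chrons, groups


def _reml_grid_oracle(chrons, n_grid=60):
    """Profile the REML criterion on a dense variance grid (independent of
    the package optimizer)."""
    years = chrons[0].years
    Y = np.array([c.rwi for c in chrons])  # sites x years
    n, T = Y.shape

    def neg2reml(s_yr, s_e):
        logdet, xtvx, xtvy = 0.0, 0.0, 0.0
        for t in range(T):
            y = Y[:, t]
            d = s_e + n * s_yr
            logdet += (n - 1) * np.log(s_e) + np.log(d)
            xtvx += n / d
            xtvy += y.sum() / d
        mu = xtvy / xtvx
        quad = 0.0
        for t in range(T):
            r = Y[:, t] - mu
            d = s_e + n * s_yr
            quad += (np.sum(r * r) - (s_yr / d) * np.sum(r) ** 2) / s_e
        return logdet + np.log(xtvx) + quad

    grid_yr = np.linspace(1e-4, 0.8, n_grid)
    grid_e = np.linspace(1e-4, 1.2, n_grid)
    best = None
    for s_yr in grid_yr:
        for s_e in grid_e:
            v = neg2reml(s_yr, s_e)
            if best is None or v < best[0]:
                best = (v, s_yr, s_e)
    return best[1] / (best[1] + best[2])


class TestFitSynchrony:
    def test_pure_shared_signal_gives_full_synchrony(self, rng):
        chrons, groups = _chronset(rng, 8, 60, sigma2_year=0.3,
                                   sigma2_resid=1e-8)
        fit = fit_synchrony(chrons, groups)["g"]
        assert fit.a_hat >= 0.99

    def test_independent_chronologies_give_no_synchrony(self, rng):
        chrons, groups = _chronset(rng, 10, 200, sigma2_year=0.0,
                                   sigma2_resid=0.3)
        fit = fit_synchrony(chrons, groups)["g"]
        assert fit.a_hat < 0.05

    def test_recovery_and_grid_search_oracle(self, rng):
        chrons, groups = _chronset(rng, 5, 30, sigma2_year=0.25,
                                   sigma2_resid=0.75)
        fit = fit_synchrony(chrons, groups)["g"]
        oracle = _reml_grid_oracle(chrons)
        # grid resolution limits the oracle to ~1e-2 in a_hat
        assert fit.a_hat == pytest.approx(oracle, abs=0.02)

    def test_a_hat_monotone_in_shared_variance(self, rng):
        a_hats = []
        for s2 in (0.05, 0.15, 0.3, 0.6):
            chrons, groups = _chronset(
                np.random.default_rng(99), 15, 120, sigma2_year=s2,
                sigma2_resid=0.5)
            a_hats.append(fit_synchrony(chrons, groups)["g"].a_hat)
        assert all(np.diff(a_hats) > 0)

    def test_two_groups_share_residual_variance(self, rng):
        ca, ga = _chronset(rng, 6, 80, 0.3, 0.5, group="a")
        cb, gb = _chronset(rng, 6, 80, 0.02, 0.5, group="b")
        fits = fit_synchrony(ca + cb, {**ga, **gb})
        assert fits["a"].sigma2_resid == fits["b"].sigma2_resid
        assert fits["a"].a_hat > fits["b"].a_hat

    def test_too_few_chronologies_rejected(self, rng):
        chrons, groups = _chronset(rng, 3, 40, 0.2, 0.5)
        with pytest.raises(ValueError, match="chronologies"):
            fit_synchrony(chrons, groups)


def test_rwi_matrix_alignment(rng):
    d1 = DetrendedSeries("a", "S", 1950, rng.normal(1, 0.1, 30))
    d2 = DetrendedSeries("b", "S", 1960, rng.normal(1, 0.1, 30))
    m = rwi_matrix([d1, d2])
    assert m.shape == (2, 40)
    assert np.isnan(m.loc["b", 1955])
    assert m.loc["a", 1950] == d1.rwi[0]


def test_mean_pairwise_correlation_small_cases(rng):
    block = rng.normal(0, 1, size=(2, 30))
    r, n_pairs = mean_pairwise_correlation(block)
    assert n_pairs == 1
    assert r == pytest.approx(np.corrcoef(block)[0, 1])
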