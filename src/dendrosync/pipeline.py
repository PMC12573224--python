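"""Single-config orchestration of the full analysis.

Stages (each reads its inputs from and writes its outputs to a workspace
directory, so ``run`` and the stepwise CLI produce identical artifacts):

    simulate -> derive-climate -> chronologies -> correlations
             -> synchrony -> tscs -> lmm

All randomness descends from the config seed through named sub-streams;
re-running with the same config and seed reproduces every CSV/JSON
byte-identically.  A manifest records the config hash, seeds, package
version and stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dendrosync import __version__
from dendrosync import climate as clim
from dendrosync import correlations as corr
from dendrosync import ringio
from dendrosync import synchrony as sync
from dendrosync import tscs
from dendrosync import sensitivity as sens
from dendrosync.chronology import site_chronology, spline_detrend, SiteChronology
from dendrosync.synthetic import SimulationConfig, simulate_network

log = logging.getLogger("dendrosync")

STAGES = ("simulate", "derive-climate", "chronologies", "correlations",
          "synchrony", "tscs", "lmm")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    early: tuple[int, int] = (1950, 1985)
    late: tuple[int, int] = (1986, 2023)
    n_boot: int = 1000
    alpha: float = 0.05
    rbar_window: int = 20
    rbar_min_trees: int = 6
    min_depth: int = 5
    bioclim_period: tuple[int, int] = (1981, 2010)
    lmm_mode: str = "all"  # or "significant"
    seed: int = 0
    write_daily: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.lmm_mode not in ("all", "significant"):
            raise ValueError(f"unknown lmm_mode {self.lmm_mode!r}")
        # validates ordering/length constraints
        corr.PeriodSplit(tuple(self.early), tuple(self.late))

    @property
    def split(self) -> corr.PeriodSplit:
        return corr.PeriodSplit(tuple(self.early), tuple(self.late))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            simd = dict(d["simulation"])
            if "trend_params" in simd:
                simd["trend_params"] = tuple(simd["trend_params"])
            d["simulation"] = SimulationConfig(**simd)
        for key in ("early", "late", "bioclim_period"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifact {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    net, daily, truth = simulate_network(cfg.simulation)
    (outdir / "rings").mkdir(parents=True, exist_ok=True)
    ringio.write_site_table(net.sites, outdir / "sites.csv")
    for sid in net.site_ids:
        ringio.write_rwl(net.site_series(sid), outdir / "rings" / f"{sid}.rwl")
    if cfg.write_daily:
        (outdir / "daily").mkdir(exist_ok=True)
        for sid, df in daily.items():
            df.to_csv(outdir / "daily" / f"{sid}.csv", index=False,
                      float_format="%.6g")
    truth.to_json(outdir / "truth.json")
    report = ringio.validate_network(net, climate_start=cfg.simulation.year_start)
    (outdir / "network_report.json").write_text(json.dumps(
        {"n_series": report.n_series, "n_sites": report.n_sites,
         "flags": report.flags}, indent=2))


def stage_derive_climate(cfg: PipelineConfig, outdir: Path) -> None:
    sites = ringio.read_site_table(_require(outdir / "sites.csv", "derive-climate"))
    (outdir / "monthly").mkdir(exist_ok=True)
    bior = []
    for sid, meta in sorted(sites.items()):
        daily = clim.read_daily_csv(
            _require(outdir / "daily" / f"{sid}.csv", "derive-climate"))
        monthly = clim.monthly_aggregate(daily, meta.latitude)
        clim.write_monthly_csv(monthly, outdir / "monthly" / f"{sid}.csv")
        bio = clim.bioclim(monthly, cfg.bioclim_period)
        bior.append({"site_id": sid, "bio9": bio.bio9, "bio10": bio.bio10,
                     "bio11": bio.bio11, "bio18": bio.bio18})
    pd.DataFrame(bior).to_csv(outdir / "bioclim.csv", index=False)


def _load_chronologies(outdir: Path, stage: str) -> list[SiteChronology]:
    df = pd.read_csv(_require(outdir / "chronologies.csv", stage))
    out = []
    for sid, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("year")
        out.append(SiteChronology(
            site_id=str(sid),
            years=grp["year"].to_numpy(dtype=int),
            rwi=grp["rwi"].to_numpy(dtype=float),
            sample_depth=grp["sample_depth"].to_numpy(dtype=int),
            prewhitened=True,
        ))
    return out


def stage_chronologies(cfg: PipelineConfig, outdir: Path) -> None:
    sites = ringio.read_site_table(_require(outdir / "sites.csv", "chronologies"))
    rows = []
    for sid in sorted(sites):
        series = ringio.read_rwl(
            _require(outdir / "rings" / f"{sid}.rwl", "chronologies"), site_id=sid)
        chron = site_chronology(series, min_depth=cfg.min_depth, prewhitened=True)
        # restrict to the climate-covered analysis span
        lo = cfg.split.bounds("full")[0]
        keep = chron.years >= lo
        rows.append(pd.DataFrame({
            "site_id": sid, "year": chron.years[keep],
            "rwi": chron.rwi[keep],
            "sample_depth": chron.sample_depth[keep],
            "ar_order": chron.ar_order,
        }))
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "chronologies.csv", index=False)


def stage_correlations(cfg: PipelineConfig, outdir: Path) -> None:
    chronologies = _load_chronologies(outdir, "correlations")
    results = []
    for chron in chronologies:
        monthly = pd.read_csv(
            _require(outdir / "monthly" / f"{chron.site_id}.csv", "correlations"))
        results.extend(corr.site_correlations(
            chron, monthly, split=cfg.split, n_boot=cfg.n_boot, seed=cfg.seed))
    frame = corr.results_to_frame(results)
    frame.to_csv(outdir / "correlations.csv", index=False)

    best = corr.best_by_cell(results)
    best_full = [r for (s, v, se, p), r in best.items() if p == "full"]
    classes, summary = corr.classify_sites(best_full, alpha=cfg.alpha)
    summary.to_csv(outdir / "significance_summary.csv", index=False)
    corr.median_correlations(best_full).to_csv(
        outdir / "median_correlations.csv", index=False)
    corr.results_to_frame(best.values()).to_csv(
        outdir / "best_correlations.csv", index=False)


def stage_synchrony(cfg: PipelineConfig, outdir: Path) -> None:
    sites = ringio.read_site_table(_require(outdir / "sites.csv", "synchrony"))
    groups = {sid: m.sdm_group for sid, m in sites.items()}
    span = cfg.split.bounds("full")
    site_rbar = {}
    for sid in sorted(sites):
        series = ringio.read_rwl(
            _require(outdir / "rings" / f"{sid}.rwl", "synchrony"), site_id=sid)
        detrended = [spline_detrend(s) for s in series]
        matrix = sync.rwi_matrix(detrended, years=span)
        site_rbar[sid] = sync.moving_rbar(
            matrix, window=cfg.rbar_window, min_trees=cfg.rbar_min_trees)
    sync.write_rbar_csv(site_rbar, outdir / "rbar.csv")
    sync.group_rbar_curve(site_rbar, groups).to_csv(
        outdir / "rbar_groups.csv", index=False)

    chronologies = _load_chronologies(outdir, "synchrony")
    fits = {}
    for period in ("early", "late"):
        years = cfg.split.bounds(period)
        try:
            per = sync.fit_synchrony(chronologies, groups, years=years,
                                     period=period)
        except ValueError as exc:
            log.warning("synchrony %s: %s", period, exc)
            continue
        for g, f in per.items():
            fits[f"{g}/{period}"] = dataclasses.asdict(f)
    (outdir / "synchrony.json").write_text(json.dumps(fits, indent=2))


def stage_tscs(cfg: PipelineConfig, outdir: Path) -> None:
    results = pd.read_csv(_require(outdir / "correlations.csv", "tscs"))
    sites = ringio.read_site_table(_require(outdir / "sites.csv", "tscs"))
    groups = {sid: m.sdm_group for sid, m in sites.items()}
    deltas = tscs.compute_deltas_frame(results, alpha=cfg.alpha)
    deltas["group"] = deltas["site_id"].map(groups)
    deltas.to_csv(outdir / "deltas.csv", index=False)
    tests = {}
    if not deltas.empty and deltas["group"].nunique() >= 2:
        try:
            w = tscs.wilcoxon_delta_frame(deltas, groups)
            tests["wilcoxon_delta"] = w.to_dict(orient="records")
        except ValueError as exc:
            log.warning("tscs wilcoxon: %s", exc)
    # KS on the full-period best correlations between groups
    best = pd.read_csv(_require(outdir / "best_correlations.csv", "tscs"))
    full = best[best["period"] == "full"].copy()
    full["group"] = full["site_id"].map(groups)
    ks_rows = []
    for (variable, season), grp in full.groupby(["variable", "season"]):
        gnames = sorted(grp["group"].unique())
        if len(gnames) < 2:
            continue
        a = grp.loc[grp["group"] == gnames[0], "r"]
        b = grp.loc[grp["group"] == gnames[1], "r"]
        try:
            d, p = tscs.ks_compare(a, b)
        except ValueError:
            continue
        ks_rows.append({"variable": variable, "season": season,
                        "group_a": gnames[0], "group_b": gnames[1],
                        "D": d, "p": p})
    tests["ks_correlations"] = ks_rows
    (outdir / "tscs_tests.json").write_text(json.dumps(tests, indent=2))


def stage_lmm(cfg: PipelineConfig, outdir: Path) -> None:
    best = pd.read_csv(_require(outdir / "best_correlations.csv", "lmm"))
    bio = pd.read_csv(_require(outdir / "bioclim.csv", "lmm"))
    sites = ringio.read_site_table(_require(outdir / "sites.csv", "lmm"))
    meta = pd.DataFrame([
        {"site_id": sid, "sdm_group": m.sdm_group, "stand_age": m.stand_age}
        for sid, m in sorted(sites.items())
    ]).merge(bio, on="site_id")

    out = {}
    mems_rows = []
    for variable in corr.VARIABLES:
        sel = best[(best["variable"] == variable)
                   & best["period"].isin(["early", "late"])]
        if cfg.lmm_mode == "significant":
            sig = best[(best["variable"] == variable)
                       & (best["period"] == "full")
                       & (best["p"] < cfg.alpha)][["site_id", "season"]]
            sel = sel.merge(sig.drop_duplicates(), on=["site_id", "season"])
        table = sel.merge(meta, on="site_id")
        table = table.rename(columns={"r": "r"})
        try:
            fit = sens.fit_sensitivity_lmm(table)
        except ValueError as exc:
            log.warning("lmm %s: %s", variable, exc)
            continue
        mems = sens.marginal_effects(fit)
        diag = sens.diagnostics(fit)
        out[variable] = {
            "fixed_effects": {k: float(v) for k, v in fit.fe_params.items()},
            "variance_components": fit.vcomp,
            "sigma2_resid": fit.sigma2_resid,
            "converged": fit.converged,
            "singular": fit.singular,
            "r2_marginal": diag.r2_marginal,
            "r2_conditional": diag.r2_conditional,
            "shapiro_w": diag.shapiro_w,
            "vif": diag.vif,
            "n_rows": int(len(table)),
        }
        for m in mems:
            mems_rows.append({"variable": variable, **m.__dict__})
    (outdir / "lmm_summary.json").write_text(json.dumps(out, indent=2))
    pd.DataFrame(mems_rows).to_csv(outdir / "marginal_effects.csv", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "derive-climate": stage_derive_climate,
    "chronologies": stage_chronologies,
    "correlations": stage_correlations,
    "synchrony": stage_synchrony,
    "tscs": stage_tscs,
    "lmm": stage_lmm,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    _STAGE_FUNCS[stage](cfg, outdir)


def run(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write a manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=str))
            raise
        # timings go to the log only, keeping the manifest byte-reproducible
        manifest["stages"][stage] = {"status": "ok"}
        log.info("stage %s done (%.1fs)", stage, time.perf_counter() - t0)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
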