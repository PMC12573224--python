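# dendrosync

Climate–growth relationships, growth synchrony and temporal shifts in
climate sensitivity for multi-site tree-ring networks whose sites are
grouped by species-distribution-model (SDM) projections.

## The problem

Temperate oak forests at the warm edge of their range are projected to
lose climatically suitable habitat ("contraction" sites), while core
populations are projected to persist ("persistence" sites).
Dendroecology offers observable early-warning indicators of such stress:
how strongly annual ring growth tracks climate, how synchronously trees
grow within and across stands, and whether those sensitivities have
shifted over recent decades.  `dendrosync` implements that full analysis
chain for networks of ring-width series with daily climate per site, plus
a synthetic-network generator with known ground truth so every stage is
testable without any external data download.

## Methods at a glance

* **Chronologies** — each tree's ring-width series is detrended with a
  cubic smoothing spline whose frequency response is 0.50 at a 30-year
  wavelength; the ring-width index is RWI<sub>t</sub> = w<sub>t</sub> / ŵ<sub>t</sub>.
  Site chronologies are Tukey-biweight robust means, then pre-whitened
  with an AR(p) model (p by AIC) so only high-frequency variation remains.
* **Climate derivation** — daily VPD from the Tetens curve,
  VPD = 0.6108·exp(17.269·T/(T+237.3))·(1−Rh); monthly PET by
  Hargreaves–Samani, PET = 0.0023·(0.408·RA)·(T+17.8)·√(Tmax−Tmin)·days,
  with FAO-56 extraterrestrial radiation RA; climatic water balance
  CWB = P − PET; bioclimatic normals BIO9/BIO10/BIO11/BIO18 from circular
  3-month quarters of a 1981–2010 climatology.
* **Climate–growth response** — Pearson correlations of each chronology
  with every 1–5-month window inside three seasons (previous Jun–Oct,
  dormancy Nov–Mar, current Apr–Sep), pairs bootstrap with 1000
  replications for 95% CIs and two-sided p, best-window extraction by
  |r|, site classification (positive / negative / insignificant) and
  sign-separated median correlations.
* **Synchrony** — running rbar (mean pairwise inter-tree correlation,
  20-year windows) per site, and regional synchrony via the homoscedastic
  variance-components mixed model
  rwi<sub>s,t</sub> = μ<sub>g</sub> + Y<sub>g,t</sub> + ε<sub>s,t</sub> (REML), with
  â<sub>C,g</sub> = σ²<sub>yr,g</sub> / (σ²<sub>yr,g</sub> + σ²<sub>ε</sub>) ∈ [0, 1].
* **Temporal shifts (TSCS)** — Δr = |r<sub>late</sub>| − |r<sub>early</sub>| between
  1950–1985 and 1986–2023 for every window significant over the full
  period; Kolmogorov–Smirnov tests between group correlation
  distributions and Wilcoxon rank-sum tests on Δr between groups.
* **Sensitivity models** — linear mixed-effects models of the correlation
  coefficients (fixed: SDM group × period, BIO9, BIO10, BIO11, BIO18,
  stand age; random intercepts: season and site; REML), marginal effects
  at the mean (MEM) with Tukey studentized-range contrasts and a compact
  letter display, plus Nakagawa R², VIF and residual diagnostics.

## Worked example

Run the whole pipeline on a simulated 12-site network (6 sites per SDM
group, ~22 trees per site, years 1950–2023) in which contraction sites
have stronger current-season CWB forcing, higher shared-signal variance,
and a late-period CWB forcing increase:

```python
import copy
from dendrosync.pipeline import PipelineConfig, run
from dendrosync.synthetic import SimulationConfig, _default_beta

beta_late = copy.deepcopy(_default_beta())
beta_late["contraction"]["cwb_current"] = 0.22   # post-1986 shift
cfg = PipelineConfig(
    simulation=SimulationConfig(n_sites_per_group=6, seed=1,
                                shift_year=1986, beta_late=beta_late),
    seed=1)
run(cfg, "out/")
```

`out/` then holds the stage artifacts (`chronologies.csv`,
`correlations.csv`, `rbar.csv`, `synchrony.json`, `deltas.csv`,
`lmm_summary.json`, …).  With seed 1 the headline numbers are:

| quantity | contraction | persistence |
|---|---|---|
| % sites with significant current-season CWB correlation | 100.0 | 50.0 |
| median best current-season CWB correlation | 0.61 | 0.30 |
| mean running rbar | 0.51 | 0.46 |
| â_C (early period) | 0.20 | 0.07 |
| median CWB Δr | +0.07 | −0.02 |

i.e. contraction-group sites are more water-limited, more synchronous
within and across stands, and gain CWB sensitivity in the late period —
the qualitative pattern the pipeline is designed to quantify.  The same
stages are available from the shell:

```bash
dendrosync run --outdir out --seed 1
dendrosync simulate --outdir out --seed 1      # or stage by stage
```

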