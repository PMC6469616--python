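# pirtfield

Estimation of **bacterial maintenance respiration** from field respirometry
data, for aquatic microbial ecologists who want to know how much of the
oxygen consumed by natural bacterioplankton funds cell upkeep rather than
growth.

## The model

Heterotrophic bacteria respire both to build biomass and to keep existing
cells running. The Pirt model of microbial energetics relates the per-cell
(specific) respiration rate to the specific growth rate μ; in its simplified
field-applicable form

```
R_sb = R_m + b · μ          (linear)
R_sb = R_m + b_n · μ²       (empirical quadratic variant)
```

where `R_sb` is cell-specific respiration (fmol O₂ day⁻¹ cell⁻¹), μ is the
specific growth rate (day⁻¹, bacterial production divided by abundance), and
the intercept `R_m` is the **maintenance respiration** — the oxygen demand
that persists at zero growth. Because both μ and `R_sb` are measured with
error, the linear form is fitted by model II **major-axis regression**
(minimising perpendicular distances); the quadratic form is a least-squares
fit linear in μ². Uncertainty intervals are case-resampling percentile
bootstrap ("trimmed range", 2.5–97.5%).

The maintenance share of respiration at a given growth rate is
`R_m / R_sb(μ)`, and its annual average is the histogram-weighted sum

```
R_mA / R_sbA = Σ_h  f_h · R_m / R_sb(μ_h)
```

over bins of width 0.02 day⁻¹ of a year of monitoring μ observations.

The package covers the full path from raw measurements to that annual
number:

| module | role |
| --- | --- |
| `pirtfield.synthetic` | generators for oxygen traces, transect tables and annual μ sets with known ground truth |
| `pirtfield.respirometry` | optode trace → respiration rate (linear/quadratic decision rule, derivative at 1 h, detection limit) |
| `pirtfield.rates` | thymidine → cell production, μ, R_sb, cell carbon allometry, growth efficiency (BGE) |
| `pirtfield.pirt` | major-axis and quadratic model fits, bootstrap intervals, maintenance-fraction curves |
| `pirtfield.annual` | μ histogram and the weighted annual maintenance share |
| `pirtfield.stats` | Kendall τ-b screening of R_sb against nutrients/temperature with Bonferroni adjustment |
| `pirtfield.workbench` | end-to-end pipeline with manifest, summary and YAML configuration |

## Worked example

Run the built-in demonstration: it simulates a 22-sample transect whose
per-cell respiration follows the linear Pirt response with maintenance
intercept 0.32 fmol O₂ day⁻¹ cell⁻¹ and slope 8.0, plus an annual set of
200 monitoring growth rates, then executes every stage:

```sh
pirtfield demo --out demo_run --seed 0
```

```
linear fit: rm=0.3164 fmol O2/d/cell, b=7.995, r2=0.956, n=22
  maintenance fraction at mu=0.06: 39.7%
  maintenance fraction at mu=0.14: 22.0%
  annual maintenance share: 30.1%
quadratic fit: rm=0.6246 fmol O2/d/cell, b=35.68, r2=0.888, n=22
  maintenance fraction at mu=0.06: 82.9%
  maintenance fraction at mu=0.14: 47.2%
  annual maintenance share: 63.5%

annual mu observations: 200 (clamped 0 low / 3 high)
```

The major-axis fit recovers the generating coefficients (0.3164 vs 0.32,
7.995 vs 8.0) from noisy data; at slow growth (μ = 0.06 day⁻¹) roughly 40%
of per-cell respiration is maintenance under the linear model, and the
annual share — weighting each growth-rate bin by how often it occurs over a
year — is ~30% here. Fitting the (mis-specified) quadratic form to the same
data illustrates how strongly the two model shapes disagree at low μ.

Every stage is also scriptable individually (`pirtfield simulate`,
`respire`, `rates`, `fit`, `annual`, `screen`, `run`) and as plain library
calls; see `docs/methods.md` for the science and the numerical choices.

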