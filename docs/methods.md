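# Methods

## Scope and model

The package estimates bacterial maintenance respiration — the per-cell
oxygen demand that persists at zero growth — from three kinds of field
inputs: optode dissolved-oxygen time series from incubated bottles,
station×depth transect tables (abundance, production, cell volume,
nutrients, bulk respiration), and an annual monitoring series of specific
growth rates. The central object is the simplified Pirt relation

    R_sb(μ) = R_m + b·μ         (linear form)
    R_sb(μ) = R_m + b_n·μ²      (empirical quadratic form)

between cell-specific respiration `R_sb` (fmol O₂ day⁻¹ cell⁻¹) and the
specific growth rate μ (day⁻¹). `R_m` lumps the constant and the
growth-rate-dependent maintenance coefficients of the full Pirt model,
which are not separable from field data; likewise `b` is a composite of
the growth yield and maximum-growth-rate terms. The package fits only the
simplified forms and documents, rather than estimates, the underlying
decomposition.

All rates are handled per day internally; oxygen traces store hours for
readability and convert on ingestion.

## Respirometry

A trace (≥ 3 strictly increasing time points, oxygen in µmol O₂ dm⁻³) is
fitted with both a straight line and a second-order polynomial by ordinary
least squares. The trace is classified **nonlinear** when
`R²_quad − R²_lin ≥ 0.02`; ties go to nonlinear because the published gap
criterion is a guideline and this choice keeps the nonlinear count
monotone non-increasing in the threshold. Plain (not adjusted) R² is used:
the criterion is a fixed gap, and the comparison is between nested fits on
identical points. For nonlinear traces the rate is the negated first
derivative of the polynomial evaluated 1 h after the first observation
(configurable); for linear traces it is the negated slope. Declining
oxygen yields positive rates. The polynomial is fitted to the full trace;
no window trimming or outlier removal is applied. A purely advisory
monotonicity check (decreasing isotonic fit explaining ≥ 99% of variance)
is logged but never decides the branch.

The detection limit from blank controls is
`sqrt(SE_sample² + SD_drift²)`, with `SE_sample` the root-mean-square of
the per-control linear-slope standard errors and `SD_drift` the sample SD
of the control rates. The square root is taken so the limit carries rate
units; the below-detection flag uses a strict `<` and preserves the rate
value.

## Rate conversions

* cell production = thymidine incorporation × TCF (default 1.7 × 10¹⁸
  cells per mol thymidine, the high-productivity seasonal factor; the
  low-productivity factor 1.2 × 10¹⁸ is a config value),
* μ = production / abundance; R_sb = bulk rate / abundance (µmol → fmol),
* cell carbon = α·V^β fg C with defaults α = 120, β = 0.72 (a standard
  Norland-style allometry; the exact published parameterisation behind any
  given dataset should be supplied via `ConversionConfig`),
* BGE = P_b / (P_b + RQ·R_b) with respiratory quotient RQ = 0.9 by
  default (mol CO₂ per mol O₂),
* `carbon_specific_maintenance(rm, cell_carbon, rq)` = rm·RQ/cell-carbon
  converts a maintenance intercept into carbon turnover per cell carbon
  (day⁻¹).

All conversions are homogeneous of degree zero in (abundance, bulk
rates): jointly rescaling leaves μ, R_sb and BGE unchanged.

## Model fitting

**Linear form.** Model II major-axis regression: the slope is the first
principal axis of the sample covariance matrix,
`(s_yy − s_xx + sqrt((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)`, the intercept
passes through the centroid. This minimises summed squared perpendicular
distances, appropriate when both variables carry error; the test suite
verifies equivalence with a brute-force numerical minimiser of the
perpendicular objective to 1 × 10⁻⁶. `s_xy = 0` raises an explicit
undefined-slope error. R² is reported as the squared Pearson correlation
(a regression-symmetric choice that matches the major-axis symmetry). A
negative fitted intercept is reported with a warning, never clamped, so
that simulation studies see the estimator's true sampling distribution.

**Quadratic form.** Least squares of R_sb on (1, μ²) — mathematically
identical to the nonlinear parameterisation but solved in closed form.

**Uncertainty.** Both fits use case-resampling percentile bootstrap
(2.5th–97.5th percentiles, the "trimmed range") with a mandatory, logged
seed; degenerate replicates are dropped with a warning. Significance of a
coefficient is read from whether its interval excludes zero. For the
major axis an approximate analytic interval is available behind
`interval_method="major-axis-analytic"`: a Jolicoeur-style interval on
the axis angle, half-width `arcsin(sqrt(H))` with
`H = F(1, n−2)·λ₁λ₂ / ((n−2)(λ₁−λ₂)²)`, intercept limits paired through
the centroid. It agrees with the normal-theory asymptotic interval to
first order and is undefined when the axis orientation is unresolved
(H ≥ 1).

**Known estimator property.** When the scatter around the line is mostly
vertical (measurement error on R_sb dominating error on μ — the realistic
regime here, since R_sb is order 1 and μ order 0.1 in their natural
units), the major axis attributes that noise to both coordinates,
over-steepens, and biases the intercept downward; percentile intervals
centre on the biased estimand. At the package's default noise levels this
bias is ~5% of the intercept at n = 22. The quadratic fit, being ordinary
least squares in μ², is unbiased under the same noise. Simulation tests
quantify both behaviours; users comparing the two forms on real data
should keep this asymmetry in mind.

## Annual integration

Annual growth-rate observations are binned into uniform half-open bins
(default width 0.02 day⁻¹ over 0.02–0.28 day⁻¹). The lower edge of the
nominal integration range is ambiguous in common usage (sums "from 0" over
an observed range starting at 0.02); the range is configurable and
defaults to the observed 0.02–0.28. Out-of-range values are clamped into
the edge bins with logged counts rather than dropped — a no-op when the
range truly encompasses the data. Each bin is represented by its midpoint
(second-order accurate for smooth densities); the annual share is
`Σ f_h · R_m/R_sb(midpoint)`. As bin width shrinks this converges to the
exact per-observation mean, which the tests verify to < 0.005 at width
0.002 with 10⁵ observations.

## Covariate screening

Kendall's τ-b (tie-corrected, two-sided; exact enumeration for small
untied samples, normal approximation otherwise, via scipy) correlates
R_sb with temperature, TDP, TDN, DOC, the molar ratios C:P = DOC/TDP and
C:N = DOC/TDN, and μ, per subset (e.g. depth layer) or combined. The
Bonferroni family defaults to the factors within one subset (multiplier =
number of factors); a global family (factors × subsets) is available. The
family definition is a logged configuration choice, as conventions differ.

## Synthetic data

The generators define the study conditions for every simulation test:

* **Traces**: `O2(t) = O2₀ − r·t − c·t²/2` plus i.i.d. Gaussian sensor
  noise (default SD 0.1 µmol dm⁻³ at 1-min sampling over 18 h; incubations
  run 12–24 h); blank controls add a per-bottle Gaussian drift rate. The
  metadata stores the true instantaneous rate at 1 h.
* **Transects** (default n = 22): true μ uniform on 0.01–0.20 day⁻¹ (the
  observed filtered-sample range under productive conditions); R_sb =
  Pirt response + additive Gaussian residual truncated at zero, default
  SD 0.08 fmol O₂ day⁻¹ cell⁻¹ (the ~9.5% between-bottle variation
  coefficient of respiration measurements at the mean per-cell rate);
  observed μ adds Gaussian error of SD 0.008 day⁻¹ (combined production
  ~6.4% and abundance ~4.2% bottle CVs at a typical μ of 0.1). Abundance
  uniform 1–5 × 10⁹ cells dm⁻³; bulk respiration and cell production are
  back-computed so the rate conversions invert exactly. Nutrient columns
  are drawn independently (they exist for the screening module; no
  mechanistic nutrient–respiration coupling is simulated).
* **Annual μ**: lognormal (default median 0.10 day⁻¹, log-SD 0.5, n = 200
  — the order of a year of duplicate monitoring casts at four depths),
  uniform, or a pass-through empirical list; values clipped to
  0.02–0.28 day⁻¹.

What the generator does **not** emulate: ecological (between-station)
variation in R_sb beyond measurement error, seasonal structure in the
annual μ series, nutrient control of respiration, or correlated errors
between μ and R_sb (both derive from the same abundance measurement in
the field). Passing recovery tests therefore demonstrate estimator
correctness under measurement noise, not robustness to model
mis-specification in real transects — where the larger observed scatter
would amplify the major-axis intercept bias discussed above.

## Numerical and design choices

* Fits are closed-form (covariances / normal equations); no iterative
  optimisation anywhere in the fitting path. The brute-force
  perpendicular-distance minimiser exists only as a test oracle.
* Constant-response data: R² is defined as 1 (a constant fits constant
  data perfectly); the quadratic slope is exactly 0.
* Bootstrap replicate matrices are drawn in one vectorised pass per fit;
  simulation suites (200 transects × 500 replicates) run in seconds.
* Simulation sizes in the test suite (200 simulated transects of n = 22,
  500 bootstrap replicates, 10⁵ annual observations, 50 oracle instances)
  were chosen to bound Monte-Carlo error well below the asserted margins
  while keeping a full run near ten seconds.
* The pipeline manifest excludes wall-clock time so fixed-seed re-runs
  are bitwise identical; every stochastic stage derives its stream from
  the single run seed.
* A `fit.override` block injects externally published coefficients to run
  the downstream stages (fraction curves, annual integration) when the
  transect behind a fit is unavailable.

## Limitations

* The maintenance/growth decomposition inherits the Pirt model's
  assumption that μ is the sole driver of R_sb; taxonomic and substrate
  effects are absorbed into μ.
* Major-axis regression presumes comparable error variances on both axes;
  with vertical-dominated scatter its intercept is biased low (quantified
  above). Reduced-major-axis or measurement-error-ratio regression would
  behave differently and is not implemented.
* The quadratic form is empirical; extrapolating its maintenance fraction
  beyond the fitted μ range assumes growth-dependent maintenance remains
  unchanged at high μ, which likely overestimates maintenance there.
* Optode calibration (phase → concentration, salinity/temperature
  compensation) is upstream of this package; inputs are assumed
  calibrated concentrations.
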