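"""Simplified Pirt model fits and maintenance-fraction curves.

The simplified Pirt model relates per-cell respiration to the specific
growth rate,

    R_sb = R_m + b * mu            (linear form)
    R_sb = R_m + b_n * mu**2       (empirical quadratic form)

where the intercept R_m is the maintenance respiration: the oxygen
consumption that persists at zero growth.  Because both mu and R_sb are
measured with error, the linear form is fitted by model II major-axis
regression (minimising summed squared perpendicular distances); the
quadratic form is an ordinary least-squares fit that is linear in
mu**2.  Uncertainty intervals come from case-resampling percentile
bootstrap ("trimmed range", 2.5th-97.5th percentiles) by default; an
approximate analytic interval on the major-axis angle is available via
``interval_method="major-axis-analytic"``.

The maintenance fraction R_m / R_sb(mu) quantifies how much of total
per-cell respiration funds maintenance at a given growth rate; it is 1
at mu = 0 and decreases monotonically for positive coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, InputError, UndefinedSlopeError

__all__ = [
    "PirtFit",
    "FractionCurve",
    "fit_major_axis",
    "fit_quadratic",
    "predict_rsb",
    "maintenance_fraction",
    "fraction_curve",
]


@dataclass(frozen=True)
class PirtFit:
    """A fitted maintenance-respiration model.

    ``rm`` is the y-intercept (fmol O2 day-1 cell-1); ``b`` the slope
    coefficient on mu (linear) or mu**2 (quadratic); ``r2`` the squared
    Pearson correlation (linear) or coefficient of determination
    (quadratic); intervals are 95% two-sided.
    """

    form: str  # "linear" | "quadratic"
    rm: float
    b: float
    r2: float
    n: int
    rm_interval: tuple[float, float] | None = None
    b_interval: tuple[float, float] | None = None
    interval_method: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic"):
            raise ConfigurationError(f"unknown model form {self.form!r}")
        for iv in (self.rm_interval, self.b_interval):
            if iv is not None and not iv[0] <= iv[1]:
                raise ConfigurationError("interval bounds must be ordered")


def _validate_xy(mu, r_sb) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(mu, dtype=float)
    y = np.asarray(r_sb, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("mu and r_sb must be 1-D arrays of equal length")
    if x.size < 3:
        raise InputError("model fitting requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("mu and r_sb must be finite")
    return x, y


def _ma_slope_intercept(x: np.ndarray, y: np.ndarray):
    """Major-axis slope/intercept; vectorised over leading axes.

    Slope of the first principal axis of the sample covariance matrix:
    ``(s_yy - s_xx + sqrt((s_yy - s_xx)**2 + 4 s_xy**2)) / (2 s_xy)``.
    """
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=-1)
    syy = np.sum((y - ym) ** 2, axis=-1)
    sxy = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)
    intercept = np.squeeze(ym, axis=-1) - slope * np.squeeze(xm, axis=-1)
    return slope, intercept, (sxx, syy, sxy)


def _bootstrap_percentile(x, y, estimator, n_boot, seed):
    """Case-resampling percentile intervals for (rm, b)."""
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    b_rep, rm_rep = estimator(x[idx], y[idx])
    keep = np.isfinite(b_rep) & np.isfinite(rm_rep)
    if keep.sum() < n_boot:
        warnings.warn(
            f"{n_boot - int(keep.sum())} degenerate bootstrap replicates dropped",
            stacklevel=3,
        )
    rm_iv = tuple(np.percentile(rm_rep[keep], [2.5, 97.5]))
    b_iv = tuple(np.percentile(b_rep[keep], [2.5, 97.5]))
    return rm_iv, b_iv


def _ma_analytic_intervals(slope, x, y, moments, alpha=0.05):
    """Approximate analytic interval on the major-axis angle.

    Jolicoeur-style: the half-width of the axis-angle interval is
    ``arcsin(sqrt(H))`` with ``H = F(1, n-2) * l1*l2 / ((n-2)*(l1-l2)**2)``
    for eigenvalues l1 > l2 of the covariance matrix.  Intercept limits
    pair the slope limits with the centroid.
    """
    sxx, syy, sxy = moments
    n = x.size
    cov = np.array([[sxx, sxy], [sxy, syy]]) / (n - 1)
    l2, l1 = np.sort(np.linalg.eigvalsh(cov))
    if l1 <= l2 or l2 < 0:
        return None, None
    fcrit = sps.f.ppf(1 - alpha, 1, n - 2)
    h = fcrit * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
    if h >= 1:
        return None, None  # axis orientation unresolved at this confidence
    phi = np.arcsin(np.sqrt(h))
    theta = np.arctan(slope)
    lims = np.tan([theta - phi, theta + phi])
    b_iv = (float(min(lims)), float(max(lims)))
    rm_lims = y.mean() - np.array(b_iv)[::-1] * x.mean()
    rm_iv = (float(min(rm_lims)), float(max(rm_lims)))
    return rm_iv, b_iv


def fit_major_axis(
    mu,
    r_sb,
    n_boot: int = 2000,
    seed: int | None = None,
    interval_method: str = "bootstrap-percentile",
) -> PirtFit:
    """Fit ``R_sb = rm + b*mu`` by model II major-axis regression.

    The major axis minimises the summed squared perpendicular distances
    from the points to the line, which is appropriate when both
    variables carry error.  ``r2`` is the squared Pearson correlation.
    A negative fitted intercept is reported as-is with a warning.
    """
    x, y = _validate_xy(mu, r_sb)
    if np.all(x == x[0]):
        raise InputError("mu has zero variance")
    slope, intercept, moments = _ma_slope_intercept(x, y)
    if moments[2] == 0:
        raise UndefinedSlopeError("zero covariance between mu and r_sb: slope undefined")
    slope = float(slope)
    intercept = float(intercept)
    if intercept < 0:
        warnings.warn(f"fitted maintenance intercept is negative ({intercept:.3g})")
    r2 = float(sps.pearsonr(x, y)[0] ** 2)

    rm_iv = b_iv = None
    if interval_method == "bootstrap-percentile":
        if seed is None:
            raise ConfigurationError("bootstrap intervals require an explicit seed")

        def estimator(xb, yb):
            s, a, _ = _ma_slope_intercept(xb, yb)
            return s, a

        rm_iv, b_iv = _bootstrap_percentile(x, y, estimator, n_boot, seed)
    elif interval_method == "major-axis-analytic":
        rm_iv, b_iv = _ma_analytic_intervals(slope, x, y, moments)
    elif interval_method is not None and interval_method != "none":
        raise ConfigurationError(f"unknown interval method {interval_method!r}")

    return PirtFit(
        form="linear", rm=intercept, b=slope, r2=r2, n=x.size,
        rm_interval=rm_iv, b_interval=b_iv, interval_method=interval_method, seed=seed,
    )


def _quad_coeffs(x, y):
    """OLS of y on [1, x**2]; vectorised over leading axes. Returns (b, rm)."""
    z = x**2
    zm = z.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    szz = np.sum((z - zm) ** 2, axis=-1)
    szy = np.sum((z - zm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(szz > 0, szy / np.where(szz > 0, szz, 1.0), 0.0)
    rm = np.squeeze(ym, axis=-1) - b * np.squeeze(zm, axis=-1)
    return b, rm


def fit_quadratic(
    mu, r_sb, n_boot: int = 2000, seed: int | None = None
) -> PirtFit:
    """Fit ``R_sb = rm + b*mu**2`` by least squares (linear in mu**2).

    The 95% intervals are 2.5th-97.5th percentiles over ``n_boot``
    case-resampling bootstrap replicates (the "trimmed range").
    """
    x, y = _validate_xy(mu, r_sb)
    if np.all(x == x[0]):
        raise InputError("mu is degenerate (all values equal)")
    b, rm = _quad_coeffs(x, y)
    b, rm = float(b), float(rm)
    fitted = rm + b * x**2
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum((y - fitted) ** 2)) / sst)

    rm_iv = b_iv = None
    if n_boot:
        if seed is None:
            raise ConfigurationError("bootstrap intervals require an explicit seed")
        rm_iv, b_iv = _bootstrap_percentile(x, y, _quad_coeffs, n_boot, seed)
    if rm < 0:
        warnings.warn(f"fitted maintenance intercept is negative ({rm:.3g})")
    return PirtFit(
        form="quadratic", rm=rm, b=b, r2=min(1.0, r2), n=x.size,
        rm_interval=rm_iv, b_interval=b_iv,
        interval_method="bootstrap-percentile" if n_boot else None, seed=seed,
    )


def predict_rsb(fit: PirtFit, mu):
    """Predicted per-cell respiration at growth rate ``mu`` (scalar or array)."""
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr < 0):
        raise InputError("mu must be >= 0")
    power = 1 if fit.form == "linear" else 2
    out = fit.rm + fit.b * mu_arr**power
    return out if out.ndim else float(out)


def maintenance_fraction(fit: PirtFit, mu):
    """Maintenance share of total respiration, ``rm / R_sb(mu)``."""
    pred = np.asarray(predict_rsb(fit, mu), dtype=float)
    if np.any(pred <= 0):
        raise InputError("predicted R_sb must be positive to form a fraction")
    out = fit.rm / pred
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FractionCurve:
    """Maintenance fraction evaluated on a grid of growth rates."""

    form: str
    mu_grid: np.ndarray
    fraction: np.ndarray


def fraction_curve(fit: PirtFit, mu_grid) -> FractionCurve:
    """Evaluate :func:`maintenance_fraction` on a grid."""
    grid = np.asarray(mu_grid, dtype=float)
    return FractionCurve(form=fit.form, mu_grid=grid,
                         fraction=np.asarray(maintenance_fraction(fit, grid)))
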