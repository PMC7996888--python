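"""OLS fits of the drift and velocity-increment models, plus cross-method
Pearson comparison.

The drift model is x(t) = vd * (t - tau1) on a user-chosen time window
(tau1 < t < tau2); it is fitted as an ordinary straight line, with tau1
recovered from the intercept and its standard error propagated from the
(slope, intercept) covariance by the delta method.  Velocity-increment
magnitudes |dV| are fitted to a half-Gaussian and an exponential density by
weighted least squares on a density-normalized histogram with Poisson
(1/sqrt(count)) bin weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from woundtrack.errors import FitError, ValidationError

__all__ = [
    "FitResult",
    "ComparisonResult",
    "adjusted_r_squared",
    "fit_drift",
    "detect_drift_window",
    "fit_increment_tails",
    "fit_increment_tails_mle",
    "compare_methods",
]


@dataclass
class FitResult:
    """Fitted model parameters with standard errors and goodness of fit."""

    model: str
    params: dict
    std_errors: dict
    adj_r_squared: float
    window: tuple = None
    n_points: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.window is not None and not self.window[0] < self.window[1]:
            raise ValidationError("fit window must satisfy t_low < t_high")


@dataclass
class ComparisonResult:
    variable: str
    pearson_r: float
    p_value: float
    n: int


def adjusted_r_squared(observed, fitted, n_params):
    """1 - (1 - R^2) (n - 1) / (n - p - 1) with R^2 the explained variance."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValidationError("observed and fitted must have identical shape")
    n = observed.size
    if n < n_params + 2:
        raise ValidationError(
            f"need at least n_params + 2 = {n_params + 2} points, got {n}"
        )
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        raise ValidationError("observed values have zero variance")
    r2 = 1.0 - np.sum((observed - fitted) ** 2) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_drift(mean_x, time_h, window):
    """OLS fit of the constant-drift model x(t) = vd * (t - tau1).

    Only samples with t_low < t < t_high (strict) enter the fit.  Returns
    vd (slope) and tau1 (the time-axis intercept, -intercept/slope) with
    standard errors from the OLS covariance matrix; the tau1 SE uses
    first-order (delta-method) propagation.
    """
    mean_x = np.asarray(mean_x, dtype=float)
    time_h = np.asarray(time_h, dtype=float)
    if mean_x.shape != time_h.shape:
        raise ValidationError("mean_x and time_h must have identical shape")
    t_low, t_high = window
    if not t_low < t_high:
        raise ValidationError("fit window must satisfy t_low < t_high")
    sel = (time_h > t_low) & (time_h < t_high)
    t, x = time_h[sel], mean_x[sel]
    if t.size < 3:
        raise ValidationError(f"fewer than 3 samples inside window {window}")
    if np.ptp(t) == 0:
        raise FitError("zero time variance inside the fit window")
    # x = intercept + slope * t
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    intercept, slope = coef
    fitted = design @ coef
    resid = x - fitted
    dof = t.size - 2
    if dof <= 0:
        raise ValidationError("not enough points for standard errors")
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    se_intercept, se_slope = np.sqrt(np.diag(cov))
    if slope == 0:
        raise FitError("zero drift slope: tau1 undefined")
    tau1 = -intercept / slope
    # delta method: tau1 = -a/b, grad = (-1/b, a/b^2)
    grad = np.array([-1.0 / slope, intercept / slope**2])
    se_tau1 = float(np.sqrt(grad @ cov @ grad))
    return FitResult(
        model="drift_linear",
        params={"vd": float(slope), "tau1": float(tau1)},
        std_errors={"vd": float(se_slope), "tau1": se_tau1},
        adj_r_squared=float(adjusted_r_squared(x, fitted, 2)),
        window=(float(t_low), float(t_high)),
        n_points=int(t.size),
        extra={"intercept": float(intercept), "intercept_se": float(se_intercept)},
    )


def detect_drift_window(mean_x, time_h, sustain=3):
    """Heuristic (t_low, t_high) window for the constant-drift fit.

    t_high defaults to the first time after the velocity peak where the
    ensemble mean velocity stays <= 0 for ``sustain`` consecutive frames
    (else the last time).  t_low is the last time before the velocity peak
    at which the mean position is still below 10% of its value at t_high.
    Both bounds are meant as overridable defaults, not precise estimates.
    """
    mean_x = np.asarray(mean_x, dtype=float)
    time_h = np.asarray(time_h, dtype=float)
    v = np.diff(mean_x)
    if v.size < sustain + 1:
        return float(time_h[0]), float(time_h[-1])
    k_peak = int(np.argmax(v))
    t_high = float(time_h[-1])
    run = 0
    for k in range(k_peak, v.size):
        run = run + 1 if v[k] <= 0 else 0
        if run >= sustain:
            t_high = float(time_h[k + 1 - sustain])
            break
    x_hi = np.interp(t_high, time_h, mean_x)
    t_low = float(time_h[0])
    for k in range(k_peak, -1, -1):
        if mean_x[k] <= 0.1 * x_hi:
            t_low = float(time_h[k])
            break
    if not t_low < t_high:
        t_low = float(time_h[0])
    return t_low, t_high


def _half_gaussian_pdf(v, sigma):
    return np.sqrt(2.0 / np.pi) / sigma * np.exp(-(v**2) / (2.0 * sigma**2))


def _exponential_pdf(v, lam):
    return np.exp(-v / lam) / lam


def _weighted_density_fit(model, name, param_name, centers, density, counts,
                          total, width, p0):
    # Poisson sd on the density; refit once with model-predicted expected
    # counts, since weighting by observed counts biases the fit toward
    # downward-fluctuating low-count bins
    sigma = np.sqrt(counts) / (total * width)
    popt, _ = optimize.curve_fit(
        model, centers, density, p0=[p0], sigma=sigma, absolute_sigma=True,
        maxfev=10000,
    )
    expected = np.clip(model(centers, *popt) * total * width, 1.0, None)
    sigma = np.sqrt(expected) / (total * width)
    popt, pcov = optimize.curve_fit(
        model, centers, density, p0=popt, sigma=sigma, absolute_sigma=True,
        maxfev=10000,
    )
    fitted = model(centers, *popt)
    return FitResult(
        model=name,
        params={param_name: float(popt[0])},
        std_errors={param_name: float(np.sqrt(pcov[0, 0]))},
        adj_r_squared=float(adjusted_r_squared(density, fitted, 1)),
        window=(float(centers[0]), float(centers[-1])),
        n_points=int(centers.size),
    )


def fit_increment_tails(abs_dv, n_bins=None):
    """Fit half-Gaussian and exponential densities to |dV| magnitudes.

    The sample is histogrammed (Freedman-Diaconis bins by default,
    ``n_bins`` overrides), density-normalized, empty bins dropped, and each
    model density fitted by weighted OLS with per-bin Poisson weights
    1/sqrt(count).

    Returns
    -------
    (FitResult, FitResult)
        The half-Gaussian fit (parameter ``sigma``) and the exponential fit
        (parameter ``lambda``).
    """
    v = np.asarray(abs_dv, dtype=float).ravel()
    if v.size < 50:
        raise ValidationError(f"need at least 50 samples, got {v.size}")
    if np.any(v < 0):
        raise ValidationError("|dV| samples must be non-negative")
    if np.ptp(v) == 0:
        raise FitError("degenerate histogram: all samples identical")
    bins = "fd" if n_bins is None else int(n_bins)
    counts, edges = np.histogram(v, bins=bins)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise FitError("degenerate histogram: fewer than 3 occupied bins")
    total = v.size
    density = counts[keep] / (total * widths[keep])
    half_gauss = _weighted_density_fit(
        _half_gaussian_pdf, "half_gaussian", "sigma",
        centers[keep], density, counts[keep], total, widths[keep],
        p0=float(np.sqrt(np.mean(v**2))),
    )
    exponential = _weighted_density_fit(
        _exponential_pdf, "exponential", "lambda",
        centers[keep], density, counts[keep], total, widths[keep],
        p0=float(np.mean(v)),
    )
    return half_gauss, exponential


def fit_increment_tails_mle(abs_dv):
    """Maximum-likelihood counterparts of :func:`fit_increment_tails`.

    Secondary cross-check path; the histogram OLS fit is the primary one.
    """
    v = np.asarray(abs_dv, dtype=float).ravel()
    if v.size < 50:
        raise ValidationError(f"need at least 50 samples, got {v.size}")
    sigma = stats.halfnorm.fit(v, floc=0)[1]
    lam = stats.expon.fit(v, floc=0)[1]
    return {"sigma": float(sigma), "lambda": float(lam)}


def compare_methods(a, b, variable="values"):
    """Pearson correlation between two same-shaped collections, pooled."""
    a = np.asarray(getattr(a, "x", a), dtype=float).ravel()
    b = np.asarray(getattr(b, "x", b), dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("inputs must have identical shapes")
    if a.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("undefined correlation: an input has zero variance")
    res = stats.pearsonr(a, b)
    return ComparisonResult(
        variable=variable,
        pearson_r=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(a.size),
    )
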