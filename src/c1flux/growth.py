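"""Growth-curve fitting, group comparison and Nash-assay calibration.

Exponential fits use ordinary least squares of log(OD) against time over an
automatically selected exponential-phase window, which is the exact maximum-
likelihood fit of N = N0 * exp(mu * t) under multiplicative lognormal noise
(the photometric error model). A nonlinear refit (lmfit, same model) is
available for cross-checking but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError, FitError

__all__ = [
    "GrowthCurve",
    "ExpFit",
    "GrowthMeasurement",
    "AssayCalibration",
    "NashInversion",
    "fit_exponential",
    "doubling_time",
    "compare_groups",
    "calibrate_nash",
    "invert_nash",
    "pool_fits",
]


@dataclass
class GrowthCurve:
    """An OD600 time series; times in h, strictly increasing, OD > 0."""

    times: np.ndarray
    od: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("od must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExpFit:
    """Result of an exponential fit: mu (h^-1), N0 (OD600), the index window
    used, r^2 of log(OD) vs t, and the standard error of mu."""

    mu: float
    n0: float
    window: tuple[int, int]
    r2: float
    mu_sd: float


@dataclass
class GrowthMeasurement:
    """Summary of replicate growth rates: mean mu, SD and replicate count."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _ols_loglinear(t: np.ndarray, od: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, r^2 and slope SE of log(od) ~ t."""
    y = np.log(od)
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    sxx = float(np.sum((t - t.mean()) ** 2))
    se = np.sqrt(ss_res / (n - 2) / sxx) if n > 2 and sxx > 0 else 0.0
    return float(slope), float(intercept), r2, float(se)


def fit_exponential(
    curve: GrowthCurve,
    od_min: float = 0.04,
    od_max: float = 0.5,
    min_points: int = 4,
    r2_threshold: float = 0.95,
    refine_nonlinear: bool = False,
) -> ExpFit:
    """Fit N = N0 * exp(mu * t) on an exponential-phase window.

    Candidate windows are contiguous runs of >= ``min_points`` samples with
    OD inside [``od_min``, ``od_max``] (the photometer's reliable operating
    range). Among windows whose log-linear r^2 meets ``r2_threshold`` the
    longest is selected (ties broken by r^2): preferring length over a
    marginally better r^2 keeps the estimate stable under noise while
    reducing to the full exponential segment on clean data. Raises
    :class:`FitError` with diagnostics when no window qualifies or the best
    window has non-positive slope.
    """
    if len(curve) < 6:
        raise FitError(f"need >= 6 points, got {len(curve)}")
    in_range = (curve.od >= od_min) & (curve.od <= od_max)
    if not in_range.any():
        raise FitError(
            f"no OD values inside the fit range [{od_min}, {od_max}] "
            f"(observed {curve.od.min():.3g}..{curve.od.max():.3g})"
        )
    # contiguous runs of in-range samples
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(in_range):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(curve)))

    best: tuple[int, float, ExpFit] | None = None  # (length, r2, fit)
    best_any: ExpFit | None = None
    for lo, hi in runs:
        if hi - lo < min_points:
            continue
        for i in range(lo, hi - min_points + 1):
            for j in range(i + min_points, hi + 1):
                slope, intercept, r2, se = _ols_loglinear(
                    curve.times[i:j], curve.od[i:j]
                )
                fit = ExpFit(slope, float(np.exp(intercept)), (i, j), r2, se)
                if best_any is None or r2 > best_any.r2:
                    best_any = fit
                if r2 >= r2_threshold and slope > 0:
                    key = (j - i, r2)
                    if best is None or key > (best[0], best[1]):
                        best = (j - i, r2, fit)
    if best is None:
        detail = (
            f"best candidate: r2={best_any.r2:.4f}, mu={best_any.mu:.4g}, "
            f"window={best_any.window}"
            if best_any
            else "no candidate window of sufficient length"
        )
        raise FitError(
            f"no exponential window with r2 >= {r2_threshold} and positive "
            f"growth; {detail}"
        )
    fit = best[2]
    if refine_nonlinear:
        fit = _refit_nonlinear(curve, fit)
    return fit


def _refit_nonlinear(curve: GrowthCurve, fit: ExpFit) -> ExpFit:
    """Optional nonlinear refit of N = N0*exp(mu*t) on the selected window."""
    import lmfit

    i, j = fit.window
    t, od = curve.times[i:j], curve.od[i:j]
    model = lmfit.Model(lambda t, n0, mu: n0 * np.exp(mu * t))
    params = model.make_params(n0=fit.n0, mu=fit.mu)
    result = model.fit(od, params, t=t)
    mu = float(result.params["mu"].value)
    mu_sd = float(result.params["mu"].stderr or fit.mu_sd)
    return ExpFit(mu, float(result.params["n0"].value), fit.window, fit.r2, mu_sd)


def pool_fits(fits: list[ExpFit]) -> GrowthMeasurement:
    """Pool per-replicate fits into mean +/- SD (ddof=1 when n > 1)."""
    mus = np.array([f.mu for f in fits])
    sd = float(mus.std(ddof=1)) if len(mus) > 1 else 0.0
    return GrowthMeasurement(mean=float(mus.mean()), sd=sd, n=len(mus))


def doubling_time(mu: float) -> float:
    """ln(2)/mu in hours; mu must be positive."""
    if mu <= 0:
        raise DomainError(f"doubling time undefined for mu = {mu}")
    return float(np.log(2) / mu)


def compare_groups(
    a: GrowthMeasurement | tuple,
    b: GrowthMeasurement | tuple,
    equal_var: bool = False,
) -> float:
    """Two-sided t-test p-value from summary statistics.

    Welch's unequal-variance form by default (variances of growth-rate groups
    are not assumed equal); ``equal_var=True`` gives the classical pooled
    Student form. Degenerate input (both SDs zero) returns 1.0 for equal
    means and 0.0 otherwise.
    """
    a = a if isinstance(a, GrowthMeasurement) else GrowthMeasurement(*a)
    b = b if isinstance(b, GrowthMeasurement) else GrowthMeasurement(*b)
    if a.n < 2 or b.n < 2:
        raise DomainError("compare_groups needs n >= 2 in each group")
    if a.sd == 0 and b.sd == 0:
        return 1.0 if a.mean == b.mean else 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    return float(res.pvalue)


# -- Nash assay ------------------------------------------------------------


@dataclass
class AssayCalibration:
    """Linear Nash-assay calibration: absorbance = slope * mM + intercept,
    valid over ``valid_range`` (mM). The fit is not forced through the
    origin because reagent blanks are nonzero in practice."""

    slope: float
    intercept: float
    valid_range: tuple[float, float] = (0.0, 1.0)
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


@dataclass
class NashInversion:
    """A back-calculated concentration with an extrapolation flag."""

    mM: float
    in_range: bool


def calibrate_nash(
    standards: list[tuple[float, float]],
    valid_range: tuple[float, float] = (0.0, 1.0),
) -> AssayCalibration:
    """OLS line through (concentration mM, absorbance) standards.

    Requires >= 3 standards; absorbance must increase monotonically with
    concentration (non-monotone standards indicate a failed assay).
    """
    if len(standards) < 3:
        raise CalibrationError(f"need >= 3 standards, got {len(standards)}")
    pts = sorted((float(c), float(a)) for c, a in standards)
    conc = np.array([p[0] for p in pts])
    absb = np.array([p[1] for p in pts])
    if len(np.unique(conc)) < 3:
        raise CalibrationError("need >= 3 distinct standard concentrations")
    if np.any(np.diff(absb) <= 0):
        raise CalibrationError(
            "standards are not monotone: absorbance must increase with "
            "formaldehyde concentration"
        )
    slope, intercept = np.polyfit(conc, absb, 1)
    pred = slope * conc + intercept
    ss_res = float(np.sum((absb - pred) ** 2))
    ss_tot = float(np.sum((absb - absb.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope <= 0:
        raise CalibrationError(f"fitted slope {slope:g} is not positive")
    return AssayCalibration(float(slope), float(intercept), valid_range, r2)


def invert_nash(cal: AssayCalibration, absorbance: float) -> NashInversion:
    """Back-calculate mM from absorbance; flags values outside the linear
    range instead of refusing them (the caller decides whether to trust an
    extrapolation)."""
    mM = (absorbance - cal.intercept) / cal.slope
    lo, hi = cal.valid_range
    return NashInversion(mM=float(mM), in_range=bool(lo <= mM <= hi))
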