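"""Screening-assay quality statistics and dose-response fitting.

Robust Z' factor
----------------
Per-spheroid IHC readouts carry gross outliers (staining artefacts, uneven
positive-cell distribution), so the assay window between stained samples and
negative isotype controls is scored with the robust Z':

    Z' = 1 - 3 * (MAD_sample + MAD_control) / |median_sample - median_control|

where MAD is the median absolute deviation, optionally scaled by 1.4826 (the
consistency factor that makes the MAD estimate a normal SD; the default here).
Z' <= 1 always; the conventional acceptance criterion is Z' > 0.5 (strict).

Dose-response
-------------
Four-parameter logistic (4PL) fits on log10 dose:

    y = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with an optional bottom = 0 constraint (used for markers expected to vanish
at full effect), Wald 95% confidence intervals for the IC50 computed on the
log10(IC50) scale, and convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    FitFailureError,
    InvalidParameterError,
    NoDataError,
    UndefinedSeparationError,
)

#: MAD consistency factor for the normal distribution (1 / Phi^-1(3/4)).
MAD_NORMAL_SCALE = 1.4826

Z_PRIME_ACCEPTANCE = 0.5


@dataclass(frozen=True)
class AssaySignal:
    """Per-spheroid measurements for stained samples vs negative controls."""

    sample: np.ndarray
    control: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample", np.asarray(self.sample, dtype=float))
        object.__setattr__(self, "control", np.asarray(self.control, dtype=float))
        if self.sample.size < 2 or self.control.size < 2:
            raise InvalidParameterError(
                "sample and control each need >= 2 values for dispersion"
            )


def median_abs_deviation(values, scale: float = MAD_NORMAL_SCALE) -> float:
    """scale * median(|x - median(x)|); robust to outliers."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise NoDataError("MAD of an empty list is undefined")
    return float(scale * np.median(np.abs(arr - np.median(arr))))


def robust_z_prime(signal: AssaySignal, mad_scale: float = MAD_NORMAL_SCALE) -> float:
    """Robust Z' assay-window statistic; <= 1, larger is better.

    Raises
    ------
    UndefinedSeparationError
        When sample and control medians coincide (zero window).
    """
    med_s = float(np.median(signal.sample))
    med_c = float(np.median(signal.control))
    sep = abs(med_s - med_c)
    if sep == 0:
        raise UndefinedSeparationError("sample and control medians are identical")
    mad_s = median_abs_deviation(signal.sample, scale=mad_scale)
    mad_c = median_abs_deviation(signal.control, scale=mad_scale)
    return 1.0 - 3.0 * (mad_s + mad_c) / sep


def classical_z_prime(signal: AssaySignal) -> float:
    """Classical Z' using means and sample standard deviations (ddof=1)."""
    mean_s, mean_c = signal.sample.mean(), signal.control.mean()
    sep = abs(mean_s - mean_c)
    if sep == 0:
        raise UndefinedSeparationError("sample and control means are identical")
    return 1.0 - 3.0 * (signal.sample.std(ddof=1) + signal.control.std(ddof=1)) / sep


def classify_assay(z: float) -> str:
    """'acceptable' iff Z' > 0.5 (strict), else 'unacceptable'."""
    if not np.isfinite(z):
        raise InvalidParameterError(f"Z' must be finite, got {z}")
    return "acceptable" if z > Z_PRIME_ACCEPTANCE else "unacceptable"


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float               # uM
    hill: float
    ic50_ci: tuple[float, float]   # Wald 95% CI (uM)
    constrained_bottom: bool
    rss: float
    n_points: int
    covariance: np.ndarray = field(repr=False)


def four_pl(x, top, bottom, log_ic50, hill):
    """4PL response at dose x (uM) with the IC50 on the log10 scale."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(x) - log_ic50)))


def fit_4pl(
    doses,
    responses,
    constrain_bottom_zero: bool = False,
    zero_dose_floor: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with Wald IC50 confidence interval.

    Zero-dose points (untreated controls) are mapped to ``zero_dose_floor``,
    by default one log below the smallest nonzero dose.  Requires >= 4
    distinct doses (>= 5 when the bottom is free).

    Raises
    ------
    FitFailureError
        On degenerate (constant) responses or optimiser non-convergence;
        the exception carries a ``diagnostics`` dict.
    """
    x = np.asarray(doses, dtype=float).copy()
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("doses and responses differ in length")
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("responses must be finite")
    if np.any(x < 0):
        raise InvalidParameterError("doses must be >= 0")
    if np.any(x == 0):
        nz = x[x > 0]
        if nz.size == 0:
            raise InvalidParameterError("all doses are zero")
        floor = zero_dose_floor if zero_dose_floor is not None else nz.min() / 10.0
        x[x == 0] = floor
    n_distinct = np.unique(x).size
    n_params = 3 if constrain_bottom_zero else 4
    min_doses = 4 if constrain_bottom_zero else 5
    if n_distinct < min_doses:
        raise InvalidParameterError(
            f"need >= {min_doses} distinct doses for a "
            f"{'constrained' if constrain_bottom_zero else 'free-bottom'} fit"
        )
    if np.ptp(y) == 0:
        raise FitFailureError(
            "constant responses: dose-response is degenerate",
            diagnostics={"response_range": 0.0},
        )

    # data-driven initialisation: direction of effect from the dose-response
    # trend, IC50 from the half-effect crossing
    top0 = float(y[np.argmin(x)].mean() if y.ndim > 1 else y[np.argmin(x)])
    bot0 = float(y[np.argmax(x)])
    if constrain_bottom_zero:
        bot0 = 0.0
        top0 = float(np.max(np.abs(y))) or 1.0
    half = (top0 + bot0) / 2.0
    order = np.argsort(x)
    crossings = np.flatnonzero(np.diff(np.sign(y[order] - half)))
    log_ic50_0 = (
        float(np.log10(x[order][crossings[0]])) if crossings.size
        else float(np.mean(np.log10(x)))
    )
    if constrain_bottom_zero:
        p0 = [top0, log_ic50_0, 1.0]
        model = lambda x_, top, lic, hill: four_pl(x_, top, 0.0, lic, hill)
        names = ["top", "log_ic50", "hill"]
    else:
        p0 = [top0, bot0, log_ic50_0, 1.0]
        model = four_pl
        names = ["top", "bottom", "log_ic50", "hill"]

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"4PL fit did not converge: {exc}",
                              diagnostics={"p0": p0}) from exc
    if not np.all(np.isfinite(popt)):
        raise FitFailureError("4PL fit produced non-finite parameters",
                              diagnostics={"popt": popt.tolist()})

    fitted = model(x, *popt)
    rss = float(np.sum((y - fitted) ** 2))
    idx = names.index("log_ic50")
    log_ic50 = float(popt[idx])
    se = float(np.sqrt(pcov[idx, idx])) if np.all(np.isfinite(pcov)) else np.inf
    ci = (10.0 ** (log_ic50 - 1.959964 * se), 10.0 ** (log_ic50 + 1.959964 * se))
    if constrain_bottom_zero:
        top, bottom, hill = float(popt[0]), 0.0, float(popt[2])
    else:
        top, bottom, hill = float(popt[0]), float(popt[1]), float(popt[3])
    return DoseResponseFit(
        top=top, bottom=bottom, ic50=10.0 ** log_ic50, hill=hill,
        ic50_ci=ci, constrained_bottom=constrain_bottom_zero,
        rss=rss, n_points=int(x.size), covariance=pcov,
    )
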