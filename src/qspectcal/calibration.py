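"""Estimation of the camera calibration factor (CF) and dead-time constant.

The calibration model relates the observed wide-spectrum count rate R_Wo
of a serial acquisition to the known activity A through

    R_Wo = CF * X_W * exp(-CF * X_W * tau),   X_W = A * R_Wo / R_Po,

where R_Po is the observed (scatter-corrected) primary rate. Two
estimation strategies are provided:

* Method A (low-activity CF): CF first, from a linear fit through the
  origin of R_Po vs A restricted to dead-time-free samples (< 1% loss);
  then tau from a non-linear fit of the model with CF held fixed.
* Method B (full-range CF): CF and tau jointly from a single non-linear
  fit over the full activity range.

Both use unweighted least squares; tau is optimized as log(tau) for
positivity and conditioning. Standard errors come from the Jacobian-based
covariance at the optimum.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .deadtime import SaturationError, correction_factor

__all__ = [
    "AcquisitionSample",
    "CalibrationFit",
    "UsableRange",
    "FitError",
    "x_w",
    "select_dt_free",
    "fit_method_a_cf",
    "fit_method_a_tau",
    "fit_method_b",
    "calibrate",
    "calibrate_with_range",
    "detect_usable_range",
    "sensitivity_table",
    "predict_wide_rate",
]

DEFAULT_TAU0 = 0.5e-6  # initial dead-time guess, seconds


class FitError(RuntimeError):
    """Calibration fit could not be performed."""


@dataclass
class AcquisitionSample:
    """One calibration observation.

    ``window_rates`` maps combination names ("photopeak", "3W", "4W",
    "6W") to the observed summed rate R_Wo in cps; ``r_po`` is the
    scatter-corrected primary rate.
    """

    activity: float                     # known activity at scan time, MBq
    r_po: float                         # observed primary rate, cps
    window_rates: dict[str, float]
    duration: float = 1.0               # frame or per-projection time, s
    phantom: str = ""
    mode: str = "planar"                # planar | tomo
    detector: str = "avg"               # "1" | "2" | "avg"
    n_projections: int | None = None

    def __post_init__(self) -> None:
        if not self.activity > 0:
            raise ValueError(f"activity must be > 0, got {self.activity}")
        if self.r_po < 0:
            raise ValueError(f"primary rate must be >= 0, got {self.r_po}")


@dataclass
class CalibrationFit:
    cf: float                           # cps/MBq
    tau: float                          # seconds
    cf_se: float
    tau_se: float
    method: str                         # "A" | "B"
    combination: str                    # photopeak | 3W | 4W | 6W
    n_used: int
    samples_excluded: list[str] = field(default_factory=list)

    @property
    def tau_us(self) -> float:
        return self.tau * 1e6


@dataclass
class UsableRange:
    """Largest sample still on the calibration curve before saturation."""

    max_activity: float                 # MBq
    max_photopeak_rate: float           # cps
    max_wide_rate: float                # cps
    reached: bool = True                # False -> "not reached" (open-ended)
    excluded_indices: list[int] = field(default_factory=list)


def x_w(sample: AcquisitionSample, combination: str) -> float:
    """Dead-time driver X_W = A * R_Wo / R_Po for one sample."""
    if sample.r_po <= 0:
        raise ValueError(
            "X_W undefined: observed primary rate is zero for sample with "
            f"activity {sample.activity} MBq"
        )
    if combination not in sample.window_rates:
        raise KeyError(f"sample has no rate for combination {combination!r}")
    return sample.activity * sample.window_rates[combination] / sample.r_po


def _model(x, cf, tau):
    return cf * x * np.exp(-cf * x * tau)


def predict_wide_rate(fit: CalibrationFit, x) -> np.ndarray:
    """Model-predicted R_Wo at driver value(s) ``x``."""
    return _model(np.asarray(x, dtype=float), fit.cf, fit.tau)


def select_dt_free(
    samples: Sequence[AcquisitionSample],
    tau_provisional: float,
    combination: str = "6W",
    dt_threshold: float = 0.01,
) -> list[AcquisitionSample]:
    """Samples with less than ``dt_threshold`` relative dead-time loss.

    A sample is dead-time-free when the correction factor implied by its
    wide-spectrum rate and a provisional tau is below 1 + threshold.
    """
    if not tau_provisional > 0:
        raise ValueError("provisional tau must be positive")

    def loss(s: AcquisitionSample) -> float:
        try:
            return correction_factor(
                s.window_rates[combination], tau_provisional
            ) - 1.0
        except SaturationError:
            return np.inf  # saturated samples are never dead-time-free

    kept = [s for s in samples if loss(s) < dt_threshold]
    if not kept:
        raise FitError(
            "no dead-time-free samples below the "
            f"{dt_threshold:.1%} loss threshold; acquire lower activities"
        )
    return kept


def fit_method_a_cf(
    samples: Sequence[AcquisitionSample],
) -> tuple[float, float]:
    """CF and its SE from a linear fit of R_Po vs A forced through origin."""
    if len(samples) < 1:
        raise FitError("at least one dead-time-free sample required")
    a = np.array([s.activity for s in samples], dtype=float)
    r = np.array([s.r_po for s in samples], dtype=float)
    denom = float(a @ a)
    if denom == 0:
        raise FitError("degenerate activities: all zero")
    cf = float(a @ r) / denom
    if len(samples) > 1:
        resid = r - cf * a
        s2 = float(resid @ resid) / (len(samples) - 1)
        se = float(np.sqrt(s2 / denom))
    else:
        se = 0.0
    return cf, se


def _poisson_sigma(samples: Sequence[AcquisitionSample],
                   y: np.ndarray) -> np.ndarray:
    # rate sd = sqrt(counts)/T = sqrt(rate/T), with a one-count floor
    t = np.array([
        s.duration * (s.n_projections or 1) for s in samples
    ], dtype=float)
    return np.sqrt(np.maximum(y * t, 1.0)) / t


def fit_method_a_tau(
    samples: Sequence[AcquisitionSample],
    cf_fixed: float,
    combination: str = "6W",
    *,
    weighted: bool = False,
) -> tuple[float, float]:
    """tau and its SE from the model with CF held fixed.

    ``weighted=True`` applies Poisson-variance weights (sigma on each rate
    from its counts and acquisition time), which also calibrates the SE.
    """
    if not cf_fixed > 0:
        raise FitError("fixed CF must be positive")
    if len(samples) < 2:
        raise FitError("at least two samples required to fit tau")
    x = np.array([x_w(s, combination) for s in samples], dtype=float)
    y = np.array([s.window_rates[combination] for s in samples], dtype=float)
    _warn_if_unidentifiable(cf_fixed, x)
    sigma = _poisson_sigma(samples, y) if weighted else None

    def f(xv, log_tau):
        return _model(xv, cf_fixed, np.exp(log_tau))

    try:
        popt, pcov = curve_fit(
            f, x, y, p0=[np.log(DEFAULT_TAU0)], maxfev=10000,
            sigma=sigma, absolute_sigma=weighted,
        )
    except RuntimeError as exc:
        raise FitError(f"tau fit did not converge: {exc}") from exc
    tau = float(np.exp(popt[0]))
    tau_se = tau * float(np.sqrt(pcov[0, 0]))
    return tau, tau_se


def fit_method_b(
    samples: Sequence[AcquisitionSample],
    combination: str = "6W",
    *,
    weighted: bool = False,
) -> CalibrationFit:
    """Joint (CF, tau) estimate from a single non-linear fit.

    The functional form forces the curve through the origin. Initial CF is
    the through-origin slope of the lowest-decile X_W points; initial tau
    is 0.5 us. ``weighted=True`` applies Poisson-variance weights, making
    the reported standard errors statistically calibrated under counting
    noise (the default unweighted fit scales them by residual variance).
    """
    if len(samples) < 3:
        raise FitError("Method B needs at least three samples")
    x = np.array([x_w(s, combination) for s in samples], dtype=float)
    y = np.array([s.window_rates[combination] for s in samples], dtype=float)
    sigma = _poisson_sigma(samples, y) if weighted else None

    order = np.argsort(x)
    n_low = max(2, len(x) // 10)
    xl, yl = x[order[:n_low]], y[order[:n_low]]
    cf0 = float(xl @ yl) / float(xl @ xl) if xl @ xl > 0 else 1.0

    def f(xv, cf, log_tau):
        return _model(xv, cf, np.exp(log_tau))

    try:
        popt, pcov = curve_fit(
            f, x, y, p0=[cf0, np.log(DEFAULT_TAU0)], maxfev=20000,
            sigma=sigma, absolute_sigma=weighted,
        )
    except RuntimeError as exc:
        raise FitError(
            "joint CF/tau fit did not converge; check that the samples span "
            f"low and high rates (X_W range {x.min():.3g}-{x.max():.3g})"
        ) from exc
    cf = float(popt[0])
    tau = float(np.exp(popt[1]))
    cf_se = float(np.sqrt(pcov[0, 0]))
    tau_se = tau * float(np.sqrt(pcov[1, 1]))
    _warn_if_unidentifiable(cf, x)
    return CalibrationFit(
        cf=cf, tau=tau, cf_se=cf_se, tau_se=tau_se,
        method="B", combination=combination, n_used=len(samples),
    )


def _warn_if_unidentifiable(cf: float, x: np.ndarray) -> None:
    # with all CF*X*tau << 1 the exponential is flat and tau carries no
    # information; flag rather than fail
    if np.max(cf * x) * 1e-6 < 1e-3:  # < 0.1% loss at tau ~ 1 us
        warnings.warn(
            "samples cover only the linear (dead-time-free) regime; "
            "tau is poorly identified and its SE will be large",
            stacklevel=3,
        )


def calibrate(
    samples: Sequence[AcquisitionSample],
    method: str = "B",
    combination: str = "6W",
    dt_threshold: float = 0.01,
    low_activity_max: float | None = None,
    weighted: bool = False,
) -> CalibrationFit:
    """Full calibration by Method A or B.

    Method A needs a provisional tau to choose its dead-time-free subset;
    by default one Method B pass supplies it, and the same provisional tau
    corrects the residual (< 1%) dead time of the subset before the
    origin-forced linear fit, so the CF stage estimates R_Pt/A rather
    than R_Po/A. ``low_activity_max`` (MBq) overrides the subset rule
    with a fixed activity cut-off (and skips the residual correction).
    """
    if method == "B":
        return fit_method_b(samples, combination, weighted=weighted)
    if method != "A":
        raise ValueError(f"unknown method {method!r}; use 'A' or 'B'")

    if low_activity_max is not None:
        low = [s for s in samples if s.activity < low_activity_max]
        if not low:
            raise FitError(
                f"no samples below {low_activity_max} MBq for Method A"
            )
    else:
        provisional = fit_method_b(samples, combination, weighted=weighted)
        selected = select_dt_free(
            samples, provisional.tau, combination, dt_threshold
        )
        low = [
            dataclasses.replace(
                s,
                r_po=s.r_po * correction_factor(
                    s.window_rates[combination], provisional.tau
                ),
            )
            for s in selected
        ]
    low_activities = {s.activity for s in low}
    cf, cf_se = fit_method_a_cf(low)
    tau, tau_se = fit_method_a_tau(samples, cf, combination,
                                   weighted=weighted)
    excluded = [
        f"activity {s.activity:.4g} MBq excluded from CF stage (dead time "
        f">= {dt_threshold:.1%})"
        for s in samples if s.activity not in low_activities
    ]
    return CalibrationFit(
        cf=cf, tau=tau, cf_se=cf_se, tau_se=tau_se,
        method="A", combination=combination, n_used=len(samples),
        samples_excluded=excluded,
    )


def calibrate_with_range(
    samples: Sequence[AcquisitionSample],
    method: str = "B",
    combination: str = "6W",
    drop_tolerance: float = 0.05,
    **kwargs,
) -> tuple[CalibrationFit, UsableRange]:
    """Calibrate while excluding samples beyond the usable range.

    A serial acquisition deliberately extends past the operating range of
    the camera (that is how the range is measured), so samples beyond the
    sensitivity drop must not enter the fit. The fit is grown forward:
    the lower half of the series (by X_W) is fitted first, then samples
    are appended in order of increasing X_W as long as each lies within
    ``drop_tolerance`` of the extrapolated curve. This keeps a saturated
    tail from dragging the fit (a joint fit that includes even one
    post-saturation sample can bend tau enough to hide the drop).
    """
    from scipy.optimize import OptimizeWarning

    ordered = sorted(samples, key=lambda s: x_w(s, combination))
    if len(ordered) < 3:
        raise FitError("too few samples to calibrate with range exclusion")
    n0 = max(3, len(ordered) // 2)
    work = list(ordered[:n0])
    # intermediate growth fits may have ill-conditioned covariance (tau is
    # weakly identified on the low half); only their point estimates are
    # used, so the covariance warning is suppressed here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        fit = calibrate(work, method=method, combination=combination,
                        **kwargs)
        for s in ordered[n0:]:
            pred = float(predict_wide_rate(fit, x_w(s, combination)))
            if s.window_rates[combination] < (1.0 - drop_tolerance) * pred:
                break
            work.append(s)
            fit = calibrate(work, method=method, combination=combination,
                            **kwargs)
    # recompute the final fit with warnings visible (its SEs are reported)
    fit = calibrate(work, method=method, combination=combination, **kwargs)
    # report the range against the full sample set
    usable = detect_usable_range(list(samples), fit, drop_tolerance)
    return fit, usable


def detect_usable_range(
    samples: Sequence[AcquisitionSample],
    fit: CalibrationFit,
    drop_tolerance: float = 0.05,
    per_detector: dict[str, Sequence[AcquisitionSample]] | None = None,
) -> UsableRange:
    """Detect where the system leaves its paralysable operating range.

    Samples are scanned in order of increasing X_W; the range ends at the
    last sample before either (a) the observed R_Wo falls more than
    ``drop_tolerance`` below the fitted model prediction (sensitivity
    drop), or (b) the two detectors' primary rates diverge by more than
    ``drop_tolerance`` relative (``per_detector`` maps detector labels to
    sample lists aligned with ``samples``). If neither occurs the range is
    open-ended (``reached=False``) at the last sample.
    """
    comb = fit.combination
    order = sorted(range(len(samples)), key=lambda i: x_w(samples[i], comb))
    boundary = None
    for pos, i in enumerate(order):
        s = samples[i]
        pred = float(predict_wide_rate(fit, x_w(s, comb)))
        dropped = s.window_rates[comb] < (1.0 - drop_tolerance) * pred
        diverged = False
        if per_detector is not None and len(per_detector) >= 2:
            rates = [dets[i].r_po for dets in per_detector.values()]
            mean = np.mean(rates)
            if mean > 0:
                diverged = (max(rates) - min(rates)) / mean > drop_tolerance
        if dropped or diverged:
            boundary = pos
            break
    if boundary is None:
        last = samples[order[-1]]
        return UsableRange(
            max_activity=last.activity,
            max_photopeak_rate=last.window_rates.get("photopeak", np.nan),
            max_wide_rate=last.window_rates[comb],
            reached=False,
        )
    if boundary == 0:
        raise FitError(
            "every sample violates the model; no usable range detected"
        )
    last = samples[order[boundary - 1]]
    return UsableRange(
        max_activity=last.activity,
        max_photopeak_rate=last.window_rates.get("photopeak", np.nan),
        max_wide_rate=last.window_rates[comb],
        reached=True,
        excluded_indices=[i for i in order[boundary:]],
    )


def sensitivity_table(
    samples: Sequence[AcquisitionSample],
    fit: CalibrationFit | None = None,
    combination: str = "6W",
) -> pd.DataFrame:
    """Per-sample camera sensitivity R_Po/A, optionally dead-time-corrected.

    The corrected column f*R_Po/A should scatter around CF within the
    usable range.
    """
    rows = []
    for s in samples:
        row = {
            "activity_MBq": s.activity,
            "r_po_cps": s.r_po,
            "sensitivity_cps_per_MBq": s.r_po / s.activity,
        }
        if fit is not None:
            f = correction_factor(s.window_rates[combination], fit.tau)
            row["corrected_sensitivity_cps_per_MBq"] = f * s.r_po / s.activity
        rows.append(row)
    return pd.DataFrame(rows)
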