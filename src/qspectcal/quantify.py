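"""Dead-time-corrected activity quantification and accuracy scoring.

With a calibration in hand (CF in cps/MBq and tau in seconds), an
observed primary rate R_Po converts to recovered activity as

    A_rec = R_Po * f(R_Wo, tau) / CF,

where f is the paralysable correction factor driven by the wide-spectrum
rate. Accuracy is the percentage deviation of recovered from known
activity. Uncorrected quantification (f forced to 1) underestimates by
(1 - 1/f) * 100 percent at high rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import AcquisitionSample, CalibrationFit, UsableRange
from .deadtime import correction_factor

__all__ = [
    "QuantResult",
    "AccuracySummary",
    "recover_activity",
    "quantify_sample",
    "accuracy_summary",
    "rescale_slope",
    "activity_concentration",
]


@dataclass
class QuantResult:
    """Recovered activity for one observation."""

    recovered_activity: float           # MBq
    correction_factor: float
    combination: str
    r_po: float                         # cps
    r_wo: float                         # cps
    known_activity: float | None = None
    accuracy_percent: float | None = None


@dataclass
class AccuracySummary:
    mean_percent: float
    sd_percent: float                   # nan when n == 1
    n: int
    out_of_range: list[QuantResult]


def recover_activity(
    r_po: float,
    r_wo: float,
    fit: CalibrationFit,
    known_activity: float | None = None,
    *,
    apply_correction: bool = True,
) -> QuantResult:
    """Recovered activity A_rec = R_Po * f(R_Wo, tau) / CF.

    Raises a saturation error when r_wo is at or beyond the paralysable
    maximum for fit.tau: beyond that point quantification is not possible.
    ``apply_correction=False`` forces f = 1 (for studying the cost of
    omitting the dead-time correction).
    """
    f = correction_factor(r_wo, fit.tau) if apply_correction else 1.0
    a_rec = r_po * f / fit.cf
    acc = None
    if known_activity is not None:
        if not known_activity > 0:
            raise ValueError("known activity must be positive")
        acc = (a_rec - known_activity) / known_activity * 100.0
    return QuantResult(
        recovered_activity=a_rec,
        correction_factor=f,
        combination=fit.combination,
        r_po=r_po,
        r_wo=r_wo,
        known_activity=known_activity,
        accuracy_percent=acc,
    )


def quantify_sample(
    sample: AcquisitionSample,
    fit: CalibrationFit,
    **kwargs,
) -> QuantResult:
    """Apply :func:`recover_activity` to one acquisition sample."""
    return recover_activity(
        sample.r_po,
        sample.window_rates[fit.combination],
        fit,
        known_activity=sample.activity,
        **kwargs,
    )


def accuracy_summary(
    results: Sequence[QuantResult],
    usable_range: UsableRange | None = None,
    *,
    include_out_of_range: bool = False,
) -> AccuracySummary:
    """Mean and sample SD of accuracy over in-range results.

    Out-of-range results (wide-spectrum rate above the usable maximum) are
    reported separately rather than averaged, unless
    ``include_out_of_range`` is set.
    """
    scored = [r for r in results if r.accuracy_percent is not None]
    if usable_range is not None and not include_out_of_range:
        def ok(r: QuantResult) -> bool:
            # beyond saturation the observed wide rate falls back below
            # the boundary, so the known activity must be checked too
            if r.r_wo > usable_range.max_wide_rate:
                return False
            if r.known_activity is not None and \
                    r.known_activity > usable_range.max_activity * (1 + 1e-9):
                return False
            return True

        in_range = [r for r in scored if ok(r)]
        out = [r for r in scored if not ok(r)]
    else:
        in_range, out = scored, []
    if not in_range:
        raise ValueError("no in-range results with a known activity")
    acc = np.array([r.accuracy_percent for r in in_range])
    sd = float(np.std(acc, ddof=1)) if len(acc) > 1 else float("nan")
    return AccuracySummary(
        mean_percent=float(np.mean(acc)),
        sd_percent=sd,
        n=len(acc),
        out_of_range=out,
    )


def rescale_slope(
    fit: CalibrationFit | float,
    f: float,
    voxel_volume_mL: float,
    acq_time_s: float,
) -> float:
    """Bq/mL per voxel count: f / (CF * t * v) * 1e6.

    Multiplying reconstructed voxel counts by this slope yields activity
    concentration in Bq/mL, folding the calibration factor, the dead-time
    correction, the total acquisition time and the voxel volume into a
    single factor (the PET-style DICOM rescale slope).
    """
    cf = fit.cf if isinstance(fit, CalibrationFit) else float(fit)
    if not (cf > 0 and f > 0 and voxel_volume_mL > 0 and acq_time_s > 0):
        raise ValueError("rescale_slope inputs must all be positive")
    return f / (cf * acq_time_s * voxel_volume_mL) * 1e6


def activity_concentration(activity_MBq: float, volume_mL: float) -> float:
    """Activity concentration in MBq/mL of a uniformly filled compartment."""
    if not volume_mL > 0:
        raise ValueError("volume must be positive")
    return activity_MBq / volume_mL
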