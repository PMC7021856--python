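"""Paralysable dead-time model.

A paralysable detector extends its dead period with every incoming event,
so the observed count rate is R_o = R_t * exp(-R_t * tau) for true rate
R_t and dead-time constant tau. The observed rate peaks at 1/(e*tau) when
R_t = 1/tau; beyond the peak an observed rate maps to two true rates and
only the below-saturation branch (R_t * tau < 1) is physical.

The dead-time correction applied to primary (scatter-corrected photopeak)
counts is driven by the observed wide-spectrum rate R_Wo, not by the
primary rate itself: the correction factor f = R_Pt/R_Po solves
1 = f * exp(-f * R_Wo * tau), i.e. f equals the relative loss the
paralysable model predicts at R_Wo.

All rates are in counts per second and tau in seconds; microseconds
appear only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

__all__ = [
    "SaturationError",
    "CorrectionResult",
    "observed_rate",
    "max_observed_rate",
    "invert_paralysable",
    "correction_factor",
    "correct_primary",
    "SATURATION_GUARD",
]

# Reject observed rates within 1e-9 (relative) of the apex 1/(e*tau):
# at the apex the two solution branches of the inversion meet.
SATURATION_GUARD = 1.0 - 1e-9


class SaturationError(ValueError):
    """Observed rate at or beyond the paralysable maximum 1/(e*tau)."""


def _check_tau(tau: float) -> None:
    if not tau > 0:
        raise ValueError(f"dead-time constant must be > 0, got {tau}")


def observed_rate(r_true, tau: float):
    """Observed count rate for true rate ``r_true`` (scalar or array)."""
    _check_tau(tau)
    r = np.asarray(r_true, dtype=float)
    if np.any(r < 0):
        raise ValueError("true rate must be non-negative")
    out = r * np.exp(-r * tau)
    return float(out) if np.isscalar(r_true) else out


def max_observed_rate(tau: float) -> float:
    """Largest observable rate, 1/(e*tau), reached at true rate 1/tau."""
    _check_tau(tau)
    return 1.0 / (np.e * tau)


def _invert_bisection(r_obs: float, tau: float) -> float:
    # bisect on u = r_true * tau in [r_obs*tau, 1]; f(u) = u*exp(-u)
    # increases on that interval. Tolerance 1e-12 on u, absolute and
    # relative (the relative criterion matters for very low rates).
    lo, hi = r_obs * tau, 1.0
    target = r_obs * tau
    while hi - lo > max(1e-12 * lo, 1e-18):
        mid = 0.5 * (lo + hi)
        if mid * np.exp(-mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / tau


def invert_paralysable(r_obs, tau: float, *, method: str = "lambertw"):
    """True rate on the physical branch for an observed rate.

    Solves r_obs = r_true * exp(-r_true * tau) for the smaller root
    (r_true * tau < 1) via the principal branch of the Lambert W function:
    r_true = -W0(-r_obs * tau) / tau. ``method="bisection"`` uses a
    bracketed bisection instead (fallback and cross-check path).

    Raises :class:`SaturationError` for r_obs at or beyond the usable
    range (>= ``SATURATION_GUARD``/(e*tau)).
    """
    _check_tau(tau)
    r = np.asarray(r_obs, dtype=float)
    if np.any(r < 0):
        raise ValueError("observed rate must be non-negative")
    if np.any(r >= SATURATION_GUARD * max_observed_rate(tau)):
        raise SaturationError(
            f"observed rate {np.max(r):.6g} cps is at or beyond the "
            f"paralysable maximum 1/(e*tau) = {max_observed_rate(tau):.6g} "
            "cps: beyond the usable range, inversion is ambiguous"
        )
    if method == "lambertw":
        out = np.where(r > 0, -lambertw(-r * tau).real / tau, 0.0)
    elif method == "bisection":
        flat = np.atleast_1d(r)
        out = np.array(
            [_invert_bisection(v, tau) if v > 0 else 0.0 for v in flat]
        ).reshape(r.shape)
    else:
        raise ValueError(f"unknown inversion method {method!r}")
    return float(out) if np.isscalar(r_obs) else out


def correction_factor(r_wo, tau: float):
    """Dead-time correction factor f = R_Pt/R_Po driven by the observed
    wide-spectrum rate ``r_wo``.

    f solves 1 = f * exp(-f * r_wo * tau), equivalently
    f = invert_paralysable(r_wo, tau) / r_wo; f = 1 at r_wo = 0 and grows
    monotonically to e as r_wo approaches 1/(e*tau).
    """
    r = np.asarray(r_wo, dtype=float)
    r_true = np.asarray(invert_paralysable(r_wo, tau), dtype=float)
    out = np.ones_like(r)
    np.divide(r_true, r, where=r > 0, out=out)
    return float(out) if np.isscalar(r_wo) else out


@dataclass(frozen=True)
class CorrectionResult:
    """Dead-time correction of one primary-rate observation."""

    f: float            # correction factor R_Pt/R_Po (>= 1)
    r_po: float         # observed primary rate (cps)
    r_pt: float         # corrected (true) primary rate (cps)
    r_wo: float         # observed wide-spectrum driver rate (cps)


def correct_primary(r_po: float, r_wo: float, tau: float) -> CorrectionResult:
    """Dead-time-correct an observed primary rate.

    The driver of the correction is the wide-spectrum rate ``r_wo``,
    never ``r_po`` itself; the corrected rate is r_po * f(r_wo, tau).
    """
    if r_po < 0:
        raise ValueError("primary rate must be non-negative")
    f = correction_factor(r_wo, tau)
    return CorrectionResult(f=f, r_po=r_po, r_pt=r_po * f, r_wo=r_wo)
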