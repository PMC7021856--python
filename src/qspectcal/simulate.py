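"""Synthetic gamma-camera and phantom generator with known ground truth.

The simulator mirrors the calibration model exactly in its noise-free
core: for known activity A, spectral ratio k = R_Wo/R_Po (constant per
phantom geometry) and camera truth (CF, tau),

    X = CF * A * k,   R_Wo = X * exp(-X * tau),   R_Po = R_Wo / k.

The wide-spectrum rate is split over the six energy windows so that TEW
subtraction returns R_Po exactly in expectation (the photopeak window
carries the primary rate plus a local-scatter share equal to the LS + US
shares). Counts are Poisson on counts (not Gaussian on rates), seeded and
bit-reproducible. Optional extensions distort the baseline: per-detector
sensitivity decay beyond a saturation rate (detector 2 decaying faster),
pile-up displacement of primary events out of the photopeak, spurious
reconstructed background in dense regions of volumes, and Lu-177 decay of
the source between acquisitions.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import CountVolume

__all__ = [
    "LU177_HALF_LIFE_DAYS",
    "CameraTruth",
    "PhantomTruth",
    "AcquisitionPlan",
    "VolumeTruth",
    "air_2d",
    "jaszczak",
    "ctdi",
    "default_planar_plan",
    "window_rate_table",
    "generate_records",
    "generate_series",
    "generate_volume",
    "with_pileup",
    "decay",
]

# Standard physical half-life of Lu-177 in days.
LU177_HALF_LIFE_DAYS = 6.6443

_WINDOW_NAMES = ("PP", "LS", "US", "G1", "G2", "G3")


@dataclass(frozen=True)
class CameraTruth:
    """Ground-truth camera parameters.

    ``divergence`` holds per-detector post-saturation sensitivity decay
    coefficients (detector 2 larger: the system prioritizes detector 1 at
    high count rate). ``pileup_tau`` > 0 enables pile-up displacement of
    primary events out of the photopeak window.
    """

    cf_true: float = 9.36               # cps/MBq
    tau_true: float = 0.550e-6          # s
    saturation_rate: float = 350e3      # cps, wide-spectrum (6W)
    divergence: tuple[float, float] = (1.5, 4.0)
    pileup_tau: float = 0.0             # s, 0 = off

    def __post_init__(self) -> None:
        if not (self.cf_true > 0 and self.tau_true > 0):
            raise ValueError("cf_true and tau_true must be positive")
        if self.saturation_rate > 1.0 / (np.e * self.tau_true):
            raise ValueError(
                "saturation_rate cannot exceed the paralysable maximum"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Phantom geometry truth.

    ``k`` is the wide-spectrum-to-primary ratio R_Wo(6W)/R_Po, larger for
    bigger attenuating/scattering volumes. ``scatter_fractions`` splits
    the non-primary counts over the five non-photopeak windows (the
    photopeak additionally receives a local-scatter share equal to the
    LS + US shares, which is what TEW removes). ``background_level`` sets
    the spurious reconstructed-background rate in dense non-radioactive
    regions, expressed as a fraction of the primary rate of a 100-MBq
    source, so its relative effect grows as activity falls.
    """

    name: str = "Air-2D"
    k: float = 4.0
    scatter_fractions: dict[str, float] = field(default_factory=lambda: {
        "LS": 0.05, "US": 0.03, "G1": 0.07, "G2": 0.70, "G3": 0.15,
    })
    background_level: float = 0.0
    geometry: dict | None = None

    def __post_init__(self) -> None:
        if not self.k >= 1:
            raise ValueError("spectral ratio k must be >= 1")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        total = sum(self.scatter_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"scatter fractions must sum to 1, got {total}"
            )


@dataclass(frozen=True)
class AcquisitionPlan:
    """Serial acquisition plan; a fixed seed makes output bit-reproducible."""

    activities: tuple[float, ...]       # MBq at reference time
    frame_duration: float = 60.0        # s per frame (planar) or projection
    mode: str = "planar"                # planar | tomo
    n_projections: int | None = None    # tomo only
    seed: int = 0
    decay_times: tuple[float, ...] | None = None  # elapsed days per acq.
    noise: bool = True

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.activities):
            raise ValueError("activities must be positive")
        if not self.frame_duration > 0:
            raise ValueError("frame duration must be positive")
        if self.mode == "tomo" and not self.n_projections:
            raise ValueError("tomo plans need n_projections")
        if self.decay_times is not None and \
                len(self.decay_times) != len(self.activities):
            raise ValueError("decay_times must match activities in length")


def air_2d(**overrides) -> PhantomTruth:
    """Capillary sources on a foam board: minimal scatter, planar use."""
    defaults = dict(name="Air-2D", k=4.0)
    defaults.update(overrides)
    return PhantomTruth(**defaults)


def jaszczak(**overrides) -> PhantomTruth:
    """Water-filled cylinder with hot spheres at 6:1 concentration.

    The default fill mirrors a 574 MBq / 31.8 mL sphere compartment
    against 18535 MBq / 6.1 L in the cylinder (18 vs 3 MBq/mL).
    """
    defaults = dict(
        name="Jaszczak",
        k=7.0,
        scatter_fractions={
            "LS": 0.07, "US": 0.04, "G1": 0.06, "G2": 0.63, "G3": 0.20,
        },
        background_level=0.02,
        geometry={
            "dense_radius_frac": 0.46,
            "sources": [
                {"centre_frac": (0.5, 0.5, 0.5), "radius_frac": 0.38,
                 "concentration": 1.0},
                {"centre_frac": (0.30, 0.5, 0.5), "radius_frac": 0.07,
                 "concentration": 6.0},
                {"centre_frac": (0.70, 0.5, 0.5), "radius_frac": 0.07,
                 "concentration": 6.0},
            ],
        },
    )
    defaults.update(overrides)
    return PhantomTruth(**defaults)


def ctdi(diameter_cm: int = 32, **overrides) -> PhantomTruth:
    """Capillary sources inside an acrylic CTDI cylinder (10/16/32 cm)."""
    presets = {
        10: dict(k=5.5, background_level=0.03),
        16: dict(k=6.0, background_level=0.05),
        32: dict(k=6.5, background_level=0.08),
    }
    if diameter_cm not in presets:
        raise ValueError("CTDI diameter must be 10, 16 or 32 cm")
    defaults = dict(
        name=f"CTDI-{diameter_cm}",
        scatter_fractions={
            "LS": 0.06, "US": 0.04, "G1": 0.06, "G2": 0.66, "G3": 0.18,
        },
        geometry={
            "dense_radius_frac": 0.45,
            "sources": [
                {"centre_frac": (0.5, 0.5, 0.5), "radius_frac": 0.05,
                 "concentration": 1.0},
                {"centre_frac": (0.35, 0.5, 0.5), "radius_frac": 0.05,
                 "concentration": 1.0},
                {"centre_frac": (0.65, 0.5, 0.5), "radius_frac": 0.05,
                 "concentration": 1.0},
            ],
        },
        **presets[diameter_cm],
    )
    defaults.update(overrides)
    return PhantomTruth(**defaults)


def default_planar_plan(seed: int = 0, noise: bool = True) -> AcquisitionPlan:
    """17 activities spanning 19 MBq to 15.1 GBq at 60-s frames.

    Mirrors a serial planar study where capillary sources are added one at
    a time, covering the full operational range of the system.
    """
    activities = tuple(np.geomspace(19.0, 15123.0, 17))
    return AcquisitionPlan(
        activities=activities, frame_duration=60.0, mode="planar",
        seed=seed, noise=noise,
    )


def with_pileup(camera: CameraTruth, pileup_tau: float) -> CameraTruth:
    """Copy of ``camera`` with pile-up displacement enabled."""
    return dataclasses.replace(camera, pileup_tau=pileup_tau)


def decay(a0: float, t_days: float,
          half_life_days: float = LU177_HALF_LIFE_DAYS) -> float:
    """Activity after ``t_days`` of radioactive decay."""
    if not a0 > 0:
        raise ValueError("initial activity must be positive")
    if t_days < 0:
        raise ValueError("elapsed time must be non-negative")
    return a0 * 2.0 ** (-t_days / half_life_days)


def window_rate_table(
    camera: CameraTruth,
    phantom: PhantomTruth,
    activity: float,
    detector: int = 1,
) -> dict[str, float]:
    """Noise-free observed count rate (cps) per energy window.

    Includes the paralysable loss, optional pile-up displacement and the
    post-saturation per-detector sensitivity decay.
    """
    if not activity > 0:
        raise ValueError("activity must be positive")
    x = camera.cf_true * activity * phantom.k
    r_wo = x * np.exp(-x * camera.tau_true)
    r_po = r_wo / phantom.k
    scatter_total = r_wo - r_po

    w = phantom.scatter_fractions
    pp_share = w["LS"] + w["US"]
    norm = 1.0 + pp_share
    rates = {
        name: scatter_total * w[name] / norm
        for name in ("LS", "US", "G1", "G2", "G3")
    }
    rates["PP"] = r_po + scatter_total * pp_share / norm

    if camera.pileup_tau > 0:
        # a fraction of surviving primary events is displaced out of the
        # photopeak into the upper-scatter and G1 windows (6W-conserving)
        p = 1.0 - np.exp(-x * camera.pileup_tau)
        moved = p * r_po
        rates["PP"] -= moved
        rates["US"] += 0.5 * moved
        rates["G1"] += 0.5 * moved

    if r_wo > camera.saturation_rate:
        beta = camera.divergence[0 if detector == 1 else 1]
        factor = np.exp(
            -beta * (r_wo - camera.saturation_rate) / camera.saturation_rate
        )
        rates = {k_: v * factor for k_, v in rates.items()}
    return rates


def generate_records(
    camera: CameraTruth,
    phantom: PhantomTruth,
    plan: AcquisitionPlan,
) -> pd.DataFrame:
    """Raw per-window counts, one row per (acquisition, detector).

    Counts are Poisson-distributed around rate * total acquisition time
    (``plan.noise=False`` yields exact expected counts). Activities decay
    between acquisitions when ``plan.decay_times`` is given.
    """
    rng = np.random.default_rng(plan.seed)
    total_time = plan.frame_duration * (
        plan.n_projections if plan.mode == "tomo" else 1
    )
    rows = []
    for i, a0 in enumerate(plan.activities):
        a = decay(a0, plan.decay_times[i]) if plan.decay_times else a0
        for det in (1, 2):
            rates = window_rate_table(camera, phantom, a, detector=det)
            row = {
                "acquisition": i,
                "phantom": phantom.name,
                "mode": plan.mode,
                "detector": det,
                "duration_s": plan.frame_duration,
                "n_projections": plan.n_projections or 0,
                "activity_MBq": a,
            }
            for name in _WINDOW_NAMES:
                expected = rates[name] * total_time
                row[f"counts_{name}"] = (
                    int(rng.poisson(expected)) if plan.noise else expected
                )
            rows.append(row)
    return pd.DataFrame(rows)


def generate_series(
    camera: CameraTruth,
    phantom: PhantomTruth,
    plan: AcquisitionPlan,
    scatter: str = "TEW",
    detector: str = "avg",
    **kwargs,
):
    """Acquisition samples ready for calibration (counts -> rates).

    Convenience wrapper over :func:`generate_records` plus the window
    bookkeeping in :mod:`qspectcal.io`; returns a list of
    :class:`~qspectcal.calibration.AcquisitionSample`.
    """
    from .io import samples_from_records
    records = generate_records(camera, phantom, plan)
    return samples_from_records(
        records, scatter=scatter, detector=detector, **kwargs
    )


@dataclass
class VolumeTruth:
    """Bookkeeping of what was injected into a synthetic volume."""

    injected_primary_counts: float
    background_counts: float
    source_mask: np.ndarray
    r_po: float                         # noise-free observed primary, cps
    r_wo: float                         # noise-free 6W wide rate, cps


def generate_volume(
    phantom: PhantomTruth,
    activity: float,
    camera: CameraTruth,
    *,
    n_projections: int = 96,
    t_projection: float = 10.0,
    shape: tuple[int, int, int] = (48, 48, 24),
    voxel_size: tuple[float, float, float] = (4.8, 4.8, 4.8),
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> tuple[CountVolume, VolumeTruth]:
    """Synthetic reconstructed count volume with ground-truth bookkeeping.

    Source regions (spheres defined in the phantom geometry, weighted by
    concentration) share the primary counts implied by the noise-free
    camera model. Dense non-radioactive regions receive diffuse spurious
    counts at a constant rate set by ``phantom.background_level``, so
    their relative contribution is largest at low activity.
    """
    rates = window_rate_table(camera, phantom, activity, detector=1)
    # primary (TEW-corrected) rate implied by the window table
    r_po = rates["PP"] - rates["LS"] - rates["US"]
    r_wo = sum(rates.values())
    total_time = n_projections * t_projection
    primary_total = r_po * total_time

    geom = phantom.geometry or {
        "dense_radius_frac": 0.45,
        "sources": [{"centre_frac": (0.5, 0.5, 0.5), "radius_frac": 0.15,
                     "concentration": 1.0}],
    }
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(
        (np.arange(nx) + 0.5) / nx,
        (np.arange(ny) + 0.5) / ny,
        (np.arange(nz) + 0.5) / nz,
        indexing="ij",
    )
    weights = np.zeros(shape, dtype=float)
    for src in geom["sources"]:
        cx, cy, cz = src["centre_frac"]
        r = src["radius_frac"]
        inside = (ix - cx) ** 2 + (iy - cy) ** 2 + (iz - cz) ** 2 <= r ** 2
        weights[inside] = src["concentration"]
    source_mask = weights > 0
    if not source_mask.any():
        raise ValueError("phantom geometry produced no source voxels")
    expected = np.zeros(shape, dtype=float)
    expected[source_mask] = (
        primary_total * weights[source_mask] / weights[source_mask].sum()
    )

    # spurious reconstructed background in the dense, non-source region
    bg_total = 0.0
    if phantom.background_level > 0:
        bg_rate = phantom.background_level * camera.cf_true * 100.0
        bg_total = bg_rate * total_time
        dense = (ix - 0.5) ** 2 + (iy - 0.5) ** 2 <= \
            geom.get("dense_radius_frac", 0.45) ** 2
        bg_region = dense & ~source_mask
        if bg_region.any():
            expected[bg_region] += bg_total / bg_region.sum()
        else:
            bg_total = 0.0

    if noise:
        rng = rng if rng is not None else np.random.default_rng(0)
        voxels = rng.poisson(expected).astype(float)
    else:
        voxels = expected
    volume = CountVolume(
        voxels=voxels, voxel_size=voxel_size,
        n_projections=n_projections, t_projection=t_projection,
    )
    truth = VolumeTruth(
        injected_primary_counts=primary_total,
        background_counts=bg_total,
        source_mask=source_mask,
        r_po=r_po,
        r_wo=r_wo,
    )
    return volume, truth
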