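"""Tabular and JSON I/O: acquisition records, samples and calibrations.

The acquisition record CSV has one row per (acquisition, detector) with
columns: phantom, mode, detector, duration_s, n_projections, activity_MBq
and raw counts per energy window (counts_PP ... counts_G3). An optional
``acquisition`` column groups detector rows belonging to one frame; when
absent, rows are grouped by (phantom, activity, duration).

Calibrations are serialized as JSON with tau in microseconds (explicit
unit in the key name); all in-memory values stay in seconds.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import AcquisitionSample, CalibrationFit, UsableRange
from .windows import WindowCounts, WindowScheme, combined_rate, default_scheme, primary_rate

__all__ = [
    "samples_from_records",
    "read_acquisition_csv",
    "write_records_csv",
    "write_calibration",
    "read_calibration",
]

_GROUP_KEYS = (
    "acquisition", "phantom", "mode", "activity_MBq", "duration_s",
    "n_projections",
)


def samples_from_records(
    records: pd.DataFrame,
    scheme: WindowScheme | None = None,
    scatter: str = "TEW",
    detector: str = "avg",
    *,
    clip_negative: bool = True,
) -> list[AcquisitionSample]:
    """Convert raw count records into calibration samples.

    ``detector`` selects one detector's rows ("1"/"2") or averages the
    per-detector counts before rate computation ("avg"). Rates divide
    counts by the total acquisition time (duration_s, times n_projections
    for tomographic records).
    """
    scheme = scheme if scheme is not None else default_scheme()
    df = records.copy()
    df["detector"] = df["detector"].astype(str)
    if detector in ("1", "2"):
        df = df[df["detector"] == detector]
        if df.empty:
            raise ValueError(f"no rows for detector {detector!r}")
    elif detector != "avg":
        raise ValueError("detector must be '1', '2' or 'avg'")

    count_cols = [c for c in df.columns if c.startswith("counts_")]
    keys = [k for k in _GROUP_KEYS if k in df.columns]
    samples = []
    for _, group in df.groupby(keys, sort=False):
        first = group.iloc[0]
        counts = {
            c.removeprefix("counts_"): float(group[c].mean())
            for c in count_cols
        }
        n_proj = int(first["n_projections"]) if "n_projections" in group \
            else 0
        is_tomo = str(first.get("mode", "planar")) == "tomo" and n_proj > 0
        total_time = float(first["duration_s"]) * (n_proj if is_tomo else 1)
        wc = WindowCounts(counts=counts, duration=total_time)
        r_po = primary_rate(
            wc, mode=scatter, scheme=scheme, clip_negative=clip_negative
        )
        window_rates = {
            name: combined_rate(wc, name, scheme)
            for name in scheme.combinations
        }
        samples.append(AcquisitionSample(
            activity=float(first["activity_MBq"]),
            r_po=r_po,
            window_rates=window_rates,
            duration=float(first["duration_s"]),
            phantom=str(first.get("phantom", "")),
            mode=str(first.get("mode", "planar")),
            detector=detector,
            n_projections=n_proj or None,
        ))
    return samples


def read_acquisition_csv(
    path: str | Path, **kwargs
) -> list[AcquisitionSample]:
    """Read an acquisition record CSV; kwargs as in samples_from_records."""
    return samples_from_records(pd.read_csv(path), **kwargs)


def write_records_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_calibration(
    fit: CalibrationFit,
    path: str | Path,
    usable_range: UsableRange | None = None,
) -> None:
    """Serialize a calibration (tau in microseconds) as JSON."""
    payload = {
        "cf_cps_per_MBq": fit.cf,
        "cf_se": fit.cf_se,
        "tau_us": fit.tau_us,
        "tau_se_us": fit.tau_se * 1e6,
        "method": fit.method,
        "combination": fit.combination,
        "n_used": fit.n_used,
        "excluded_samples": fit.samples_excluded,
    }
    if usable_range is not None:
        payload["usable_range"] = {
            "max_activity_MBq": usable_range.max_activity,
            "max_photopeak_rate_cps": usable_range.max_photopeak_rate,
            "max_wide_rate_cps": usable_range.max_wide_rate,
            "reached": usable_range.reached,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration(
    path: str | Path,
) -> tuple[CalibrationFit, UsableRange | None]:
    d = json.loads(Path(path).read_text())
    fit = CalibrationFit(
        cf=d["cf_cps_per_MBq"],
        tau=d["tau_us"] * 1e-6,
        cf_se=d.get("cf_se", 0.0),
        tau_se=d.get("tau_se_us", 0.0) * 1e-6,
        method=d.get("method", "B"),
        combination=d.get("combination", "6W"),
        n_used=d.get("n_used", 0),
        samples_excluded=list(d.get("excluded_samples", [])),
    )
    ur = None
    if "usable_range" in d:
        u = d["usable_range"]
        ur = UsableRange(
            max_activity=u["max_activity_MBq"],
            max_photopeak_rate=u["max_photopeak_rate_cps"],
            max_wide_rate=u["max_wide_rate_cps"],
            reached=u.get("reached", True),
        )
    return fit, ur
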