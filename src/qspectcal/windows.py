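"""Energy-window schema and scatter-corrected primary count rates.

A gamma camera records counts in a set of named energy windows. For
Lu-177 quantitative SPECT the 208-keV photopeak window (PP) is flanked by
narrow lower/upper scatter windows (LS, US) and supplemented by general
scatter windows (G1-G3) so that the summed "wide-spectrum" count rate over
a window combination (3W, 4W or 6W) can be monitored as a dead-time
driver. Scatter correction of the photopeak counts uses the triple- or
dual-energy-window technique (TEW/DEW): the counts collected in the
flanking scatter window(s) are subtracted from the photopeak counts, and
the result divided by the acquisition duration gives the observed primary
count rate R_Po.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "WindowError",
    "EnergyWindow",
    "WindowScheme",
    "WindowCounts",
    "window_limits",
    "reported_limits",
    "default_scheme",
    "combined_rate",
    "primary_rate",
]


class WindowError(ValueError):
    """Invalid window parameters, unknown window names or bad counts."""


def window_limits(centre: float, width_fraction: float) -> tuple[float, float]:
    """Exact lower/upper limits in keV of a window.

    The window is centred at ``centre`` keV with a total width equal to
    ``width_fraction`` of the centre energy (e.g. 0.20 for a "20%" window),
    so each limit sits half a width away from the centre.
    """
    if not centre > 0:
        raise WindowError(f"window centre must be positive, got {centre}")
    if not 0 < width_fraction <= 1:
        raise WindowError(
            f"width fraction must be in (0, 1], got {width_fraction}"
        )
    half = centre * width_fraction / 2.0
    return centre - half, centre + half


def reported_limits(centre: float, width_fraction: float) -> tuple[int, int]:
    """Integer keV limits for display, rounded half-up (187.2 -> 187)."""
    lower, upper = window_limits(centre, width_fraction)
    return math.floor(lower + 0.5), math.floor(upper + 0.5)


@dataclass(frozen=True)
class EnergyWindow:
    """One named energy window with exact keV limits."""

    name: str
    centre: float
    width_fraction: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise WindowError(
                f"window {self.name}: lower ({self.lower}) must be below "
                f"upper ({self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @classmethod
    def from_centre(
        cls,
        name: str,
        centre: float,
        width_fraction: float,
        limits: tuple[float, float] | None = None,
    ) -> "EnergyWindow":
        """Build a window from centre/width; ``limits`` overrides the
        computed limits (used for vendor-printed integer limits)."""
        lower, upper = window_limits(centre, width_fraction)
        if limits is not None:
            lower, upper = limits
        return cls(name, centre, width_fraction, lower, upper)


@dataclass
class WindowScheme:
    """A set of energy windows plus named combinations and scatter rules.

    ``combinations`` maps a name (e.g. "6W") to the window names summed to
    form the wide-spectrum rate; ``scatter_windows`` maps a scatter
    correction mode ("TEW"/"DEW") to the windows subtracted from PP.
    """

    windows: dict[str, EnergyWindow]
    combinations: dict[str, tuple[str, ...]]
    scatter_windows: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"TEW": ("LS", "US"), "DEW": ("LS",)}
    )
    photopeak: str = "PP"

    def __post_init__(self) -> None:
        if self.photopeak not in self.windows:
            raise WindowError(
                f"photopeak window {self.photopeak!r} missing from scheme"
            )
        for name, members in self.combinations.items():
            unknown = set(members) - set(self.windows)
            if unknown:
                raise WindowError(
                    f"combination {name!r} references unknown windows "
                    f"{sorted(unknown)}"
                )
        for mode, members in self.scatter_windows.items():
            unknown = set(members) - set(self.windows)
            if unknown:
                raise WindowError(
                    f"scatter mode {mode!r} references unknown windows "
                    f"{sorted(unknown)}"
                )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "windows": [
                {
                    "name": w.name,
                    "centre_keV": w.centre,
                    "width_percent": w.width_fraction * 100.0,
                    "lower_keV": w.lower,
                    "upper_keV": w.upper,
                }
                for w in self.windows.values()
            ],
            "combinations": {k: list(v) for k, v in self.combinations.items()},
            "scatter_windows": {
                k: list(v) for k, v in self.scatter_windows.items()
            },
            "photopeak": self.photopeak,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WindowScheme":
        windows = {
            w["name"]: EnergyWindow(
                w["name"],
                w["centre_keV"],
                w["width_percent"] / 100.0,
                w["lower_keV"],
                w["upper_keV"],
            )
            for w in d["windows"]
        }
        return cls(
            windows=windows,
            combinations={k: tuple(v) for k, v in d["combinations"].items()},
            scatter_windows={
                k: tuple(v) for k, v in d.get(
                    "scatter_windows", {"TEW": ["LS", "US"], "DEW": ["LS"]}
                ).items()
            },
            photopeak=d.get("photopeak", "PP"),
        )

    def save(self, path: str) -> None:
        text_path = str(path)
        with open(text_path, "w") as fh:
            if text_path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "WindowScheme":
        with open(str(path)) as fh:
            if str(path).endswith((".yaml", ".yml")):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))


def default_scheme() -> WindowScheme:
    """The bundled six-window Lu-177 scheme.

    PP is the 20% window around the 208-keV photopeak; LS and US are the
    flanking scatter windows whose widths equal 10% of the photopeak
    centre; G1-G3 cover the remainder of the recordable spectrum
    (18-680 keV). Limits are stored as the vendor's printed integer values;
    LS/US centres are the window midpoints and width fractions are derived
    from the stored limits.
    """
    def w(name, centre, lower, upper, width_fraction=None):
        if width_fraction is None:
            width_fraction = (upper - lower) / centre
        return EnergyWindow(name, centre, width_fraction, lower, upper)

    windows = {
        "PP": w("PP", 208.0, 187.0, 229.0, 0.20),
        "LS": w("LS", 176.5, 166.0, 187.0),
        "US": w("US", 239.5, 229.0, 250.0),
        "G1": w("G1", 465.0, 250.0, 680.0, 0.93),
        "G2": w("G2", 111.0, 55.0, 166.0, 1.00),
        "G3": w("G3", 37.0, 18.0, 55.0, 1.00),
    }
    combinations = {
        "photopeak": ("PP",),
        "3W": ("PP", "LS", "G2"),
        "4W": ("PP", "LS", "US", "G2"),
        "6W": ("PP", "LS", "US", "G1", "G2", "G3"),
    }
    return WindowScheme(windows=windows, combinations=combinations)


@dataclass
class WindowCounts:
    """Counts recorded per window over one acquisition of given duration."""

    counts: Mapping[str, float]
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise WindowError(f"duration must be > 0, got {self.duration}")
        for name, c in self.counts.items():
            if c < 0:
                raise WindowError(f"negative counts for window {name!r}: {c}")


def combined_rate(
    wc: WindowCounts,
    combination: str,
    scheme: WindowScheme | None = None,
) -> float:
    """Summed observed count rate (cps) over a named window combination."""
    scheme = scheme if scheme is not None else default_scheme()
    if combination not in scheme.combinations:
        raise WindowError(f"unknown combination {combination!r}")
    members = scheme.combinations[combination]
    try:
        total = sum(wc.counts[name] for name in members)
    except KeyError as exc:
        raise WindowError(f"counts missing for window {exc.args[0]!r}") from exc
    return total / wc.duration


def primary_rate(
    wc: WindowCounts,
    mode: str = "TEW",
    scheme: WindowScheme | None = None,
    *,
    clip_negative: bool = True,
    width_weighted: bool = False,
) -> float:
    """Scatter-corrected primary count rate R_Po (cps).

    TEW subtracts LS+US counts from PP; DEW subtracts LS only. The default
    is the plain (unweighted) subtraction: with LS and US each half the PP
    width, the standard trapezoid TEW estimate reduces to the plain sum.
    ``width_weighted=True`` applies the trapezoid weighting
    (C_LS/w_LS + C_US/w_US)·w_PP/2 instead.

    A negative corrected rate (possible in low-count frames) is clipped to
    zero with a warning under the default policy; ``clip_negative=False``
    keeps the negative value for fitting studies.
    """
    scheme = scheme if scheme is not None else default_scheme()
    if mode not in scheme.scatter_windows:
        raise WindowError(f"unknown scatter mode {mode!r}")
    scatter_names = scheme.scatter_windows[mode]
    pp_name = scheme.photopeak
    missing = [n for n in (pp_name, *scatter_names) if n not in wc.counts]
    if missing:
        raise WindowError(f"counts missing for window(s) {missing}")

    pp = wc.counts[pp_name]
    if width_weighted:
        w_pp = scheme.windows[pp_name].width
        scatter = sum(
            wc.counts[n] / scheme.windows[n].width for n in scatter_names
        ) * w_pp / 2.0
    else:
        scatter = sum(wc.counts[n] for n in scatter_names)

    net = pp - scatter
    if net < 0 and clip_negative:
        warnings.warn(
            f"negative primary counts after {mode} subtraction "
            f"({net:.1f}); clipped to zero",
            stacklevel=2,
        )
        net = 0.0
    return net / wc.duration
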