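"""Primary count rates from reconstructed SPECT volumes, with segmentation.

A reconstructed SPECT volume holds projection-number-scaled counts, so the
observed primary rate is the (masked) voxel sum divided by the product of
the number of projections and the time per projection. Segmentation by
circular per-slice ROIs or by a threshold at a fraction of the maximum
voxel suppresses spurious background counts that scatter correction leaves
in non-radioactive dense regions.

Coordinate conventions: voxel arrays are indexed (x, y, z) with slices
along the last axis; physical mm are measured from the volume corner and a
voxel's centre sits at (index + 0.5) * voxel_size. A voxel belongs to a
disc when its centre lies inside it (no area weighting), matching typical
clinical ROI tools.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "CountVolume",
    "RoiSpec",
    "volume_primary_rate",
    "threshold_mask",
    "roi_mask",
    "save_volume",
    "load_volume",
    "load_roi_specs",
]


@dataclass
class CountVolume:
    """Reconstructed count volume plus the metadata needed to form rates."""

    voxels: np.ndarray          # 3-D non-negative counts
    voxel_size: tuple[float, float, float]  # mm per axis
    n_projections: int
    t_projection: float         # seconds per projection

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if np.any(self.voxels < 0):
            raise ValueError("voxel counts must be non-negative")
        if not self.n_projections > 0:
            raise ValueError("n_projections must be > 0")
        if not self.t_projection > 0:
            raise ValueError("t_projection must be > 0")

    @property
    def voxel_volume_mL(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz / 1000.0


@dataclass
class RoiSpec:
    """Circular per-slice ROI: a disc repeated over a slice range."""

    centre: tuple[float, float]     # (x, y) in mm from the volume corner
    diameter: float                 # mm
    slice_range: tuple[int, int]    # inclusive z-index range

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("ROI diameter must be > 0")


def volume_primary_rate(
    v: CountVolume, mask: np.ndarray | None = None
) -> float:
    """Observed primary rate: masked voxel sum / (n_projections * t)."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != v.voxels.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume "
                f"{v.voxels.shape}"
            )
        total = float(v.voxels[mask].sum())
    else:
        total = float(v.voxels.sum())
    return total / (v.n_projections * v.t_projection)


def threshold_mask(v: CountVolume, fraction: float = 0.01) -> np.ndarray:
    """Voxels at or above ``fraction`` of the maximum voxel value.

    The comparison is inclusive, so the maximum voxel is always kept.
    """
    if fraction < 0:
        raise ValueError("threshold fraction must be >= 0")
    vmax = float(v.voxels.max())
    if vmax <= 0:
        raise ValueError("all-zero volume: threshold undefined")
    return v.voxels >= fraction * vmax


def roi_mask(v: CountVolume, rois: Sequence[RoiSpec]) -> np.ndarray:
    """Union of per-slice discs as a boolean mask on the volume grid."""
    nx, ny, nz = v.voxels.shape
    vx, vy, _ = v.voxel_size
    xc = (np.arange(nx) + 0.5) * vx
    yc = (np.arange(ny) + 0.5) * vy
    mask = np.zeros(v.voxels.shape, dtype=bool)
    for roi in rois:
        z0, z1 = roi.slice_range
        if z0 < 0 or z1 >= nz or z0 > z1:
            raise ValueError(
                f"ROI slice range {roi.slice_range} outside volume with "
                f"{nz} slices"
            )
        cx, cy = roi.centre
        if not (0 <= cx <= nx * vx and 0 <= cy <= ny * vy):
            raise ValueError(f"ROI centre {roi.centre} outside volume bounds")
        r2 = (roi.diameter / 2.0) ** 2
        disc = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2 <= r2
        mask[:, :, z0:z1 + 1] |= disc[:, :, None]
    return mask


# -- I/O -----------------------------------------------------------------

def save_volume(v: CountVolume, path: str | Path) -> None:
    """Write a volume as NIfTI plus a JSON sidecar with timing metadata."""
    path = Path(path)
    affine = np.diag([*v.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(v.voxels, affine), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "n_projections": v.n_projections,
        "t_projection_s": v.t_projection,
    }, indent=2))


def load_volume(path: str | Path) -> CountVolume:
    """Read a NIfTI volume and its JSON sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return CountVolume(
        voxels=np.asarray(img.dataobj, dtype=float),
        voxel_size=voxel_size,
        n_projections=int(meta["n_projections"]),
        t_projection=float(meta["t_projection_s"]),
    )


def load_roi_specs(path: str | Path) -> list[RoiSpec]:
    """ROI specs from YAML: a list of {centre_mm: [x, y], diameter_mm,
    slice_range: [z0, z1]} entries."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        RoiSpec(
            centre=tuple(e["centre_mm"]),
            diameter=float(e["diameter_mm"]),
            slice_range=tuple(e["slice_range"]),
        )
        for e in entries
    ]
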