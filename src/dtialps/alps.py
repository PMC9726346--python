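"""ALPS-index computation from fitted tensor fields.

The ALPS (Analysis aLong the Perivascular Space) index is the ratio of
water diffusivity along the perivascular direction (right–left, x) to
diffusivity perpendicular to it, measured in small spherical ROIs over
the projection- and association-fibre regions at the level of the
lateral ventricle body:

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

where Dxproj/Dxassoc are the mean x-axis diffusivities in the projection
and association ROIs and Dyproj/Dzassoc the mean diffusivities along
each ROI's fibre-transverse in-plane axis. An index near 1 indicates no
preferential perivascular diffusion; larger values indicate freer
perivascular flow. ROIs are placed automatically at the world-space
centroid of each labelled fibre region (the original manual placement on
colour-FA maps is not reproducible in software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import REGION_LABELS
from .tensorfit import TensorField, axis_diffusivities

__all__ = [
    "RoiSpec",
    "AlpsMeasurement",
    "EmptyRoiError",
    "MissingRegionError",
    "MeasurementError",
    "spherical_mask",
    "locate_rois",
    "extract_alps",
    "subject_alps",
    "measurements_to_frame",
]

FIBER_CLASSES = ("projection", "association", "subcortical")
DEFAULT_ROI_DIAMETER_MM = 5.0


class EmptyRoiError(ValueError):
    """A spherical ROI contains no voxel centres."""


class MissingRegionError(ValueError):
    """The label map lacks a region required for ROI placement."""


class MeasurementError(ValueError):
    """An ROI has no valid (unflagged, in-mask) voxels."""


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI on one fibre region of one hemisphere."""

    fiber: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.fiber not in FIBER_CLASSES:
            raise ValueError(f"fiber must be one of {FIBER_CLASSES}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")


@dataclass(frozen=True)
class AlpsMeasurement:
    """Per-hemisphere ROI diffusivities and the resulting ALPS index."""

    hemisphere: str
    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dz_assoc: float
    alps_index: float
    n_voxels: dict[str, int] = field(default_factory=dict)
    dx_subcort: float | None = None


def _voxel_centers_world(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """(nx, ny, nz, 3) world coordinates of every voxel centre."""
    grid = np.stack(
        np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
    ).astype(float)
    return grid @ affine[:3, :3].T + affine[:3, 3]


def spherical_mask(
    roi: RoiSpec, shape: tuple[int, int, int], affine: np.ndarray
) -> np.ndarray:
    """Boolean voxel mask: centre-to-centre world distance ≤ diameter/2.

    Voxel inclusion is by centre (no partial-volume weighting). Raises
    :class:`EmptyRoiError` when the sphere captures no voxel centre,
    which can happen off-grid when the diameter is below the voxel
    spacing; move the centre onto the grid or enlarge the ROI.
    """
    centers = _voxel_centers_world(shape, affine)
    dist = np.linalg.norm(centers - np.asarray(roi.center_mm), axis=-1)
    mask = dist <= roi.diameter_mm / 2.0
    if not mask.any():
        raise EmptyRoiError(
            f"{roi.fiber}/{roi.hemisphere} ROI at {roi.center_mm} captures no "
            "voxel centre; adjust the centre onto the grid or increase the diameter"
        )
    return mask


def locate_rois(
    labels: np.ndarray,
    affine: np.ndarray,
    hemisphere: str,
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> list[RoiSpec]:
    """Deterministic ROI placement at each fibre region's world centroid."""
    rois = []
    centers = _voxel_centers_world(labels.shape, affine)
    for fiber in FIBER_CLASSES:
        code = REGION_LABELS[f"{fiber}_{hemisphere}"]
        mask = labels == code
        if not mask.any():
            raise MissingRegionError(
                f"label map has no {fiber!r} region for hemisphere {hemisphere!r}"
            )
        centroid = tuple(centers[mask].mean(axis=0))
        rois.append(
            RoiSpec(fiber=fiber, hemisphere=hemisphere, center_mm=centroid,
                    diameter_mm=diameter_mm)
        )
    return rois


def _roi_mean(map_: np.ndarray, roi_mask: np.ndarray, valid: np.ndarray, name: str):
    sel = roi_mask & valid
    n = int(sel.sum())
    if n == 0:
        raise MeasurementError(f"ROI {name!r} has no valid voxels")
    return float(map_[sel].mean()), n


def extract_alps(field: TensorField, rois: list[RoiSpec]) -> AlpsMeasurement:
    """Compute one hemisphere's ALPS index from its ROI set.

    Flagged voxels (clamped eigenvalues or floored signal) are excluded
    from ROI means. The subcortical ROI, when present, is measured for
    reporting but does not enter the index.
    """
    by_fiber = {r.fiber: r for r in rois}
    for needed in ("projection", "association"):
        if needed not in by_fiber:
            raise MeasurementError(f"no {needed!r} ROI provided")
    hemisphere = rois[0].hemisphere
    dxx, dyy, dzz = axis_diffusivities(field)
    valid = field.mask & ~field.flags
    shape = field.fa.shape
    proj_mask = spherical_mask(by_fiber["projection"], shape, field.affine)
    assoc_mask = spherical_mask(by_fiber["association"], shape, field.affine)

    dx_proj, n_proj = _roi_mean(dxx, proj_mask, valid, "projection")
    dy_proj, _ = _roi_mean(dyy, proj_mask, valid, "projection")
    dx_assoc, n_assoc = _roi_mean(dxx, assoc_mask, valid, "association")
    dz_assoc, _ = _roi_mean(dzz, assoc_mask, valid, "association")

    n_voxels = {"projection": n_proj, "association": n_assoc}
    dx_subcort = None
    if "subcortical" in by_fiber:
        sub_mask = spherical_mask(by_fiber["subcortical"], shape, field.affine)
        dx_subcort, n_sub = _roi_mean(dxx, sub_mask, valid, "subcortical")
        n_voxels["subcortical"] = n_sub

    alps = ((dx_proj + dx_assoc) / 2.0) / ((dy_proj + dz_assoc) / 2.0)
    return AlpsMeasurement(
        hemisphere=hemisphere,
        dx_proj=dx_proj, dx_assoc=dx_assoc,
        dy_proj=dy_proj, dz_assoc=dz_assoc,
        alps_index=alps, n_voxels=n_voxels, dx_subcort=dx_subcort,
    )


def subject_alps(
    field: TensorField, labels: np.ndarray,
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> dict[str, AlpsMeasurement]:
    """Bilateral ALPS for one subject: hemisphere → measurement."""
    out = {}
    for hemisphere in ("left", "right"):
        rois = locate_rois(labels, field.affine, hemisphere, diameter_mm)
        out[hemisphere] = extract_alps(field, rois)
    return out


def measurements_to_frame(
    per_subject: dict[str, dict[str, AlpsMeasurement]]
) -> pd.DataFrame:
    """Long-format table: one row per subject × hemisphere."""
    rows = []
    for subject_id, hemis in per_subject.items():
        for h, m in hemis.items():
            rows.append(
                {
                    "subject_id": subject_id,
                    "hemisphere": h,
                    "dx_proj": m.dx_proj,
                    "dx_assoc": m.dx_assoc,
                    "dy_proj": m.dy_proj,
                    "dz_assoc": m.dz_assoc,
                    "alps_index": m.alps_index,
                    "n_voxels": sum(m.n_voxels.values()),
                }
            )
    return pd.DataFrame(rows)
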