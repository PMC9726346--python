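"""Digital DWI phantoms with known perivascular (ALPS) diffusivity structure.

The phantom realises the geometric premise of the ALPS method at the
level of the lateral ventricle body: projection fibres run superior–
inferior (z), association fibres anterior–posterior (y), and the
perivascular direction is right–left (x), orthogonal to both. Tissue in
each labelled region carries an axis-aligned diagonal diffusion tensor,
so per-voxel diffusivity along each world axis is known in closed form
and the analytic ALPS index of a hemisphere can be dialled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "REGION_LABELS",
    "TissueTensorSpec",
    "PhantomLayout",
    "DWIVolume",
    "InvalidTargetError",
    "LayoutError",
    "alps_to_tensors",
    "analytic_alps",
    "default_layout",
    "build_phantom",
    "simulate_dwi",
    "DEFAULT_LAMBDA_PERP",
    "DEFAULT_LAMBDA_PAR",
    "CSF_DIFFUSIVITY",
]

# Typical white-matter single-tensor diffusivities (mm²/s): transverse
# and fibre-parallel. Per-subject ALPS variation enters only through the
# x-axis diffusivity of the projection/association regions.
DEFAULT_LAMBDA_PERP = 0.3e-3
DEFAULT_LAMBDA_PAR = 1.4e-3
CSF_DIFFUSIVITY = 3.0e-3  # free-water, isotropic

REGIONS = ("projection", "association", "subcortical", "csf", "background")
_AXES = {"x": 0, "y": 1, "z": 2}

# integer codes in the label volume
REGION_LABELS: dict[str, int] = {
    "background": 0,
    "csf": 1,
    "projection_left": 2,
    "association_left": 3,
    "subcortical_left": 4,
    "projection_right": 5,
    "association_right": 6,
    "subcortical_right": 7,
}


class InvalidTargetError(ValueError):
    """The requested ALPS value cannot be realised by a valid tensor pair."""


class LayoutError(ValueError):
    """The phantom layout references an undefined or missing region."""


@dataclass(frozen=True)
class TissueTensorSpec:
    """Axis-aligned diagonal tensor for one tissue region.

    ``eigenvalues`` are the diffusivities (λx, λy, λz) along the world
    x/y/z axes in mm²/s; ``principal_axis`` names the fibre direction.
    """

    region: str
    eigenvalues: tuple[float, float, float]
    principal_axis: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.principal_axis not in _AXES:
            raise ValueError(f"principal_axis must be x/y/z, got {self.principal_axis!r}")
        if any(ev <= 0 for ev in self.eigenvalues):
            raise ValueError("all eigenvalues must be positive")
        if self.region == "projection" and self.principal_axis != "z":
            raise ValueError("projection fibres must have principal_axis 'z'")
        if self.region == "association" and self.principal_axis != "y":
            raise ValueError("association fibres must have principal_axis 'y'")

    @property
    def lambda_x(self) -> float:
        return self.eigenvalues[0]

    @property
    def lambda_y(self) -> float:
        return self.eigenvalues[1]

    @property
    def lambda_z(self) -> float:
        return self.eigenvalues[2]


def alps_to_tensors(
    target_alps: float,
    baseline: float = DEFAULT_LAMBDA_PERP,
    parallel: float = DEFAULT_LAMBDA_PAR,
) -> tuple[TissueTensorSpec, TissueTensorSpec]:
    """Invert the ALPS formula: tensors whose analytic index equals the target.

    Sets λx of both fibre regions to ``target_alps·baseline`` and keeps the
    other transverse eigenvalue at ``baseline`` and the fibre-parallel one at
    ``parallel``, so that

        ALPS = mean(λx_proj, λx_assoc) / mean(λy_proj, λz_assoc) = target_alps.

    Raises :class:`InvalidTargetError` when ``target_alps·baseline`` would
    reach the fibre-parallel diffusivity (the x-axis must stay transverse).
    """
    if target_alps <= 0:
        raise InvalidTargetError("target ALPS must be positive")
    lam_x = target_alps * baseline
    if lam_x >= parallel:
        raise InvalidTargetError(
            f"target ALPS {target_alps} needs λx = {lam_x:.3e} mm²/s, which is "
            f"not below the fibre-parallel diffusivity {parallel:.3e}; the "
            f"realisable bound is target < {parallel / baseline:.4g}"
        )
    proj = TissueTensorSpec("projection", (lam_x, baseline, parallel), "z")
    assoc = TissueTensorSpec("association", (lam_x, parallel, baseline), "y")
    return proj, assoc


def analytic_alps(proj: TissueTensorSpec, assoc: TissueTensorSpec) -> float:
    """Closed-form ALPS index of a projection/association tensor pair."""
    num = 0.5 * (proj.lambda_x + assoc.lambda_x)
    den = 0.5 * (proj.lambda_y + assoc.lambda_z)
    return num / den


@dataclass(frozen=True)
class PhantomLayout:
    """Voxel grid, affine and region label map of one phantom.

    The label map uses :data:`REGION_LABELS`. The affine is RAS with the
    world origin at the grid centre, so hemispheres mirror about the
    world plane x = 0 (voxel index i ↔ nx−1−i).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.shape != self.shape:
            raise LayoutError("label map shape does not match grid shape")
        present = set(np.unique(self.labels))
        for name in (
            "projection_left", "association_left", "subcortical_left",
            "projection_right", "association_right", "subcortical_right",
        ):
            if REGION_LABELS[name] not in present:
                raise LayoutError(f"layout is missing region {name!r}")

    @property
    def mirror_index(self) -> float:
        """x voxel index of the mid-sagittal mirror plane."""
        return (self.shape[0] - 1) / 2.0


# Block extents as fractions of the grid, chosen so that left/right blocks
# are exact voxel mirrors (right = nx−b .. nx−a) and blocks never touch.
_X_BLOCKS = {  # left-hemisphere x extents; csf straddles the midline
    "subcortical": (4 / 64, 10 / 64),
    "association": (12 / 64, 18 / 64),
    "projection": (20 / 64, 26 / 64),
    "csf": (28 / 64, 36 / 64),
}
_Y_FIBER = (28 / 64, 34 / 64)
_Y_CSF = (24 / 64, 40 / 64)
_Z_BAND = (6 / 16, 10 / 16)


def _span(frac: tuple[float, float], n: int) -> tuple[int, int]:
    a = int(round(frac[0] * n))
    b = max(a + 1, int(round(frac[1] * n)))
    return a, b


def default_layout(
    shape: tuple[int, int, int] = (64, 64, 16),
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 2.5),
) -> PhantomLayout:
    """Build the standard mirror-symmetric slab layout.

    Defaults match the emulated acquisition: 1.875 mm in-plane (240 mm
    FOV / 128 matrix) and 2.5 mm slices, on a cropped 64×64×16 grid.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    z0, z1 = _span(_Z_BAND, nz)

    yc0, yc1 = _span(_Y_CSF, ny)
    xc0, xc1 = _span(_X_BLOCKS["csf"], nx)
    labels[xc0:xc1, yc0:yc1, z0:z1] = REGION_LABELS["csf"]

    yf0, yf1 = _span(_Y_FIBER, ny)
    for region in ("projection", "association", "subcortical"):
        a, b = _span(_X_BLOCKS[region], nx)
        labels[a:b, yf0:yf1, z0:z1] = REGION_LABELS[f"{region}_left"]
        labels[nx - b : nx - a, yf0:yf1, z0:z1] = REGION_LABELS[f"{region}_right"]

    dx, dy, dz = voxel_size
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz]
    return PhantomLayout(shape=shape, voxel_size=voxel_size, affine=affine, labels=labels)


def _diag_tensor(lx: float, ly: float, lz: float) -> np.ndarray:
    # symmetric-tensor storage order: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    return np.array([lx, ly, lz, 0.0, 0.0, 0.0])


def build_phantom(
    layout: PhantomLayout,
    specs: Mapping[str, TissueTensorSpec],
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise region tensor specs into per-voxel tensors and an S0 map.

    ``specs`` maps label names (e.g. ``"projection_left"``) to tensor specs;
    every fibre-region label present in the layout must be covered. CSF
    voxels get an isotropic free-water tensor; background has S0 = 0.

    Returns ``(tensors, s0)`` with ``tensors`` of shape ``shape + (6,)`` in
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) order and ``s0`` of shape ``shape``.
    """
    tensors = np.zeros(layout.shape + (6,), dtype=float)
    s0 = np.zeros(layout.shape, dtype=float)

    csf_mask = layout.labels == REGION_LABELS["csf"]
    tensors[csf_mask] = _diag_tensor(CSF_DIFFUSIVITY, CSF_DIFFUSIVITY, CSF_DIFFUSIVITY)
    s0[csf_mask] = 1.0

    for name, code in REGION_LABELS.items():
        if name in ("background", "csf"):
            continue
        mask = layout.labels == code
        if not mask.any():
            continue
        if name not in specs:
            raise LayoutError(f"no tensor spec provided for region {name!r}")
        spec = specs[name]
        tensors[mask] = _diag_tensor(*spec.eigenvalues)
        s0[mask] = 1.0
    return tensors, s0


@dataclass(frozen=True)
class DWIVolume:
    """A 4-D diffusion-weighted signal with its affine and scheme."""

    data: np.ndarray  # (nx, ny, nz, n_volumes)
    affine: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] != len(self.scheme):
            raise ValueError("data must be 4-D with one volume per scheme entry")


def _quadratic_form(tensors: np.ndarray, g: np.ndarray) -> np.ndarray:
    """gᵀDg per voxel for one direction g, with D in 6-component storage."""
    gx, gy, gz = g
    return (
        tensors[..., 0] * gx * gx
        + tensors[..., 1] * gy * gy
        + tensors[..., 2] * gz * gz
        + 2 * tensors[..., 3] * gx * gy
        + 2 * tensors[..., 4] * gx * gz
        + 2 * tensors[..., 5] * gy * gz
    )


def simulate_dwi(
    tensors: np.ndarray,
    s0: np.ndarray,
    scheme: AcquisitionScheme,
    affine: np.ndarray,
    snr: float = np.inf,
    seed: int | np.random.SeedSequence | None = None,
) -> DWIVolume:
    """Simulate magnitude DWI from the single-tensor model S = S0·exp(−b·gᵀDg).

    Rician noise is applied as the magnitude of (S + ε₁, ε₂) with
    ε ~ N(0, σ) and σ = S0_ref / snr, where S0_ref is the mean S0 over
    tissue voxels. ``snr = inf`` yields the noiseless signal. Fully
    seeded and reproducible.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    n_vol = len(scheme)
    signal = np.empty(tensors.shape[:3] + (n_vol,), dtype=float)
    for k in range(n_vol):
        b = scheme.bvals[k]
        if b == 0:
            signal[..., k] = s0
        else:
            signal[..., k] = s0 * np.exp(-b * _quadratic_form(tensors, scheme.bvecs[k]))
    if np.isfinite(snr):
        tissue = s0 > 0
        s0_ref = float(s0[tissue].mean()) if tissue.any() else 1.0
        sigma = s0_ref / snr
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, sigma, size=signal.shape)
        e2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.hypot(signal + e1, e2)
    return DWIVolume(data=signal, affine=np.array(affine, dtype=float), scheme=scheme)
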