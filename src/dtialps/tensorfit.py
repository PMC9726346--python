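"""Per-voxel diffusion-tensor estimation and derived scalar maps.

The fit is the standard log-linear model: for volume i with b-value b and
unit gradient g,

    log S_i = −b (gx²·Dxx + gy²·Dyy + gz²·Dzz
              + 2gxgy·Dxy + 2gxgz·Dxz + 2gygz·Dyz) + log S0,

solved per voxel by ordinary least squares followed by one weighted
refinement pass with weights equal to the predicted squared signal (the
first-order variance correction for log-transformed Rician/Gaussian
magnitude data). Eigenvalues are sorted descending; negative eigenvalues
are clamped to zero and the voxel flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIVolume
from .scheme import AcquisitionScheme

__all__ = [
    "TensorField",
    "FitError",
    "UnsupportedOrientationError",
    "design_matrix",
    "fit_tensor",
    "axis_diffusivities",
    "color_fa",
    "fractional_anisotropy",
]


class FitError(ValueError):
    """The tensor fit cannot be performed (rank-deficient design, empty mask)."""


class UnsupportedOrientationError(ValueError):
    """The volume affine is oblique; axis diffusivities are undefined."""


@dataclass(frozen=True)
class TensorField:
    """Fitted per-voxel tensors with eigensystem and scalar maps.

    ``tensor`` stores (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm²/s.
    ``evals`` are sorted descending (λ1 ≥ λ2 ≥ λ3, clamped ≥ 0);
    ``evecs[..., :, j]`` is the eigenvector of λ_{j+1}. ``flags`` marks
    voxels where the signal was floored before the log or an eigenvalue
    was clamped; such voxels are excluded from downstream ROI means.
    """

    tensor: np.ndarray  # (..., 6)
    evals: np.ndarray  # (..., 3)
    evecs: np.ndarray  # (..., 3, 3)
    fa: np.ndarray
    md: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    flags: np.ndarray
    affine: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        return self.evecs[..., :, 0]


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes, 7) design: log S = X · (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0)."""
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
            np.ones_like(b),
        ]
    )


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues: √(3/2)·‖λ − λ̄‖ / ‖λ‖, zero where ‖λ‖ = 0."""
    ev = np.asarray(evals, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((ev - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(ev**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


_SIGNAL_FLOOR_FACTOR = 1e-8  # ε = factor · S0_ref, applied before the log


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Fit the diffusion tensor in every masked voxel.

    ``mask`` defaults to voxels with positive mean b0 signal. Requires a
    rank-7 design (≥ 7 volumes with ≥ 6 independent directions plus b0).
    """
    X = design_matrix(dwi.scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise FitError("design matrix is rank deficient; need >= 6 independent "
                       "gradient directions plus a b0")
    data = dwi.data
    b0_mean = data[..., dwi.scheme.b0_mask].mean(axis=-1)
    if mask is None:
        mask = b0_mean > 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise FitError("mask shape does not match volume grid")
    if not mask.any():
        raise FitError("empty fit mask")

    y_raw = data[mask]  # (m, n)
    s0_ref = float(b0_mean[mask].mean())
    floor = _SIGNAL_FLOOR_FACTOR * max(s0_ref, np.finfo(float).tiny)
    floored = (y_raw < floor).any(axis=1)
    y = np.log(np.maximum(y_raw, floor))

    # OLS
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, m)
    beta = beta.T

    # one WLS pass, weights = predicted squared signal
    pred = np.exp(beta @ X.T)  # (m, n)
    w = pred**2
    Xw = np.einsum("mn,ni,nj->mij", w, X, X)  # (m, 7, 7)
    yw = np.einsum("mn,ni,mn->mi", w, X, y)  # (m, 7)
    try:
        beta = np.linalg.solve(Xw, yw[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # degenerate weights in isolated voxels: keep the OLS solution there
        ok = np.linalg.matrix_rank(Xw) == 7
        beta[ok] = np.linalg.solve(Xw[ok], yw[ok][..., None])[..., 0]

    m = beta.shape[0]
    D = np.empty((m, 3, 3))
    D[:, 0, 0] = beta[:, 0]
    D[:, 1, 1] = beta[:, 1]
    D[:, 2, 2] = beta[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 5]

    evals_asc, evecs_asc = np.linalg.eigh(D)
    evals_v = evals_asc[:, ::-1]  # descending
    evecs_v = evecs_asc[:, :, ::-1]
    clamped = (evals_v < 0).any(axis=1)
    evals_v = np.clip(evals_v, 0.0, None)

    shape = data.shape[:3]
    tensor = np.zeros(shape + (6,))
    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    fa = np.zeros(shape)
    md = np.zeros(shape)
    s0 = np.zeros(shape)
    flags = np.zeros(shape, dtype=bool)

    tensor[mask] = beta[:, :6]
    evals[mask] = evals_v
    evecs[mask] = evecs_v
    fa[mask] = fractional_anisotropy(evals_v)
    md[mask] = evals_v.mean(axis=1)
    s0[mask] = np.exp(beta[:, 6])
    flags[mask] = floored | clamped

    return TensorField(
        tensor=tensor, evals=evals, evecs=evecs, fa=fa, md=md, s0=s0,
        mask=mask, flags=flags, affine=np.array(dwi.affine, dtype=float),
    )


def _rotation_part(affine: np.ndarray) -> np.ndarray:
    R = np.asarray(affine, dtype=float)[:3, :3]
    return R / np.linalg.norm(R, axis=0, keepdims=True)


def axis_diffusivities(field: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusivity along the world x, y, z axes: the tensor's diagonal.

    Tensors are stored in the world (RAS) frame, valid when the affine's
    rotation part is axis-aligned (a signed axis permutation). An oblique
    affine raises :class:`UnsupportedOrientationError`.
    """
    A = np.abs(_rotation_part(field.affine))
    perm = A > 0.5
    axis_aligned = (
        perm.sum(axis=0).tolist() == [1, 1, 1]
        and perm.sum(axis=1).tolist() == [1, 1, 1]
        and np.allclose(A[perm], 1.0, atol=1e-6)
        and np.allclose(A[~perm], 0.0, atol=1e-6)
    )
    if not axis_aligned:
        raise UnsupportedOrientationError(
            "affine rotation is oblique; axis diffusivities are defined only "
            "for axis-aligned volumes"
        )
    return field.tensor[..., 0], field.tensor[..., 1], field.tensor[..., 2]


def color_fa(field: TensorField) -> np.ndarray:
    """Directionally colour-coded FA: RGB = FA·|e1| with (R,G,B) = (|x|,|y|,|z|).

    Projection fibres (z principal) appear blue, association fibres (y
    principal) green, perivascular-aligned tissue (x) red.
    """
    rgb = field.fa[..., None] * np.abs(field.principal_direction)
    return np.clip(rgb, 0.0, 1.0)
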