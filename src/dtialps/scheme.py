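"""Diffusion acquisition schemes and FSL-style gradient-table I/O.

The default scheme reproduces a single-shell paediatric DTI protocol:
8 interleaved b = 0 volumes followed by 30 unique gradient directions at
b = 600 s/mm². Directions are placed by a deterministic spherical
Fibonacci lattice so the scheme is reproducible bit-for-bit without an
electrostatic-repulsion optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "build_default_scheme",
    "fibonacci_directions",
    "read_bval_bvec",
    "write_bval_bvec",
]

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm²) and unit gradient directions.

    ``bvals`` has shape (n,), ``bvecs`` shape (n, 3). A zero direction is
    permitted only on b = 0 volumes; every nonzero direction must be unit
    norm to within 1e-8.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape != (bvecs.shape[0],):
            raise ValueError(
                f"bvals length {bvals.shape} does not match bvecs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero = bvals > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > _UNIT_TOL):
            raise ValueError("every nonzero-b gradient direction must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` unit vectors on the sphere via the Fibonacci (golden-angle) lattice.

    Deterministic and near-uniform; adjacent points are separated by
    roughly the mean nearest-neighbour angle of an optimal packing.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    vecs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def build_default_scheme() -> AcquisitionScheme:
    """The default 38-volume scheme: 8 × b0 then 30 × b = 600 s/mm²."""
    n_b0, n_dir, b = 8, 30, 600.0
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dir, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_dir)])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-style gradient tables: one row of b-values; three rows x/y/z."""
    Path(bval_path).write_text(
        " ".join(f"{b:g}" for b in scheme.bvals) + "\n", encoding="utf-8"
    )
    rows = []
    for axis in range(3):
        rows.append(" ".join(f"{v:.10f}" for v in scheme.bvecs[:, axis]))
    Path(bvec_path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_bval_bvec(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-style .bval/.bvec files into an :class:`AcquisitionScheme`."""
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float)
    bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is rows = axes
        bvecs = bvecs.T
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)
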