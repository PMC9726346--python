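import numpy as np
import pytest

from dtialps.cohort import SubjectGroundTruth
from dtialps.phantom import (
    DEFAULT_LAMBDA_PAR,
    DEFAULT_LAMBDA_PERP,
    TissueTensorSpec,
    alps_to_tensors,
    default_layout,
)
from dtialps.scheme import build_default_scheme
from dtialps.tensorfit import TensorField


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_layout():
    return default_layout((16, 16, 16))


def make_subject(
    alps_left: float,
    alps_right: float,
    subject_id: str = "sub-001",
    group: str = "ASD",
    seed: int = 1,
) -> SubjectGroundTruth:
    """A subject with exactly known per-hemisphere ALPS."""
    specs = {}
    for h, t in (("left", alps_left), ("right", alps_right)):
        proj, assoc = alps_to_tensors(t)
        specs[f"projection_{h}"] = proj
        specs[f"association_{h}"] = assoc
        specs[f"subcortical_{h}"] = TissueTensorSpec(
            "subcortical", (DEFAULT_LAMBDA_PERP, DEFAULT_LAMBDA_PAR, DEFAULT_LAMBDA_PERP), "y"
        )
    return SubjectGroundTruth(
        subject_id=subject_id, group=group, age_months=48.0, ga_weeks=39.5,
        sex="male", alps_true={"left": alps_left, "right": alps_right},
        specs=specs, seed=seed,
    )


def field_from_diag(dxx, dyy, dzz, affine, flags=None, mask=None) -> TensorField:
    """Build a TensorField directly from diagonal diffusivity maps."""
    dxx = np.asarray(dxx, float)
    shape = dxx.shape
    tensor = np.zeros(shape + (6,))
    tensor[..., 0] = dxx
    tensor[..., 1] = dyy
    tensor[..., 2] = dzz
    evals = np.sort(tensor[..., :3], axis=-1)[..., ::-1]
    evecs = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    from dtialps.tensorfit import fractional_anisotropy

    fa = fractional_anisotropy(evals)
    md = evals.mean(axis=-1)
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    flags = np.zeros(shape, bool) if flags is None else np.asarray(flags, bool)
    return TensorField(
        tensor=tensor, evals=evals, evecs=evecs, fa=fa, md=md,
        s0=np.ones(shape), mask=mask, flags=flags,
        affine=np.asarray(affine, float),
    )
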