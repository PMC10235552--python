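"""Shared fixtures: small phantoms and hard-label probability sets."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resectmorph.phantom import (
    PhantomSpec,
    ResectionSpec,
    generate_phantom,
    tissue_priors,
)
from resectmorph.volumes import ImageVolume, Tissue, TissueProbabilitySet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def hard_probability_set(labels: np.ndarray, affine=None) -> TissueProbabilitySet:
    """One-hot probability maps from an integer tissue label volume."""
    affine = np.eye(4) if affine is None else affine
    present = [t for t in Tissue if (labels == t).any()]
    maps = {t.name: (labels == t).astype(np.float32) for t in present}
    return TissueProbabilitySet(maps=maps, affine=affine, brain_mask=labels > 0)


def shell_labels(h: float, r_in: float = 8.0, r_out: float = 11.0, extent: float = 30.0):
    """Spherical GM shell (WM core, CSF outside) voxelized at spacing h."""
    n = int(np.ceil(extent / h))
    ax = (np.arange(n) - (n - 1) / 2) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    lab = np.full((n, n, n), Tissue.CSF, dtype=np.int8)
    lab[r < r_out] = Tissue.GM
    lab[r < r_in] = Tissue.WM
    return lab, np.diag([h, h, h, 1.0])


@pytest.fixture(scope="session")
def atl_phantom():
    """48^3 ATL-like phantom pair with noise at class SNR 5."""
    spec = PhantomSpec(
        shape=(48, 48, 48),
        resection=ResectionSpec(kind="ATL", side="R"),
        noise_sigma=6.0,
        seed=7,
    )
    pre, post, truth = generate_phantom(spec)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def atl_priors(atl_phantom):
    _, _, _, truth = atl_phantom
    return tissue_priors(truth)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 48^3 phantom without resection."""
    spec = PhantomSpec(shape=(48, 48, 48), noise_sigma=0.0, seed=3)
    pre, post, truth = generate_phantom(spec)
    return spec, pre, post, truth
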