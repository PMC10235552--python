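"""Registration parameter recovery, mask resampling, SST imputation."""

import numpy as np
import pytest

from resectmorph.phantom import PhantomSpec, generate_phantom
from resectmorph.resection import ResectionMask
from resectmorph.spatial import (
    AffineTransform,
    RigidTransform,
    build_sst,
    load_transform,
    register_affine,
    register_rigid,
    resample_mask,
    resample_volume,
)
from resectmorph.volumes import GridMismatchError, ImageVolume


@pytest.fixture(scope="module")
def fixed_clean():
    pre, _, _ = generate_phantom(PhantomSpec(shape=(64, 64, 64), noise_sigma=0.0, seed=5))
    return pre


def test_identity_registration(fixed_clean):
    tfm = register_rigid(fixed_clean, fixed_clean)
    assert np.abs(tfm.translation).max() < 0.1
    assert np.rad2deg(np.abs(tfm.rotation)).max() < 0.1


def test_translation_recovery_under_noise():
    pre, _, _ = generate_phantom(PhantomSpec(shape=(48, 48, 48), noise_sigma=3.0, seed=5))
    _, mov, _ = generate_phantom(
        PhantomSpec(shape=(48, 48, 48), noise_sigma=3.0, seed=7,
                    rigid_offset=(0, 0, 0, 2.0, 0, 0))
    )
    tfm = register_rigid(pre, mov)
    # content shifted by +2 voxels -> recovered map is the inverse
    assert abs(tfm.translation[0] - (-2.0)) < 0.5
    assert np.abs(tfm.translation[1:]).max() < 0.5


def test_rotation_recovery(fixed_clean):
    _, mov, _ = generate_phantom(
        PhantomSpec(shape=(64, 64, 64), noise_sigma=0.0, seed=5,
                    rigid_offset=(3.0, 0, 0, 0, 0, 0))
    )
    tfm = register_rigid(fixed_clean, mov)
    assert abs(np.rad2deg(tfm.rotation[0]) - (-3.0)) < 0.5
    assert np.rad2deg(np.abs(tfm.rotation[1:])).max() < 0.5


def test_affine_scale_recovery(fixed_clean):
    c = np.array([31.5] * 3)
    S = np.eye(4)
    S[:3, :3] *= 1.1
    S[:3, 3] = c - 1.1 * c
    mov = resample_volume(fixed_clean, AffineTransform(S), fixed_clean)
    tfm = register_affine(fixed_clean, mov)
    recovered_scale = np.diag(tfm.matrix[:3, :3])
    np.testing.assert_allclose(recovered_scale, 1 / 1.1, rtol=0.02)


def test_affine_shear_translation_recovery():
    # smoothed random field: structure at every orientation, so the shear
    # cannot trade off against a rotation as it can on the nearly
    # spherically symmetric head phantom
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(12)
    data = gaussian_filter(rng.normal(size=(64, 64, 64)), 3.0) * 100.0
    ax = np.arange(64) - 31.5
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    data *= np.exp(-((r / 22.0) ** 6))  # taper to zero well inside the grid
    field = ImageVolume(data.astype(np.float32), np.eye(4))
    c = np.array([31.5] * 3)
    A = np.eye(4)
    A[0, 1] = 0.05  # shear
    A[:3, 3] = np.array([1.5, -1.0, 0.5]) + c - A[:3, :3] @ c
    mov = resample_volume(field, AffineTransform(A), field)
    tfm = register_affine(field, mov)
    # recovered composed with applied should be identity: check mean voxel
    # displacement of the composition over the head region
    comp = A @ tfm.matrix
    pts = np.mgrid[8:40:4, 8:40:4, 8:40:4].reshape(3, -1).T.astype(float)
    moved = pts @ comp[:3, :3].T + comp[:3, 3]
    disp = np.linalg.norm(moved - pts, axis=1)
    assert disp.mean() < 0.5


def test_transform_round_trip_and_serialization(tmp_path):
    tfm = RigidTransform(
        rotation=(0.02, -0.01, 0.03), translation=(1.0, -2.0, 0.5),
        center=(24.0, 24.0, 24.0),
    )
    pts = np.random.default_rng(0).uniform(0, 48, size=(50, 3))
    back = tfm.inverse().apply(tfm.apply(pts))
    assert np.abs(back - pts).max() < 1e-3

    tfm.to_json(tmp_path / "t.json")
    loaded = load_transform(tmp_path / "t.json")
    np.testing.assert_allclose(loaded.matrix, tfm.matrix, atol=1e-12)


def test_mask_resampling_identity_and_translation():
    mask = np.zeros((20, 20, 20), bool)
    mask[8:12, 8:12, 8:12] = True
    rm = ResectionMask(mask, np.eye(4))
    target = ImageVolume(np.zeros((20, 20, 20)), np.eye(4))

    ident = resample_mask(rm, RigidTransform((0, 0, 0), (0, 0, 0)), target)
    np.testing.assert_array_equal(ident.mask, mask)

    shifted = resample_mask(rm, RigidTransform((0, 0, 0), (1.0, 0, 0)), target)
    assert shifted.n_voxels == rm.n_voxels  # interior block: count preserved

    far = resample_mask(rm, RigidTransform((0, 0, 0), (15.0, 0, 0)), target)
    assert far.n_voxels < rm.n_voxels  # clipped at the grid boundary


def test_sst_imputation_is_exact():
    rng = np.random.default_rng(3)
    pre = ImageVolume(rng.normal(100, 10, (16, 16, 16)), np.eye(4))
    post = ImageVolume(rng.normal(100, 10, (16, 16, 16)), np.eye(4))
    mask = np.zeros((16, 16, 16), bool)
    mask[4:8, 4:8, 4:8] = True
    sst = build_sst(pre, post, ResectionMask(mask, np.eye(4)))
    np.testing.assert_array_equal(sst.data[mask], pre.data[mask])
    outside = ~mask
    np.testing.assert_array_equal(
        sst.data[outside], ((pre.data + post.data) / 2.0)[outside]
    )

    empty = build_sst(pre, post, ResectionMask(np.zeros((16, 16, 16), bool), np.eye(4)))
    np.testing.assert_array_equal(empty.data, (pre.data + post.data) / 2.0)


def test_sst_rejects_grid_mismatch():
    pre = ImageVolume(np.zeros((8, 8, 8)), np.eye(4))
    post = ImageVolume(np.zeros((8, 8, 9)), np.eye(4))
    with pytest.raises(GridMismatchError):
        build_sst(pre, post, ResectionMask(np.zeros((8, 8, 8), bool), np.eye(4)))


def test_sst_restores_cavity_intensity(atl_phantom):
    """Inside the true cavity the SST matches preoperative tissue, not the
    depressed pre/post average."""
    _, pre, post, truth = atl_phantom
    mask = ResectionMask(truth.resection_mask, truth.affine)
    sst = build_sst(pre, post, mask)
    plain = (np.asarray(pre.data, float) + np.asarray(post.data, float)) / 2
    cav = truth.resection_mask
    mean_pre = np.asarray(pre.data, float)[cav].mean()
    assert abs(np.asarray(sst.data)[cav].mean() - mean_pre) < 1e-9
    assert plain[cav].mean() < mean_pre - 10  # averaging dims the cavity
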