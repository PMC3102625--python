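"""Background-offset fitting and VENC phase unwrapping."""

import numpy as np
import pytest

from voltrack import (
    GridGeometry,
    TimeAxis,
    VelocityField,
    default_phantom_spec,
    detect_stationary,
    fit_background,
    generate_field,
    subtract_background,
    unwrap_velocity,
)
from voltrack.errors import DegenerateGeometryError, DiagnosticError


def make_field(data, spacing=3.0, origin=(0.0, 0.0, 0.0), venc=1.0):
    shape = data.shape[2:]
    grid = GridGeometry(shape=shape, spacing=(spacing,) * 3, origin=origin)
    times = TimeAxis(times=np.arange(data.shape[0]) * 0.05)
    return VelocityField(grid=grid, time=times, data=data, venc=venc)


# ----------------------------------------------------------------------------
# stationary-tissue detection
# ----------------------------------------------------------------------------


def test_stationary_mask_excludes_a_moving_jet():
    data = np.zeros((5, 3, 16, 16, 16))
    jet = np.zeros((16, 16, 16), bool)
    jet[6:10, 6:10, :] = True
    for k in range(5):
        data[k, 2][jet] = 0.4 * np.sin(np.pi * (k + 1) / 6)
    field = make_field(data)
    mask = detect_stationary(field, threshold=0.03)
    assert (mask == ~jet).all()


def test_stationary_recall_is_perfect_at_three_sigma():
    rng = np.random.default_rng(42)
    sigma = 0.005
    data = rng.normal(0, sigma, (11, 3, 16, 16, 16))
    jet = np.zeros((16, 16, 16), bool)
    jet[6:10, 6:10, :] = True
    for k in range(11):
        data[k, 2][jet] += 0.5 * np.sin(np.pi * k / 10)
    field = make_field(data)
    mask = detect_stationary(field, threshold=3 * sigma)
    static = ~jet
    assert (mask & static).sum() == static.sum()  # 100% recall of static voxels
    assert not (mask & jet).any()


def test_all_noise_field_gives_empty_mask_error():
    rng = np.random.default_rng(0)
    data = rng.normal(0, 0.5, (4, 3, 8, 8, 8))  # sigma >> threshold
    with pytest.raises(DiagnosticError):
        detect_stationary(make_field(data), threshold=0.01)


# ----------------------------------------------------------------------------
# background fit
# ----------------------------------------------------------------------------


def linear_background_field(bg, shape=(16, 16, 16), n_frames=3, noise=0.0, seed=0):
    grid = GridGeometry(shape=shape, spacing=(3.0,) * 3)
    xyz = grid.voxel_centers()
    rng = np.random.default_rng(seed)
    data = np.zeros((n_frames, 3) + shape)
    for c in range(3):
        data[:, c] += bg[c, 0] + bg[c, 1] * xyz[0] + bg[c, 2] * xyz[1] + bg[c, 3] * xyz[2]
    if noise:
        data += rng.normal(0, noise, data.shape)
    times = TimeAxis(times=np.arange(n_frames) * 0.05)
    return VelocityField(grid=grid, time=times, data=data, venc=1.0)


BG = np.array([[0.02, 0.001, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [-0.01, 0.0, 2e-4, -5e-4]])


def test_zero_velocities_fit_zero_coefficients():
    field = linear_background_field(np.zeros((3, 4)))
    model = fit_background(field, np.ones(field.grid.shape, bool))
    assert np.abs(model.coefficients).max() == 0.0
    assert (model.residual_rms == 0).all()


def test_noise_free_fit_matches_normal_equations_oracle():
    field = linear_background_field(BG)
    mask = np.ones(field.grid.shape, bool)
    model = fit_background(field, mask)
    np.testing.assert_allclose(model.coefficients, np.broadcast_to(BG, (3, 3, 4)), atol=1e-10)
    # independent closed-form oracle: beta = (X'X)^-1 X'y
    xyz = field.grid.voxel_centers()
    X = np.column_stack([np.ones(mask.sum()), xyz[0][mask], xyz[1][mask], xyz[2][mask]])
    beta = np.linalg.solve(X.T @ X, X.T @ field.data[0, 0][mask])
    np.testing.assert_allclose(model.coefficients[0, 0], beta, atol=1e-12)


def test_noisy_fit_within_four_standard_errors():
    sigma = 0.01
    field = linear_background_field(BG, noise=sigma, seed=7)
    rng = np.random.default_rng(3)
    mask = np.zeros(field.grid.shape, bool)
    flat = rng.choice(mask.size, 500, replace=False)
    mask.ravel()[flat] = True
    model = fit_background(field, mask)
    xyz = field.grid.voxel_centers()
    X = np.column_stack([np.ones(500), xyz[0][mask], xyz[1][mask], xyz[2][mask]])
    se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))  # OLS sampling SD
    err = np.abs(model.coefficients - BG[None])
    assert (err <= 4 * se).all()


def test_coplanar_mask_raises_degenerate_geometry():
    field = linear_background_field(BG)
    mask = np.zeros(field.grid.shape, bool)
    mask[:, :, 5] = True  # all voxels share one z-plane
    with pytest.raises(DegenerateGeometryError):
        fit_background(field, mask)


def test_subtracting_the_fit_zeroes_a_pure_polynomial_field():
    field = linear_background_field(BG)
    model = fit_background(field, np.ones(field.grid.shape, bool))
    corrected = subtract_background(field, model)
    assert np.abs(corrected.data).max() <= 1e-10


def test_zero_model_leaves_field_unchanged():
    field = linear_background_field(BG)
    model = fit_background(linear_background_field(np.zeros((3, 4))), np.ones(field.grid.shape, bool))
    corrected = subtract_background(field, model)
    np.testing.assert_array_equal(corrected.data, field.data)


def test_fit_is_equivariant_under_origin_translation():
    """Predicted background at fixed world points is origin-independent."""
    field_a = linear_background_field(BG)
    grid_b = GridGeometry(shape=field_a.grid.shape, spacing=field_a.grid.spacing,
                          origin=(-30.0, 12.0, 7.0))
    field_b = VelocityField(grid=grid_b, time=field_a.time,
                            data=np.empty_like(field_a.data), venc=1.0)
    xyz_b = grid_b.voxel_centers()
    for c in range(3):
        field_b.data[:, c] = (BG[c, 0] + BG[c, 1] * xyz_b[0]
                              + BG[c, 2] * xyz_b[1] + BG[c, 3] * xyz_b[2])
    mask = np.ones(field_a.grid.shape, bool)
    ma = fit_background(field_a, mask)
    mb = fit_background(field_b, mask)
    np.testing.assert_allclose(ma.coefficients, mb.coefficients, atol=1e-10)


# ----------------------------------------------------------------------------
# phase unwrapping
# ----------------------------------------------------------------------------


def test_unwrapped_field_without_aliasing_is_unchanged():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(1)
    # smooth in space and time: physical fields vary slowly on the voxel/frame scale
    data = gaussian_filter(rng.normal(size=(4, 3, 10, 10, 10)), sigma=1.5, axes=(0, 2, 3, 4))
    data *= 0.9 / np.abs(data).max()  # smooth field spanning (-venc, venc)
    field = make_field(data, venc=1.0)
    out, rep = unwrap_velocity(field)
    assert rep.n_corrected == 0
    np.testing.assert_array_equal(out.data, field.data)


def test_single_wrapped_voxel_amid_fast_neighbors_is_restored():
    """True 1.30 m/s stored as -0.70 m/s amid ~1.2 m/s neighbours (VENC 1)."""
    data = np.full((2, 3, 8, 8, 8), 0.0)
    data[:, 0] = 1.2
    data[:, 0, 4, 4, 4] = 1.30 - 2.0  # wrapped by -2*venc
    field = make_field(data, venc=1.0)
    out, rep = unwrap_velocity(field)
    assert out.data[0, 0, 4, 4, 4] == pytest.approx(1.30, abs=1e-12)
    assert rep.shifts[0, 0, 4, 4, 4] == 1  # one positive 2*venc shift
    assert rep.n_corrected == 2  # both frames


def test_temporal_wrap_detected_against_previous_frame():
    data = np.zeros((3, 3, 6, 6, 6))
    data[0, 0] = 0.9
    data[1, 0] = 1.3  # peak frame; a patch of it aliases
    data[1, 0, 2:4] = 1.3 - 2.0
    data[2, 0] = 0.9
    field = make_field(data, venc=1.0)
    out, _ = unwrap_velocity(field)
    np.testing.assert_allclose(out.data[1, 0], 1.3, atol=1e-12)


def test_phantom_jet_wraps_are_restored_and_congruent():
    spec = default_phantom_spec(n=32, e_peak_speed=1.4, wrap=True,
                                noise_sigma=0.02, seed=3)
    corrupted, truth, meta = generate_field(spec)
    wm = meta["wrapped_mask"]
    assert wm.any()
    venc = spec.venc
    wrapped_truth = np.mod(truth.data + venc, 2 * venc) - venc
    ideal = corrupted.data + (truth.data - wrapped_truth)  # noise kept, wraps undone
    out, rep = unwrap_velocity(corrupted)
    restored = np.abs(out.data - ideal)[wm] < 1e-9
    assert restored.mean() >= 0.99
    # exact congruence: every change is an integer multiple of 2*venc
    k = (out.data - corrupted.data) / (2 * venc)
    np.testing.assert_allclose(k, np.round(k), atol=1e-9)
    assert rep.n_corrected >= wm.sum() * 0.99
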