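"""Volume functions, level-set tracking, surfaces and volume measurement."""

import numpy as np
import pytest

from voltrack import (
    GridGeometry,
    SolverOptions,
    TimeAxis,
    VelocityField,
    compute_flowmap,
    extract_surface,
    make_volume_function,
    measure_volume,
    track_volume,
)
from voltrack.errors import ParameterError
from voltrack.volumes import TrackedVolume, surface_area, write_ply, write_vtk_polydata


def grid_1mm(n=32):
    return GridGeometry(shape=(n, n, n), spacing=(1.0, 1.0, 1.0))


def static_tracked(f, grid):
    """TrackedVolume of f under zero flow (g == f on the grid)."""
    pts = np.moveaxis(grid.voxel_centers(), 0, -1)
    return TrackedVolume(grid=grid, t0=0.0, query_times=np.array([0.0]), g=f(pts)[None], f=f)


# ----------------------------------------------------------------------------
# volume functions
# ----------------------------------------------------------------------------


def test_plane_signed_distance():
    f = make_volume_function("plane", point=(0, 0, 0), normal=(0, 0, 2.0))  # normalized
    assert f(np.array([0.0, 0.0, 5.0])) == pytest.approx(5.0)
    assert f(np.array([3.0, -2.0, 0.0])) == pytest.approx(0.0)


def test_sphere_zero_on_surface_and_box_sign():
    f = make_volume_function("sphere", center=(1.0, 2.0, 3.0), radius=7.0)
    assert f(np.array([8.0, 2.0, 3.0])) == pytest.approx(0.0)
    b = make_volume_function("box", lo=(0, 0, 0), hi=(10, 10, 10))
    assert b(np.array([5.0, 5.0, 5.0])) == pytest.approx(-5.0)
    assert b(np.array([12.0, 5.0, 5.0])) == pytest.approx(2.0)


def test_sampled_function_reproduces_linear_data_exactly():
    grid = grid_1mm(16)
    plane = make_volume_function("plane", point=(7.5, 0, 0), normal=(1, 0, 0))
    pts = np.moveaxis(grid.voxel_centers(), 0, -1)
    sampled = make_volume_function("sampled", values=plane(pts), grid=grid)
    rng = np.random.default_rng(0)
    q = rng.uniform(1, 14, (40, 3))
    np.testing.assert_allclose(sampled(q), plane(q), atol=1e-12)


def test_invalid_parameters_raise():
    with pytest.raises(ParameterError):
        make_volume_function("plane", point=(0, 0, 0), normal=(0, 0, 0))
    with pytest.raises(ParameterError):
        make_volume_function("sphere", center=(0, 0, 0), radius=-1.0)
    with pytest.raises(ParameterError):
        make_volume_function("box", lo=(0, 0, 0), hi=(0, 1, 1))


# ----------------------------------------------------------------------------
# tracking
# ----------------------------------------------------------------------------


def uniform_field(c, n=32, spacing=2.0, t1=1.0):
    grid = GridGeometry(shape=(n, n, n), spacing=(spacing,) * 3)
    times = TimeAxis(times=np.array([0.0, t1]))
    data = np.zeros((2, 3, n, n, n))
    for i in range(3):
        data[:, i] = c[i]
    return VelocityField(grid=grid, time=times, data=data, venc=1.0)


def test_g_equals_f_at_start_time():
    field = uniform_field((0.01, 0.0, 0.0))
    fm = compute_flowmap(field, 0.0, [0.0, 1.0])
    f = make_volume_function("sphere", center=(31.0, 31.0, 31.0), radius=15.0)
    tv = track_volume(fm, f)
    pts = np.moveaxis(field.grid.voxel_centers(), 0, -1)
    np.testing.assert_array_equal(tv.g[0], f(pts))


def test_plane_under_uniform_flow_translates_with_the_flow():
    c = (0.01, 0.0, 0.0)  # 10 mm/s
    field = uniform_field(c)
    fm = compute_flowmap(field, 0.0, [1.0])
    f = make_volume_function("plane", point=(20.0, 31.0, 31.0), normal=(1, 0, 0))
    tv = track_volume(fm, f)
    # zero level set at t=1 is the plane translated to x = 30 mm
    rng = np.random.default_rng(2)
    pts = np.column_stack([
        np.full(30, 30.0), rng.uniform(20, 42, 30), rng.uniform(20, 42, 30)
    ])
    vals, _ = tv.sample(pts, 1.0)
    assert np.abs(vals).max() <= 0.25 * field.grid.spacing[0]


def test_sphere_spinning_about_its_own_center_is_invariant():
    n, spacing = 32, 2.0
    grid = GridGeometry(shape=(n, n, n), spacing=(spacing,) * 3)
    center = np.full(3, (n - 1) * spacing / 2.0)
    xyz = grid.voxel_centers()
    omega = np.pi
    data = np.zeros((2, 3, n, n, n))
    data[:, 0] = -omega * (xyz[1] - center[1]) / 1000.0
    data[:, 1] = omega * (xyz[0] - center[0]) / 1000.0
    field = VelocityField(grid=grid, time=TimeAxis(times=np.array([0.0, 0.5])),
                          data=data, venc=1.0)
    fm = compute_flowmap(field, 0.0, [0.5], SolverOptions(scheme="high_resolution"))
    f = make_volume_function("sphere", center=center, radius=14.0)
    tv = track_volume(fm, f)
    pts = np.moveaxis(grid.voxel_centers(), 0, -1)
    q = n // 4
    sl = (slice(q, -q),) * 3
    assert np.abs(tv.g[0] - f(pts))[sl].max() <= 0.5 * spacing


def test_nesting_is_preserved_by_composition():
    """f1 <= f2 pointwise implies V1(t) contains V2(t) at every stored time."""
    field = uniform_field((0.008, -0.004, 0.002))
    fm = compute_flowmap(field, 0.0, [0.0, 0.5, 1.0])
    f1 = make_volume_function("sphere", center=(31.0, 31.0, 31.0), radius=18.0)
    f2 = make_volume_function("sphere", center=(31.0, 31.0, 31.0), radius=12.0)
    tv1, tv2 = track_volume(fm, f1), track_volume(fm, f2)
    for j in range(3):
        inside2 = tv2.g[j] <= 0
        assert (tv1.g[j][inside2] <= 0).all()


# ----------------------------------------------------------------------------
# surfaces
# ----------------------------------------------------------------------------


def test_plane_surface_vertices_and_orientation():
    grid = grid_1mm()
    f = make_volume_function("plane", point=(15.2, 0, 0), normal=(1, 0, 0))
    tv = static_tracked(f, grid)
    verts, faces = extract_surface(tv, 0.0)
    assert len(verts) > 0
    assert np.abs(verts[:, 0] - 15.2).max() <= 0.5  # within half a voxel of the plane
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    normals = np.cross(v1 - v0, v2 - v0)
    # outward = toward g > 0 = +x
    assert (normals[:, 0] > 0).mean() > 0.99


def test_sphere_surface_area_within_five_percent():
    grid = grid_1mm()
    f = make_volume_function("sphere", center=(15.5, 15.5, 15.5), radius=10.0)
    tv = static_tracked(f, grid)
    verts, faces = extract_surface(tv, 0.0)
    area = surface_area(verts, faces)
    assert area == pytest.approx(4 * np.pi * 100.0, rel=0.05)


def test_empty_level_set_gives_empty_mesh():
    grid = grid_1mm(8)
    f = make_volume_function("sphere", center=(100.0, 100.0, 100.0), radius=1.0)
    tv = static_tracked(f, grid)
    verts, faces = extract_surface(tv, 0.0)
    assert len(verts) == 0 and len(faces) == 0


def test_mesh_writers_emit_readable_text(tmp_path):
    grid = grid_1mm(16)
    f = make_volume_function("sphere", center=(7.5, 7.5, 7.5), radius=5.0)
    tv = static_tracked(f, grid)
    verts, faces = extract_surface(tv, 0.0)
    ply = write_ply(verts, faces, tmp_path / "m.ply")
    vtk = write_vtk_polydata(verts, faces, tmp_path / "m.vtk")
    head = (tmp_path / "m.ply").read_text().splitlines()
    assert head[0] == "ply" and f"element vertex {len(verts)}" in head
    assert "POLYGONS" in (tmp_path / "m.vtk").read_text()


# ----------------------------------------------------------------------------
# measurement
# ----------------------------------------------------------------------------


def test_sphere_volume_within_two_percent():
    grid = grid_1mm()
    f = make_volume_function("sphere", center=(15.5, 15.5, 15.5), radius=10.0)
    tv = static_tracked(f, grid)
    assert measure_volume(tv, 0.0) == pytest.approx(4.18879, rel=0.02)


def test_all_positive_g_measures_zero():
    grid = grid_1mm(8)
    f = make_volume_function("sphere", center=(100.0, 100.0, 100.0), radius=1.0)
    tv = static_tracked(f, grid)
    assert measure_volume(tv, 0.0) == 0.0


def test_function_and_complement_partition_the_grid():
    grid = grid_1mm()
    f = make_volume_function("sphere", center=(15.5, 15.5, 15.5), radius=9.0)
    pts = np.moveaxis(grid.voxel_centers(), 0, -1)
    g = f(pts)
    tv_in = TrackedVolume(grid=grid, t0=0.0, query_times=np.array([0.0]), g=g[None])
    tv_out = TrackedVolume(grid=grid, t0=0.0, query_times=np.array([0.0]), g=-g[None])
    total = grid.voxel_volume * np.prod(grid.shape) / 1000.0
    v = measure_volume(tv_in, 0.0) + measure_volume(tv_out, 0.0)
    assert abs(v - total) <= 1e-9
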