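"""Medial curve, thickness, log-Jacobian, and bilateral map computations."""

import numpy as np
import pytest

from shapemeta.mesh_io import SurfaceMesh, vertex_normals
from shapemeta.shape_measures import (
    MeasureError,
    VertexMeasureMap,
    _one_ring_areas,
    _point_to_polyline_distance,
    asymmetry_index,
    compute_log_jacobian,
    compute_medial_curve,
    compute_thickness,
    interhemispheric_mean,
)
from shapemeta.synthetic_cohort import make_structure_mesh
from shapemeta.mesh_io import triangle_areas


def _rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# medial curve
# ---------------------------------------------------------------------------


def test_cylinder_curve_lies_on_axis(cylinder_mesh):
    curve = compute_medial_curve(cylinder_mesh)
    assert np.abs(curve.points[:, :2]).max() < 0.02


def test_curve_translation_equivariance(cylinder_mesh):
    shift = np.array([10.0, -3.0, 5.0])
    moved = SurfaceMesh(cylinder_mesh.vertices + shift, cylinder_mesh.faces)
    c0 = compute_medial_curve(cylinder_mesh)
    c1 = compute_medial_curve(moved)
    np.testing.assert_allclose(c1.points, c0.points + shift, atol=1e-9)


def test_ellipsoid_curve_matches_slicing_oracle(rng):
    """Brute-force oracle: centroids of 500 thin cross-sectional slices of a
    2:1:1 ellipsoid trace its major axis; the banded curve must agree."""
    mesh = make_structure_mesh("ellipsoid", 400, rng, radius=1.0, length=4.0)
    curve = compute_medial_curve(mesh)
    z = mesh.vertices[:, 2]
    edges = np.linspace(z.min(), z.max(), 501)
    centroids = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (z >= a) & (z < b)
        if sel.sum() >= 3:
            centroids.append(mesh.vertices[sel].mean(axis=0))
    d = _point_to_polyline_distance(curve.points, np.asarray(centroids))
    assert d.max() < 0.02


def test_near_spherical_mesh_degenerates_to_centroid():
    # area-uniform sphere lattice (rings uniform in z): an isotropic closed
    # mesh with no distinguished long axis
    from shapemeta.synthetic_cohort import _lattice_counts, _lattice_faces, \
        _lattice_vertices

    n_theta, n_z = _lattice_counts(300)

    def profile(u):
        z = -1.0 + 2.0 * u
        return np.sqrt(max(0.0, 1.0 - z * z)), z

    mesh = SurfaceMesh(_lattice_vertices(n_theta, n_z, profile),
                       _lattice_faces(n_theta, n_z))
    with pytest.warns(UserWarning, match="near-spherical"):
        curve = compute_medial_curve(mesh)
    assert curve.degenerate and len(curve.points) == 1
    np.testing.assert_allclose(curve.points[0], mesh.vertices.mean(axis=0),
                               atol=1e-12)
    thick = compute_thickness(mesh, curve)
    oracle = np.linalg.norm(mesh.vertices - mesh.vertices.mean(axis=0), axis=1)
    np.testing.assert_allclose(thick.values, oracle, atol=1e-12)


def test_curve_input_validation(cylinder_mesh):
    with pytest.raises(MeasureError):
        compute_medial_curve(cylinder_mesh, n_bands=1)
    with pytest.raises(MeasureError):
        compute_medial_curve(cylinder_mesh, n_bands=10_000)


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------


def test_cylinder_thickness_equals_radius(cylinder_mesh):
    curve = compute_medial_curve(cylinder_mesh)
    thick = compute_thickness(cylinder_mesh, curve)
    lateral = np.abs(cylinder_mesh.vertices[:, 2]) < 2.4
    assert np.abs(thick.values[lateral] - 1.0).max() < 0.02


def test_thickness_scaling_law(cylinder_mesh):
    c = compute_medial_curve(cylinder_mesh)
    t1 = compute_thickness(cylinder_mesh, c)
    scaled = SurfaceMesh(2.0 * cylinder_mesh.vertices, cylinder_mesh.faces)
    c2 = compute_medial_curve(scaled)
    t2 = compute_thickness(scaled, c2)
    np.testing.assert_allclose(t2.values, 2.0 * t1.values, atol=1e-9)


def test_thickness_rigid_motion_invariance(cylinder_mesh, rng):
    q = _rotation(rng)
    moved = SurfaceMesh(cylinder_mesh.vertices @ q.T + [3.0, 1.0, -7.0],
                        cylinder_mesh.faces)
    t0 = compute_thickness(cylinder_mesh, compute_medial_curve(cylinder_mesh))
    t1 = compute_thickness(moved, compute_medial_curve(moved))
    np.testing.assert_allclose(t1.values, t0.values, atol=1e-6)


def test_thickness_matches_dense_sampling_oracle(rng):
    """Point-to-segment minimisation at 10x curve sampling density agrees."""
    mesh = make_structure_mesh("bumpy-ellipsoid", 400, rng, radius=1.0,
                               length=4.0)
    coarse = compute_medial_curve(mesh, n_samples=100)
    dense = compute_medial_curve(mesh, n_samples=1000)
    t_coarse = compute_thickness(mesh, coarse).values
    t_dense = compute_thickness(mesh, dense).values
    assert np.abs(t_coarse - t_dense).max() < 1e-3


# ---------------------------------------------------------------------------
# log-Jacobian
# ---------------------------------------------------------------------------


def test_log_jacobian_identity(cylinder_mesh):
    lj = compute_log_jacobian(cylinder_mesh, cylinder_mesh)
    assert np.abs(lj.values).max() < 1e-12


@pytest.mark.parametrize("s", [0.5, 2.0, 3.0])
def test_log_jacobian_uniform_scaling(cylinder_mesh, s):
    scaled = SurfaceMesh(s * cylinder_mesh.vertices, cylinder_mesh.faces)
    lj = compute_log_jacobian(scaled, cylinder_mesh)
    np.testing.assert_allclose(lj.values, 2.0 * np.log(s), atol=1e-9)


def test_log_jacobian_matches_face_level_oracle(cylinder_mesh, rng):
    """Independent per-face re-implementation aggregated by the same
    one-ring rule agrees to machine precision."""
    normals = vertex_normals(cylinder_mesh)
    z = cylinder_mesh.vertices[:, 2]
    defo = 0.1 * np.sin(z) + 0.05 * rng.normal(size=len(z)) * 0.0  # smooth
    subject = SurfaceMesh(cylinder_mesh.vertices + defo[:, None] * normals,
                          cylinder_mesh.faces)
    lj = compute_log_jacobian(subject, cylinder_mesh)

    # oracle: explicit python loop over faces and vertices
    def ring_area(mesh):
        v, f = mesh.vertices, mesh.faces
        out = np.zeros(mesh.n_vertices)
        for (a, b, c) in f:
            area = 0.5 * np.linalg.norm(np.cross(v[b] - v[a], v[c] - v[a]))
            for vi in (a, b, c):
                out[vi] += area
        return out

    oracle = np.log(ring_area(subject) / ring_area(cylinder_mesh))
    assert np.abs(lj.values - oracle).max() < 1e-12


def test_log_jacobian_total_area_consistency(cylinder_mesh):
    """exp(area-weighted mean log-Jacobian) ~ total area ratio (within 1%)."""
    normals = vertex_normals(cylinder_mesh)
    z = cylinder_mesh.vertices[:, 2]
    defo = 0.05 * np.sin(z) + 0.02
    subject = SurfaceMesh(cylinder_mesh.vertices + defo[:, None] * normals,
                          cylinder_mesh.faces)
    lj = compute_log_jacobian(subject, cylinder_mesh)
    w = _one_ring_areas(cylinder_mesh)
    lhs = np.exp(np.average(lj.values, weights=w))
    rhs = triangle_areas(subject).sum() / triangle_areas(cylinder_mesh).sum()
    assert abs(lhs / rhs - 1.0) < 0.01


def test_log_jacobian_topology_mismatch(cylinder_mesh):
    other = SurfaceMesh(cylinder_mesh.vertices,
                        cylinder_mesh.faces[::-1].copy())
    with pytest.raises(MeasureError, match="topology"):
        compute_log_jacobian(other, cylinder_mesh)


# ---------------------------------------------------------------------------
# bilateral maps
# ---------------------------------------------------------------------------


def _pair(toy_atlas, left_vals, right_vals, kind="thickness"):
    n = toy_atlas.n_vertices("hippocampus")
    left = VertexMeasureMap("s", "hippocampus", "L", kind,
                            np.broadcast_to(left_vals, n).astype(float))
    right = VertexMeasureMap("s", "hippocampus", "R", kind,
                             np.broadcast_to(right_vals, n).astype(float))
    return left, right


def test_asymmetry_identical_maps_zero(toy_atlas):
    left, right = _pair(toy_atlas, 1.7, 1.7)
    asym = asymmetry_index(left, right, toy_atlas)
    assert asym.measure_kind == "asym_thickness"
    assert np.all(asym.values == 0.0)


def test_asymmetry_constant_difference_and_symmetry(toy_atlas):
    left, right = _pair(toy_atlas, 2.0, 1.0)
    a1 = asymmetry_index(left, right, toy_atlas)
    a2 = asymmetry_index(right, left, toy_atlas)
    assert np.all(a1.values == 1.0)
    np.testing.assert_array_equal(a1.values, a2.values)


def test_asymmetry_kind_mismatch(toy_atlas):
    left, _ = _pair(toy_atlas, 2.0, 1.0, kind="thickness")
    _, right = _pair(toy_atlas, 2.0, 1.0, kind="log_jacobian")
    with pytest.raises(MeasureError, match="kind"):
        asymmetry_index(left, right, toy_atlas)


def test_interhemispheric_mean_values_and_linearity(toy_atlas, rng):
    n = toy_atlas.n_vertices("hippocampus")
    lv = rng.uniform(1, 2, n)
    rv = rng.uniform(1, 2, n)
    left = VertexMeasureMap("s", "hippocampus", "L", "thickness", lv)
    right = VertexMeasureMap("s", "hippocampus", "R", "thickness", rv)
    mean = interhemispheric_mean(left, right, toy_atlas)
    lr = toy_atlas.lr_map["hippocampus"]
    np.testing.assert_allclose(mean.values, 0.5 * (lv + rv[lr]))
    left2 = VertexMeasureMap("s", "hippocampus", "L", "thickness", 3 * lv)
    right2 = VertexMeasureMap("s", "hippocampus", "R", "thickness", 3 * rv)
    mean2 = interhemispheric_mean(left2, right2, toy_atlas)
    np.testing.assert_allclose(mean2.values, 3 * mean.values, rtol=1e-12)
    const = interhemispheric_mean(*_pair(toy_atlas, 1.0, 3.0), toy_atlas)
    assert np.all(const.values == 2.0)


def test_measure_map_csv_and_npy_round_trip(tmp_path, rng):
    m = VertexMeasureMap("s9", "caudate", "L", "log_jacobian",
                         rng.normal(size=50))
    m.to_csv(tmp_path / "m.csv")
    back = VertexMeasureMap.from_csv(tmp_path / "m.csv", subject_id="s9",
                                     structure_id="caudate", hemisphere="L",
                                     measure_kind="log_jacobian")
    np.testing.assert_array_equal(back.values, m.values)
    m.save_npy(tmp_path / "m.npy")
    back2 = VertexMeasureMap.load_npy(tmp_path / "m.npy")
    np.testing.assert_array_equal(back2.values, m.values)
    assert back2.structure_id == "caudate"
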