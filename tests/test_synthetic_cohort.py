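"""Synthetic templates, subject simulation, and multi-site datasets."""

import numpy as np
import pytest

from shapemeta.mesh_io import SubjectRecord, triangle_areas
from shapemeta.shape_measures import (
    compute_log_jacobian,
    compute_medial_curve,
    compute_thickness,
)
from shapemeta.synthetic_cohort import (
    EffectField,
    Patch,
    SimConfig,
    SimulationError,
    make_structure_mesh,
    make_template,
    mirror_mesh,
    simulate_multisite,
    simulate_subject,
)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("family", ["cylinder", "ellipsoid", "bumpy-ellipsoid"])
def test_template_is_closed_surface(family, rng):
    mesh = make_structure_mesh(family, 600, rng)
    V, F = mesh.n_vertices, mesh.n_faces
    edges = set()
    for a, b, c in mesh.faces:
        for e in ((a, b), (b, c), (c, a)):
            edges.add(frozenset(e))
    E = len(edges)
    assert V - E + F == 2  # Euler characteristic of a genus-0 surface


def test_template_determinism():
    a = make_template("bumpy-ellipsoid", 300, seed=7)
    b = make_template("bumpy-ellipsoid", 300, seed=7)
    assert a.checksum() == b.checksum()
    for key in a.meshes:
        np.testing.assert_array_equal(a.meshes[key].vertices,
                                      b.meshes[key].vertices)


def test_mirrored_hemisphere_is_isometric(rng):
    mesh = make_structure_mesh("bumpy-ellipsoid", 300, rng)
    mirrored = mirror_mesh(mesh)
    a0 = triangle_areas(mesh)
    a1 = triangle_areas(mirrored)
    np.testing.assert_allclose(a1, a0, rtol=1e-12)


def test_template_too_small_rejected(rng):
    with pytest.raises(SimulationError):
        make_structure_mesh("cylinder", 10, rng)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def _control(subject_id="c1"):
    return SubjectRecord(subject_id, "site00", 0, 40.0, 1, 1.5e6)


def _patient(subject_id="p1", cpz=None, saps=None):
    return SubjectRecord(subject_id, "site00", 1, 40.0, 1, 1.5e6,
                         cpz=cpz, saps_total=saps)


def test_zero_effects_zero_noise_reproduces_template():
    atlas = make_template("cylinder", 300, seed=3)
    eff = EffectField.zeros(atlas)
    out = simulate_subject(atlas, _patient(), eff, 0.0,
                           np.random.default_rng(0))
    for key, mesh in out.items():
        np.testing.assert_array_equal(mesh.vertices,
                                      atlas.meshes[key].vertices)
        lj = compute_log_jacobian(mesh, atlas.meshes[key])
        assert np.abs(lj.values).max() < 1e-12


def test_controls_unaffected_by_dx_patches():
    atlas = make_template("cylinder", 300, seed=3)
    eff = EffectField.from_patches(
        atlas, [Patch("hippocampus", 150, 12.0, 0.5, "dx"),
                Patch("hippocampus", 100, 10.0, 0.3, "asym")])
    out = simulate_subject(atlas, _control(), eff, 0.0,
                           np.random.default_rng(0))
    for key, mesh in out.items():
        np.testing.assert_array_equal(mesh.vertices,
                                      atlas.meshes[key].vertices)


def test_planted_patch_thickness_response():
    """A +0.3 mm radial patch covering full cross-sections raises thickness
    by 0.3 mm over its azimuthally complete interior."""
    atlas = make_template("cylinder", 300, seed=3)
    patch = Patch("hippocampus", 150, 12.0, 0.3, "dx")
    eff = EffectField.from_patches(atlas, [patch])
    out = simulate_subject(atlas, _patient(), eff, 0.0,
                           np.random.default_rng(0))
    mesh = out[("hippocampus", "L")]
    template = atlas.meshes[("hippocampus", "L")]
    th = compute_thickness(mesh, compute_medial_curve(mesh)).values
    th0 = compute_thickness(template, compute_medial_curve(template)).values
    pv = eff.patch_vertices("hippocampus")
    coords = template.vertices
    center = coords[patch.center_vertex]
    # interior: rings fully inside the ball (|dz| small enough that the
    # far side of the cross-section is still within the patch radius)
    radius_struct = 4.0
    interior_z = np.sqrt(patch.radius ** 2 - (2 * radius_struct) ** 2)
    interior = pv[np.abs(coords[pv, 2] - center[2]) <= interior_z - 1e-9]
    off = np.setdiff1d(np.arange(template.n_vertices), pv)
    delta = th - th0
    assert abs(delta[interior].mean() - delta[off].mean() - 0.3) < 0.02


def test_asymmetry_field_has_opposite_hemisphere_signs():
    atlas = make_template("cylinder", 300, seed=3)
    eff = EffectField.from_patches(
        atlas, [Patch("hippocampus", 150, 12.0, 0.2, "asym")])
    out = simulate_subject(atlas, _patient(), eff, 0.0,
                           np.random.default_rng(0))
    pv = eff.patch_vertices("hippocampus", "asym")
    for hemi, sign in (("L", 1.0), ("R", -1.0)):
        mesh = out[("hippocampus", hemi)]
        template = atlas.meshes[("hippocampus", hemi)]
        disp = np.linalg.norm(mesh.vertices - template.vertices, axis=1)
        offset = np.zeros(template.n_vertices)
        offset[pv] = sign * 0.2
        np.testing.assert_allclose(disp[pv], 0.2, atol=1e-9)


def test_triangle_inversion_raises_amplitude_error():
    atlas = make_template("cylinder", 300, seed=3)
    eff = EffectField.from_patches(
        atlas, [Patch("hippocampus", 150, 6.0, -50.0, "dx")])
    with pytest.raises(SimulationError, match="smaller planted effect"):
        simulate_subject(atlas, _patient(), eff, 0.0,
                         np.random.default_rng(0))


# ---------------------------------------------------------------------------
# multi-site datasets
# ---------------------------------------------------------------------------


def test_multisite_bookkeeping():
    cfg = SimConfig(n_sites=3, n_patients=30, n_controls=30, n_vertices=120,
                    seed=4)
    ds = simulate_multisite(cfg)
    assert len(ds.records) == 180
    assert ds.site_ids == ["site00", "site01", "site02"]
    assert all(r.cpz is not None for r in ds.records if r.dx == 1)
    assert all(r.cpz is None for r in ds.records if r.dx == 0)


def test_zero_tau_shares_effects_across_sites():
    cfg = SimConfig(n_sites=3, n_patients=10, n_controls=10, n_vertices=120,
                    tau=0.0, seed=4)
    ds = simulate_multisite(cfg, patches=[Patch("hippocampus", 60, 12.0,
                                                0.1, "dx")])
    amps = ds.manifest["site_true_dx_amplitudes"]
    first = amps["site00"]["hippocampus"]
    assert all(amps[s]["hippocampus"] == first for s in amps)


def test_dataset_determinism():
    cfg = SimConfig(n_sites=2, n_patients=8, n_controls=8, n_vertices=120,
                    seed=11)
    a = simulate_multisite(cfg)
    b = simulate_multisite(cfg)
    assert a.manifest == b.manifest
    for sid in a.meshes:
        for key in a.meshes[sid]:
            np.testing.assert_array_equal(a.meshes[sid][key].vertices,
                                          b.meshes[sid][key].vertices)
    assert [r.__dict__ for r in a.records] == [r.__dict__ for r in b.records]


def test_dataset_write_round_trip(tmp_path):
    cfg = SimConfig(n_sites=1, n_patients=5, n_controls=5, n_vertices=120,
                    seed=2)
    ds = simulate_multisite(cfg)
    ds.write(tmp_path / "data")
    assert (tmp_path / "data" / "atlas" / "atlas.json").exists()
    assert (tmp_path / "data" / "covariates.csv").exists()
    assert (tmp_path / "data" / "ground_truth.json").exists()
    meshes = list((tmp_path / "data" / "meshes" / "site00").glob("*.ply"))
    assert len(meshes) == 10 * 2  # subjects x hemispheres (one structure)
    cfg2 = SimConfig.from_yaml(tmp_path / "data" / "sim_config.yaml")
    assert cfg2 == cfg


def test_effect_monotonicity_in_planted_amplitude():
    """Doubling the planted amplitude increases the recovered pooled |d|."""
    from shapemeta.pipeline import RunConfig, analyze_dataset

    config = RunConfig(models=("m1_dx_thickness",))
    recovered = []
    for amp in (0.05, 0.10):
        cfg = SimConfig(n_sites=3, n_patients=30, n_controls=30,
                        n_vertices=120, noise_sd=0.3, seed=5)
        ds = simulate_multisite(cfg, patches=[Patch("hippocampus", 60, 12.0,
                                                    -amp, "dx")])
        res = analyze_dataset(ds, config)
        pv = np.asarray(ds.manifest["patch_vertices"]["dx"]["hippocampus"])
        meta = res.meta[("m1_dx_thickness", "hippocampus", "mean_thickness")]
        recovered.append(abs(meta.pooled_d[pv].mean()))
    assert recovered[1] > recovered[0]


def test_null_configuration_yields_no_discoveries():
    """All effects zero: site-level type-I error calibrated and the
    searchlight masks reject (almost) nothing family-wide."""
    from shapemeta.pipeline import RunConfig, analyze_dataset
    from shapemeta.site_glm import MODELS

    cfg = SimConfig(n_sites=3, n_patients=40, n_controls=40, n_vertices=120,
                    seed=6)
    ds = simulate_multisite(cfg)
    config = RunConfig(models=tuple(MODELS))
    res = analyze_dataset(ds, config)
    n_total = sum(m.n_vertices for m in res.meta.values())
    n_rej = sum(mask.n_rejections() for mask in res.masks.values())
    assert n_rej <= 0.01 * n_total
    rates = [float((m.p < 0.05).mean()) for m in res.meta.values()]
    assert np.mean(rates) < 0.10  # no systematic inflation


def test_infeasible_config_rejected():
    with pytest.raises(SimulationError):
        SimConfig(n_sites=0).validate()
    with pytest.raises(SimulationError):
        SimConfig(noise_sd=-1.0).validate()
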