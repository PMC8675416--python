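"""Synthetic multi-site shape cohorts with known ground truth.

The generator emulates the structure of a multi-site subcortical shape
study — a shared template atlas, per-subject corresponded meshes, and a
covariate table — with every planted quantity recorded in a manifest so
downstream stages can be validated against ground truth.

Generative model
----------------
Subject meshes are the template deformed by a per-vertex *radial offset*
along the template vertex normal:

    offset(v) = dx * [effect_dx(v) + site_dev] + cpz * slope_cpz(v)
              + saps * slope_saps(v) + dx * s_hemi * asym(v)
              + beta_age * (age - 40) + beta_icv * (icv - icv_mean) + eps(v)

where ``eps ~ N(0, noise_sd)`` i.i.d. per vertex, smoothed over the
one-ring (mean of a vertex and its edge neighbours) to keep meshes valid,
and ``s_hemi`` is +1 on the left and -1 on the right hemisphere so the
asymmetry field perturbs |L - R| in patients. The radial-offset model is
chosen because both shape measures respond to it analytically: thickness
shifts by the offset, and the log-Jacobian by the induced local area
change.

Site heterogeneity: each site's diagnosis effect is the global planted
effect plus a scalar deviation drawn from ``N(0, tau^2)`` applied inside
the planted patches.

Randomness: one RNG stream per (site, subject), derived from the master
seed with ``numpy.random.SeedSequence(master_seed, spawn_key=(site,
subject))`` — reproducibility is independent of generation order.

Default covariate distributions (realistic ranges, not asserted as any
cohort's truth): age ~ Uniform(18, 60); sex ~ Bernoulli(0.6 male) for
patients and 0.55 for controls; ICV ~ Normal(1.5e6, 1.5e5) mm^3;
chlorpromazine dose equivalents ~ LogNormal matched to a mean of 376
mg/day; SAPS total ~ Normal(17, 6) truncated at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .mesh_io import (
    AtlasTemplate,
    SubjectRecord,
    SurfaceMesh,
    triangle_areas,
    vertex_adjacency,
    vertex_normals,
    write_covariates,
    write_mesh,
)

SHAPE_FAMILIES = ("cylinder", "ellipsoid", "bumpy-ellipsoid")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def _lattice_counts(n_vertices: int) -> tuple[int, int]:
    """Ring/segment counts for a pole-capped lattice with ~n_vertices."""
    if n_vertices < 50:
        raise SimulationError("n_vertices must be >= 50")
    # n = n_theta * n_z + 2 with n_z ~ 2 * n_theta for elongated shapes
    n_theta = max(6, int(round(np.sqrt((n_vertices - 2) / 2.0))))
    n_z = max(4, (n_vertices - 2) // n_theta)
    return n_theta, n_z


def _lattice_faces(n_theta: int, n_z: int) -> np.ndarray:
    """Faces of a closed lattice: two poles plus n_z rings of n_theta."""
    faces = []
    bottom = 0
    top = 1
    ring = lambda k, j: 2 + k * n_theta + (j % n_theta)  # noqa: E731
    for j in range(n_theta):  # bottom fan (outward: counter-clockwise seen from below)
        faces.append([bottom, ring(0, j + 1), ring(0, j)])
    for k in range(n_z - 1):  # lateral quads split into triangles
        for j in range(n_theta):
            a, b = ring(k, j), ring(k, j + 1)
            c, d = ring(k + 1, j), ring(k + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_theta):  # top fan
        faces.append([top, ring(n_z - 1, j), ring(n_z - 1, j + 1)])
    return np.asarray(faces, dtype=np.int64)


def _lattice_vertices(n_theta: int, n_z: int, profile) -> np.ndarray:
    """Vertices of the closed lattice; ``profile(u)`` maps u in (0, 1) to
    (radius, z) of each ring; poles from profile at u=0, 1."""
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    _, z0 = profile(0.0)
    _, z1 = profile(1.0)
    verts = [np.array([0.0, 0.0, z0]), np.array([0.0, 0.0, z1])]
    for k in range(n_z):
        u = (k + 0.5) / n_z
        rad, z = profile(u)
        ring = np.column_stack([rad * np.cos(theta), rad * np.sin(theta),
                                np.full(n_theta, z)])
        verts.extend(ring)
    return np.asarray(verts, dtype=np.float64)


def make_structure_mesh(shape_family: str, n_vertices: int,
                        rng: np.random.Generator,
                        radius: float = 4.0, length: float = 40.0
                        ) -> SurfaceMesh:
    """One closed genus-0 mesh of the requested family, z its long axis."""
    n_theta, n_z = _lattice_counts(n_vertices)
    half = length / 2.0

    if shape_family == "cylinder":
        # lateral wall with small conical caps at the poles
        def profile(u):
            return radius, -half + u * length
    elif shape_family in ("ellipsoid", "bumpy-ellipsoid"):
        def profile(u):
            phi = np.pi * u
            return radius * np.sin(phi), -half * np.cos(phi)
    else:
        raise SimulationError(f"unknown shape family {shape_family!r}; "
                              f"choose from {SHAPE_FAMILIES}")

    v = _lattice_vertices(n_theta, n_z, profile)
    f = _lattice_faces(n_theta, n_z)
    if shape_family == "bumpy-ellipsoid":
        # smooth seeded radial modulation of the lateral rings
        coef = rng.normal(0.0, 1.0, size=6)
        xy = v[:, :2]
        rad = np.linalg.norm(xy, axis=1)
        lateral = rad > 0
        ang = np.arctan2(v[lateral, 1], v[lateral, 0])
        zz = v[lateral, 2] / half
        bump = (coef[0] * np.cos(ang) + coef[1] * np.sin(ang)
                + coef[2] * np.cos(2 * ang) + coef[3] * np.sin(2 * ang)
                + coef[4] * np.sin(np.pi * zz) + coef[5] * np.cos(np.pi * zz))
        scale = 1.0 + 0.05 * bump / max(1.0, np.abs(bump).max())
        v[lateral, :2] *= scale[:, None]
    mesh = SurfaceMesh(v, f)
    mesh.validate()
    areas = triangle_areas(mesh)
    if areas.min() <= 1e-9:
        raise SimulationError(
            f"n_vertices={n_vertices} too small to triangulate {shape_family}")
    return mesh


def mirror_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Reflect across the x = 0 plane, reversing winding to keep outward
    normals. Vertex indices are unchanged, so the L↔R map is the identity."""
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    f = mesh.faces[:, ::-1].copy()
    return SurfaceMesh(v, f, mesh.structure_id, mesh.hemisphere, mesh.subject_id)


def make_template(shape_family: str, n_vertices: int, seed: int,
                  structures: Sequence[str] = ("hippocampus",),
                  radius: float = 4.0, length: float = 40.0,
                  spacing: float = 60.0) -> AtlasTemplate:
    """Synthetic atlas: one L/R mesh pair per structure.

    Each structure's left mesh is placed at ``x = -spacing/2``, offset in y
    by its index so structures are spatially separated; the right mesh is
    its mirror image (identity L↔R vertex correspondence). Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    meshes: dict[tuple[str, str], SurfaceMesh] = {}
    lr_map: dict[str, np.ndarray] = {}
    for idx, structure in enumerate(structures):
        base = make_structure_mesh(shape_family, n_vertices, rng,
                                   radius=radius, length=length)
        v = base.vertices.copy()
        v[:, 0] -= spacing / 2.0
        v[:, 1] += idx * spacing
        left = SurfaceMesh(v, base.faces.copy(), structure, "L", "template")
        right = mirror_mesh(left)
        right.hemisphere = "R"
        meshes[(structure, "L")] = left
        meshes[(structure, "R")] = right
        lr_map[structure] = np.arange(left.n_vertices, dtype=np.int64)
    atlas = AtlasTemplate(meshes=meshes, lr_map=lr_map,
                          provenance=f"synthetic:{shape_family}:seed={seed}")
    return atlas.validate()


# ---------------------------------------------------------------------------
# Effect fields
# ---------------------------------------------------------------------------


@dataclass
class Patch:
    """A planted effect patch: constant amplitude within a Euclidean ball
    around a template vertex. ``kind`` selects the field it contributes to:
    "dx" (mm), "cpz" (mm per mg/day), "saps" (mm per score point), or
    "asym" (mm, applied with opposite hemisphere signs in patients)."""

    structure: str
    center_vertex: int
    radius: float
    amplitude: float
    kind: str = "dx"


@dataclass
class EffectField:
    """Per-vertex planted fields on the left template (applied to both
    hemispheres through the identity-index correspondence)."""

    dx: dict[str, np.ndarray]
    cpz: dict[str, np.ndarray]
    saps: dict[str, np.ndarray]
    asym: dict[str, np.ndarray]
    patches: list[Patch] = field(default_factory=list)

    @classmethod
    def zeros(cls, atlas: AtlasTemplate) -> "EffectField":
        def z():
            return {s: np.zeros(atlas.n_vertices(s)) for s in atlas.structures}
        return cls(dx=z(), cpz=z(), saps=z(), asym=z())

    @classmethod
    def from_patches(cls, atlas: AtlasTemplate,
                     patches: Sequence[Patch]) -> "EffectField":
        eff = cls.zeros(atlas)
        fields = {"dx": eff.dx, "cpz": eff.cpz, "saps": eff.saps, "asym": eff.asym}
        for patch in patches:
            if patch.kind not in fields:
                raise SimulationError(f"unknown patch kind {patch.kind!r}")
            coords = atlas.meshes[(patch.structure, "L")].vertices
            center = coords[patch.center_vertex]
            inside = np.linalg.norm(coords - center, axis=1) <= patch.radius
            fields[patch.kind][patch.structure][inside] += patch.amplitude
            eff.patches.append(patch)
        return eff

    def patch_vertices(self, structure: str, kind: str = "dx") -> np.ndarray:
        """Indices of vertices with a nonzero planted field."""
        return np.flatnonzero(getattr(self, kind)[structure] != 0.0)


# ---------------------------------------------------------------------------
# Simulation config
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions of one simulated multi-site cohort."""

    n_sites: int = 5
    n_patients: int = 100
    n_controls: int = 100
    age_range: tuple[float, float] = (18.0, 60.0)
    sex_p_patient: float = 0.6
    sex_p_control: float = 0.55
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    cpz_mean: float = 376.0  # mg/day; lognormal with sigma_log below
    cpz_sigma_log: float = 0.5
    saps_mean: float = 17.0
    saps_sd: float = 6.0
    noise_sd: float = 0.3  # mm, radial, before one-ring smoothing
    beta_age: float = -0.005  # mm per year from age 40
    beta_icv: float = 4e-7  # mm per mm^3 from the ICV mean
    tau: float = 0.0  # between-site SD of the dx patch amplitude (mm)
    shape_family: str = "cylinder"
    n_vertices: int = 350
    structure_radius: float = 4.0  # mm; thin enough that a ball patch can
    structure_length: float = 40.0  # cover full cross-sections (see docs)
    structures: tuple[str, ...] = ("hippocampus",)
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_sites < 1 or self.n_patients < 0 or self.n_controls < 0:
            raise SimulationError("counts must be non-negative (n_sites >= 1)")
        if self.noise_sd < 0 or self.tau < 0 or self.icv_sd < 0:
            raise SimulationError("SDs must be non-negative")
        return self

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["structures"] = list(self.structures)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["age_range"] = tuple(d["age_range"])
        d["structures"] = tuple(d["structures"])
        return cls(**d).validate()


def _subject_rng(master_seed: int, site: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(site, subject)))


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------


def _smooth_one_ring(values: np.ndarray, adjacency: list[np.ndarray]) -> np.ndarray:
    out = np.empty_like(values)
    for v, nb in enumerate(adjacency):
        out[v] = (values[v] + values[nb].sum()) / (1 + nb.size)
    return out


class _TemplateCache:
    """Per-template precomputation shared across subjects."""

    def __init__(self, atlas: AtlasTemplate):
        self.normals = {}
        self.adjacency = {}
        self.face_normals = {}
        for key, mesh in atlas.meshes.items():
            self.normals[key] = vertex_normals(mesh)
            self.adjacency[key] = vertex_adjacency(mesh)
            v, f = mesh.vertices, mesh.faces
            self.face_normals[key] = np.cross(v[f[:, 1]] - v[f[:, 0]],
                                              v[f[:, 2]] - v[f[:, 0]])


def simulate_subject(atlas: AtlasTemplate, record: SubjectRecord,
                     effects: EffectField, noise_sd: float,
                     rng: np.random.Generator,
                     site_dev: float = 0.0,
                     beta_age: float = 0.0, beta_icv: float = 0.0,
                     icv_mean: float = 1.5e6,
                     cache: "_TemplateCache | None" = None
                     ) -> dict[tuple[str, str], SurfaceMesh]:
    """One subject's meshes: template plus radial offsets (see module doc).

    Raises :class:`SimulationError` if the offsets invert any triangle,
    with instructions to reduce the planted amplitudes.
    """
    cache = cache or _TemplateCache(atlas)
    out: dict[tuple[str, str], SurfaceMesh] = {}
    for structure in atlas.structures:
        dx_field = effects.dx[structure]
        site_patch = np.where(dx_field != 0.0, site_dev, 0.0)
        base = (record.dx * (dx_field + site_patch)
                + (record.cpz or 0.0) * effects.cpz[structure]
                + (record.saps_total or 0.0) * effects.saps[structure]
                + beta_age * (record.age - 40.0)
                + beta_icv * (record.icv - icv_mean))
        for hemi, s_hemi in (("L", 1.0), ("R", -1.0)):
            key = (structure, hemi)
            template = atlas.meshes[key]
            eps = rng.normal(0.0, noise_sd, size=template.n_vertices) \
                if noise_sd > 0 else np.zeros(template.n_vertices)
            eps = _smooth_one_ring(eps, cache.adjacency[key])
            offset = base + record.dx * s_hemi * effects.asym[structure] + eps
            v = template.vertices + offset[:, None] * cache.normals[key]
            mesh = SurfaceMesh(v, template.faces.copy(), structure, hemi,
                               record.subject_id)
            fn = np.cross(v[mesh.faces[:, 1]] - v[mesh.faces[:, 0]],
                          v[mesh.faces[:, 2]] - v[mesh.faces[:, 0]])
            if np.any(np.einsum("ij,ij->i", fn, cache.face_normals[key]) <= 0):
                raise SimulationError(
                    f"{record.subject_id} {structure} {hemi}: radial offsets "
                    "invert triangles — use smaller planted effect amplitudes "
                    "or noise_sd")
            out[key] = mesh
    return out


def _draw_record(cfg: SimConfig, site: int, idx: int, dx: int,
                 rng: np.random.Generator) -> SubjectRecord:
    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi)
    p_male = cfg.sex_p_patient if dx else cfg.sex_p_control
    sex = int(rng.random() < p_male)
    icv = rng.normal(cfg.icv_mean, cfg.icv_sd)
    cpz = saps = None
    if dx:
        mu_log = np.log(cfg.cpz_mean) - 0.5 * cfg.cpz_sigma_log ** 2
        cpz = float(rng.lognormal(mu_log, cfg.cpz_sigma_log))
        saps = float(max(0.0, rng.normal(cfg.saps_mean, cfg.saps_sd)))
    return SubjectRecord(
        subject_id=f"s{site:02d}_{idx:04d}", site_id=f"site{site:02d}",
        dx=dx, age=float(age), sex=sex, icv=float(icv), cpz=cpz,
        saps_total=saps).validate()


@dataclass
class SimulatedDataset:
    """In-memory multi-site dataset plus its ground-truth manifest."""

    config: SimConfig
    atlas: AtlasTemplate
    records: list[SubjectRecord]
    meshes: dict[str, dict[tuple[str, str], SurfaceMesh]]  # subject_id -> meshes
    manifest: dict

    def site_records(self, site_id: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.site_id == site_id]

    @property
    def site_ids(self) -> list[str]:
        return sorted({r.site_id for r in self.records})

    def write(self, directory: str | Path) -> None:
        """Materialise as PLY meshes + CSV covariates + JSON manifest."""
        directory = Path(directory)
        (directory / "atlas").mkdir(parents=True, exist_ok=True)
        self.atlas.save(directory / "atlas")
        write_covariates(self.records, directory / "covariates.csv")
        self.config.to_yaml(directory / "sim_config.yaml")
        meshdir = directory / "meshes"
        for record in self.records:
            sdir = meshdir / record.site_id
            sdir.mkdir(parents=True, exist_ok=True)
            for (structure, hemi), mesh in self.meshes[record.subject_id].items():
                write_mesh(mesh,
                           sdir / f"{record.subject_id}_{structure}_{hemi}.ply")
        with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)


def calibrate_patch_amplitude(config: SimConfig, patch: Patch,
                              target_d: float = 0.15,
                              pilot_subjects: int = 40) -> float:
    """Planted amplitude (mm) giving a standardized diagnosis effect of
    ``target_d`` on the interhemispheric-mean measure.

    The calibration is part of the generator and deterministic given the
    config seed: (i) a small no-effect pilot site measures the residual SD
    of the measure after removing the covariate structure; (ii) a single
    noise-free planted subject measures the geometric attenuation of the
    measure response to the radial offset (the subject's own medial curve
    can absorb part of an azimuthally uneven offset). The returned
    amplitude is ``target_d * sd / attenuation``.
    """
    from .shape_measures import compute_medial_curve, compute_thickness

    atlas = make_template(config.shape_family, config.n_vertices,
                          seed=config.seed, structures=config.structures,
                          radius=config.structure_radius,
                          length=config.structure_length)
    cache = _TemplateCache(atlas)
    eff0 = EffectField.zeros(atlas)
    structure = patch.structure

    # (i) residual SD from a covariates-only pilot
    rows = []
    for idx in range(pilot_subjects):
        rng = _subject_rng(config.seed, 2 ** 18, idx)
        rec = _draw_record(config, 0, idx, idx % 2, rng)
        meshes = simulate_subject(atlas, rec, eff0, config.noise_sd, rng,
                                  beta_age=config.beta_age,
                                  beta_icv=config.beta_icv,
                                  icv_mean=config.icv_mean, cache=cache)
        vals = {}
        for hemi in ("L", "R"):
            mesh = meshes[(structure, hemi)]
            vals[hemi] = compute_thickness(
                mesh, compute_medial_curve(mesh)).values
        rows.append((rec, 0.5 * (vals["L"] + vals["R"])))
    Y = np.stack([v for _, v in rows])
    X = np.column_stack([
        np.ones(len(rows)),
        [r.sex for r, _ in rows],
        [r.age for r, _ in rows],
        [r.icv for r, _ in rows],
    ])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    sd = float(np.median(resid.std(axis=0, ddof=X.shape[1])))

    # (ii) geometric attenuation from a noise-free planted subject
    probe_amp = 0.25 * sd if sd > 0 else 0.1
    probe = Patch(patch.structure, patch.center_vertex, patch.radius,
                  probe_amp, patch.kind)
    eff = EffectField.from_patches(atlas, [probe])
    rec = SubjectRecord("probe", "probe", 1, 40.0, 1, config.icv_mean)
    meshes = simulate_subject(atlas, rec, eff, 0.0,
                              np.random.default_rng(0), cache=cache)
    deltas = []
    for hemi in ("L", "R"):
        mesh = meshes[(structure, hemi)]
        tm = atlas.meshes[(structure, hemi)]
        th = compute_thickness(mesh, compute_medial_curve(mesh)).values
        th0 = compute_thickness(tm, compute_medial_curve(tm)).values
        deltas.append(th - th0)
    delta = 0.5 * (deltas[0] + deltas[1])
    pv = eff.patch_vertices(structure, patch.kind)
    attenuation = float(delta[pv].mean() / probe_amp)
    if not (0.05 < abs(attenuation) <= 1.5):
        raise SimulationError(
            f"implausible patch attenuation {attenuation:.3f}; "
            "check patch geometry")
    return float(target_d * sd / attenuation)


def simulate_multisite(config: SimConfig,
                       effects: EffectField | None = None,
                       patches: Sequence[Patch] = ()) -> SimulatedDataset:
    """Generate a full multi-site dataset from a config and planted effects.

    Fully reproducible from ``(config, config.seed)``: the atlas, all
    covariates, site deviations, and subject noise derive from
    counter-based streams of the master seed.
    """
    config.validate()
    atlas = make_template(config.shape_family, config.n_vertices,
                          seed=config.seed, structures=config.structures,
                          radius=config.structure_radius,
                          length=config.structure_length)
    if effects is None:
        effects = EffectField.from_patches(atlas, patches)
    cache = _TemplateCache(atlas)

    site_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2 ** 20,)))
    site_devs = (site_rng.normal(0.0, config.tau, size=config.n_sites)
                 if config.tau > 0 else np.zeros(config.n_sites))

    records: list[SubjectRecord] = []
    meshes: dict[str, dict] = {}
    for site in range(config.n_sites):
        groups = [1] * config.n_patients + [0] * config.n_controls
        for idx, dx in enumerate(groups):
            rng = _subject_rng(config.seed, site, idx)
            record = _draw_record(config, site, idx, dx, rng)
            records.append(record)
            meshes[record.subject_id] = simulate_subject(
                atlas, record, effects, config.noise_sd, rng,
                site_dev=float(site_devs[site]),
                beta_age=config.beta_age, beta_icv=config.beta_icv,
                icv_mean=config.icv_mean, cache=cache)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "site_devs": site_devs.tolist(),
        "site_true_dx_amplitudes": {
            f"site{site:02d}": {
                s: (effects.dx[s][effects.patch_vertices(s, "dx")]
                    + site_devs[site]).tolist()
                for s in atlas.structures
            } for site in range(config.n_sites)
        },
        "patches": [asdict(p) for p in effects.patches],
        "patch_vertices": {
            kind: {s: effects.patch_vertices(s, kind).tolist()
                   for s in atlas.structures}
            for kind in ("dx", "cpz", "saps", "asym")
        },
        "atlas_checksum": atlas.checksum(),
    }
    return SimulatedDataset(config=config, atlas=atlas, records=records,
                            meshes=meshes, manifest=manifest)
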