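"""Surface meshes, atlas bundles, covariate tables, and geometric primitives.

The in-memory conventions used throughout the package are fixed here:

* vertex and face indices are 0-based (OBJ's 1-based disk convention is
  translated at the read/write boundary);
* vertex order IS the correspondence — vertex ``i`` of a subject mesh
  denotes the same anatomical location as vertex ``i`` of the template
  mesh of the same structure and hemisphere;
* coordinates are millimetres, stored as float64 and written to disk at
  full precision (``%.17g`` for text formats, IEEE double for binary PLY).

The readers are deliberately strict: non-triangular faces are rejected with
a line-numbered error instead of being silently triangulated, because a
change in face count would silently break vertex-wise correspondence
downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: The seven bilateral deep-brain structures handled by the pipeline.
STRUCTURES = (
    "hippocampus",
    "amygdala",
    "caudate",
    "accumbens",
    "putamen",
    "pallidum",
    "thalamus",
)

HEMISPHERES = ("L", "R")


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed under the strict contract."""


class MeshValidationError(ValueError):
    """Raised when an in-memory mesh violates its invariants."""


# ---------------------------------------------------------------------------
# SurfaceMesh
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated boundary surface of one structure/hemisphere.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        0-based vertex index triples with consistent (outward) orientation.
    structure_id : str
        One of :data:`STRUCTURES` (or "" for anonymous meshes in tests).
    hemisphere : str
        "L", "R" or "" .
    subject_id : str
        Opaque subject identifier.
    """

    vertices: np.ndarray
    faces: np.ndarray
    structure_id: str = ""
    hemisphere: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array of triangles")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def validate(self) -> "SurfaceMesh":
        """Check invariants; return self for chaining."""
        if self.n_vertices == 0:
            raise MeshValidationError("mesh has no vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("non-finite vertex coordinates")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshValidationError(
                f"face index out of range [0, {self.n_vertices})"
            )
        return self

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.structure_id,
            self.hemisphere,
            self.subject_id,
        )


# ---------------------------------------------------------------------------
# PLY / OBJ readers and writers
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("ply", "obj"):
            raise ValueError(f"unsupported mesh format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "obj"):
        return suffix
    raise ValueError(f"cannot infer mesh format from {path.name!r}; pass fmt=")


def read_mesh(path: str | Path, fmt: str | None = None, **meta: str) -> SurfaceMesh:
    """Read a triangulated mesh from a PLY (ASCII or binary-LE) or OBJ file.

    Vertex order is preserved exactly as stored; non-triangular faces raise
    :class:`MeshFormatError` naming the offending face.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "ply":
        vertices, faces = _read_ply(path)
    else:
        vertices, faces = _read_obj(path)
    return SurfaceMesh(vertices, faces, **meta).validate()


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None,
               binary: bool = False) -> None:
    """Write a mesh so that :func:`read_mesh` reproduces it exactly.

    ``binary=True`` selects binary little-endian PLY (ignored for OBJ).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    mesh.validate()
    if fmt == "ply":
        _write_ply(mesh, path, binary=binary)
    else:
        _write_obj(mesh, path)


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"{path}: line 1: not a PLY file")
        storage = None
        elements: list[tuple[str, int, list]] = []  # (name, count, props)
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise MeshFormatError(f"{path}: unexpected EOF in header")
            line = raw.decode("ascii", errors="replace").strip()
            if line == "end_header":
                break
            if not line or line.startswith("comment") or line.startswith("obj_info"):
                continue
            tok = line.split()
            if tok[0] == "format":
                if tok[1] == "ascii":
                    storage = "ascii"
                elif tok[1] == "binary_little_endian":
                    storage = "binary"
                else:
                    raise MeshFormatError(
                        f"{path}: line {lineno}: unsupported PLY format {tok[1]!r}"
                    )
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if not elements:
                    raise MeshFormatError(
                        f"{path}: line {lineno}: property before element"
                    )
                if tok[1] == "list":
                    elements[-1][2].append(("list", tok[2], tok[3], tok[4]))
                else:
                    elements[-1][2].append(("scalar", tok[1], tok[2]))
            else:
                raise MeshFormatError(
                    f"{path}: line {lineno}: unrecognized header line {line!r}"
                )
        if storage is None:
            raise MeshFormatError(f"{path}: missing PLY format line")

        names = [e[0] for e in elements]
        if "vertex" not in names or "face" not in names:
            raise MeshFormatError(f"{path}: PLY must declare vertex and face elements")

        vertices = faces = None
        for name, count, props in elements:
            if storage == "ascii":
                data_lines = []
                for _ in range(count):
                    raw = fh.readline()
                    lineno += 1
                    if not raw:
                        raise MeshFormatError(f"{path}: unexpected EOF in {name} data")
                    data_lines.append((lineno, raw.decode("ascii").split()))
                if name == "vertex":
                    vertices = _ply_ascii_vertices(path, props, data_lines)
                elif name == "face":
                    faces = _ply_ascii_faces(path, props, data_lines)
            else:
                if name == "vertex":
                    vertices = _ply_binary_vertices(path, props, count, fh)
                elif name == "face":
                    faces = _ply_binary_faces(path, props, count, fh)
                else:
                    _ply_binary_skip(path, props, count, fh)
        assert vertices is not None and faces is not None
        return vertices, faces


def _vertex_prop_layout(path: Path, props: list) -> tuple[np.dtype, tuple[str, str, str]]:
    fields = []
    for i, p in enumerate(props):
        if p[0] == "list":
            raise MeshFormatError(f"{path}: list property in vertex element unsupported")
        _, ptype, pname = p
        if ptype not in _PLY_DTYPES:
            raise MeshFormatError(f"{path}: unknown PLY type {ptype!r}")
        fields.append((pname, "<" + _PLY_DTYPES[ptype]))
    names = [f[0] for f in fields]
    for ax in ("x", "y", "z"):
        if ax not in names:
            raise MeshFormatError(f"{path}: vertex element lacks property {ax!r}")
    return np.dtype(fields), ("x", "y", "z")


def _ply_ascii_vertices(path, props, data_lines) -> np.ndarray:
    dtype, axes = _vertex_prop_layout(path, props)
    names = list(dtype.names)
    out = np.empty((len(data_lines), 3), dtype=np.float64)
    ix = [names.index(a) for a in axes]
    for row, (lineno, tok) in enumerate(data_lines):
        if len(tok) != len(names):
            raise MeshFormatError(
                f"{path}: line {lineno}: expected {len(names)} vertex fields, "
                f"got {len(tok)}"
            )
        try:
            for j, k in enumerate(ix):
                out[row, j] = float(tok[k])
        except ValueError as exc:
            raise MeshFormatError(f"{path}: line {lineno}: {exc}") from None
    return out


def _ply_ascii_faces(path, props, data_lines) -> np.ndarray:
    if len(props) != 1 or props[0][0] != "list":
        raise MeshFormatError(f"{path}: face element must be a single list property")
    out = np.empty((len(data_lines), 3), dtype=np.int64)
    for row, (lineno, tok) in enumerate(data_lines):
        try:
            n = int(tok[0])
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}: line {lineno}: bad face line") from None
        if n != 3:
            raise MeshFormatError(
                f"{path}: line {lineno}: face with {n} vertices — triangles only"
            )
        if len(tok) != 4:
            raise MeshFormatError(f"{path}: line {lineno}: bad face line")
        out[row] = [int(t) for t in tok[1:4]]
    return out


def _ply_binary_vertices(path, props, count, fh) -> np.ndarray:
    dtype, axes = _vertex_prop_layout(path, props)
    buf = fh.read(dtype.itemsize * count)
    if len(buf) != dtype.itemsize * count:
        raise MeshFormatError(f"{path}: truncated vertex data")
    rec = np.frombuffer(buf, dtype=dtype)
    return np.stack([rec[a].astype(np.float64) for a in axes], axis=1)


def _ply_binary_faces(path, props, count, fh) -> np.ndarray:
    if len(props) != 1 or props[0][0] != "list":
        raise MeshFormatError(f"{path}: face element must be a single list property")
    _, ctype, itype, _name = props[0]
    cdt = np.dtype("<" + _PLY_DTYPES[ctype])
    idt = np.dtype("<" + _PLY_DTYPES[itype])
    out = np.empty((count, 3), dtype=np.int64)
    for row in range(count):
        cbuf = fh.read(cdt.itemsize)
        if len(cbuf) != cdt.itemsize:
            raise MeshFormatError(f"{path}: truncated face data at face {row}")
        n = int(np.frombuffer(cbuf, dtype=cdt)[0])
        if n != 3:
            raise MeshFormatError(
                f"{path}: face {row}: face with {n} vertices — triangles only"
            )
        ibuf = fh.read(idt.itemsize * 3)
        if len(ibuf) != idt.itemsize * 3:
            raise MeshFormatError(f"{path}: truncated face data at face {row}")
        out[row] = np.frombuffer(ibuf, dtype=idt).astype(np.int64)
    return out


def _ply_binary_skip(path, props, count, fh) -> None:
    for p in props:
        if p[0] == "list":
            raise MeshFormatError(f"{path}: cannot skip list-typed element")
    dtype = np.dtype([(p[2], "<" + _PLY_DTYPES[p[1]]) for p in props])
    fh.read(dtype.itemsize * count)


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshFormatError(f"{path}: line {lineno}: short vertex line")
                try:
                    verts.append([float(t) for t in tok[1:4]])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}: line {lineno}: {exc}") from None
            elif tok[0] == "f":
                refs = tok[1:]
                if len(refs) != 3:
                    raise MeshFormatError(
                        f"{path}: line {lineno}: face with {len(refs)} vertices — "
                        "triangles only"
                    )
                idx = []
                for r in refs:
                    head = r.split("/")[0]
                    i = int(head)
                    if i < 1:
                        raise MeshFormatError(
                            f"{path}: line {lineno}: non-positive OBJ index {i}"
                        )
                    idx.append(i - 1)  # OBJ is 1-based on disk
                faces.append(idx)
            # vn/vt/usemtl etc. ignored
    if not verts:
        raise MeshFormatError(f"{path}: no vertices found")
    return (np.asarray(verts, dtype=np.float64),
            np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _write_ply(mesh: SurfaceMesh, path: Path, binary: bool) -> None:
    storage = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {storage} 1.0\n"
        f"comment structure={mesh.structure_id} hemisphere={mesh.hemisphere} "
        f"subject={mesh.subject_id}\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            for f in mesh.faces:
                fh.write(struct.pack("<B3i", 3, *(int(i) for i in f)))
        else:
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def _write_obj(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# structure={mesh.structure_id} hemisphere={mesh.hemisphere} "
                 f"subject={mesh.subject_id}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

#: Areas below this floor (mm^2) are clamped so log-area ratios stay finite.
AREA_FLOOR = 1e-12


def triangle_areas(mesh: SurfaceMesh, return_degenerate_count: bool = False):
    """Per-face triangle areas in mm².

    Degenerate (near-zero-area) faces are floored at :data:`AREA_FLOOR`,
    counted, and logged — they signal data problems but must not poison a
    later log transform.
    """
    v = mesh.vertices
    f = mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    degenerate = int(np.count_nonzero(areas < AREA_FLOOR))
    if degenerate:
        logger.warning("%d degenerate face(s) floored at %g mm^2 (%s %s %s)",
                       degenerate, AREA_FLOOR, mesh.subject_id,
                       mesh.structure_id, mesh.hemisphere)
        areas = np.maximum(areas, AREA_FLOOR)
    if return_degenerate_count:
        return areas, degenerate
    return areas


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted unit vertex normals (used by the simulator)."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    vn = np.zeros_like(v)
    for j in range(3):
        np.add.at(vn, f[:, j], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    return vn / norms[:, None]


def vertex_face_rings(mesh: SurfaceMesh) -> list[np.ndarray]:
    """For each vertex, the indices of the faces incident to it (one-ring)."""
    rings: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for fi, face in enumerate(mesh.faces):
        for vi in face:
            rings[int(vi)].append(fi)
    return [np.asarray(r, dtype=np.int64) for r in rings]


def vertex_adjacency(mesh: SurfaceMesh) -> list[np.ndarray]:
    """For each vertex, the indices of its edge-connected neighbours."""
    adj: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        a, b, c = int(a), int(b), int(c)
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return [np.asarray(sorted(s), dtype=np.int64) for s in adj]


# ---------------------------------------------------------------------------
# Atlas bundle
# ---------------------------------------------------------------------------


@dataclass
class AtlasTemplate:
    """Per-structure/hemisphere template meshes with L↔R correspondence.

    ``lr_map[structure][i]`` gives the right-hemisphere vertex index
    corresponding to left-hemisphere vertex ``i``. ``vertex_coords`` holds
    the template-space coordinates used for searchlight distances, keyed by
    ``(structure, hemisphere)``; it defaults to the template mesh vertices.
    """

    meshes: dict[tuple[str, str], SurfaceMesh]
    lr_map: dict[str, np.ndarray]
    vertex_coords: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for key, mesh in self.meshes.items():
            self.vertex_coords.setdefault(key, mesh.vertices)

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.meshes}))

    def n_vertices(self, structure: str) -> int:
        return self.meshes[(structure, "L")].n_vertices

    def validate(self) -> "AtlasTemplate":
        for structure in self.structures:
            left = self.meshes.get((structure, "L"))
            right = self.meshes.get((structure, "R"))
            if left is None or right is None:
                raise MeshValidationError(f"{structure}: missing hemisphere mesh")
            left.validate()
            right.validate()
            if left.n_vertices != right.n_vertices:
                raise MeshValidationError(f"{structure}: L/R vertex counts differ")
            lr = np.asarray(self.lr_map[structure])
            if sorted(lr.tolist()) != list(range(left.n_vertices)):
                raise MeshValidationError(f"{structure}: lr_map is not a bijection")
        return self

    def checksum(self) -> str:
        """SHA-256 over template vertex coordinates; guards cross-site alignment."""
        h = hashlib.sha256()
        for key in sorted(self.meshes):
            h.update(np.ascontiguousarray(self.meshes[key].vertices).tobytes())
            h.update(np.ascontiguousarray(self.meshes[key].faces).tobytes())
        return h.hexdigest()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "structures": {},
            "provenance": self.provenance,
            "checksum": self.checksum(),
        }
        for (structure, hemi), mesh in sorted(self.meshes.items()):
            fname = f"{structure}_{hemi}.ply"
            write_mesh(mesh, directory / fname, binary=False)
            manifest["structures"].setdefault(structure, {})[hemi] = fname
        for structure, lr in self.lr_map.items():
            manifest["structures"][structure]["lr_map"] = np.asarray(lr).tolist()
        with open(directory / "atlas.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, directory: str | Path) -> "AtlasTemplate":
        directory = Path(directory)
        with open(directory / "atlas.json", "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
        meshes: dict[tuple[str, str], SurfaceMesh] = {}
        lr_map: dict[str, np.ndarray] = {}
        for structure, entry in manifest["structures"].items():
            for hemi in HEMISPHERES:
                meshes[(structure, hemi)] = read_mesh(
                    directory / entry[hemi],
                    structure_id=structure, hemisphere=hemi, subject_id="template",
                )
            lr_map[structure] = np.asarray(entry["lr_map"], dtype=np.int64)
        atlas = cls(meshes=meshes, lr_map=lr_map,
                    provenance=manifest.get("provenance", ""))
        return atlas.validate()


class Neighborhoods:
    """Searchlight neighbourhoods on the atlas.

    ``by_region[(structure, hemisphere)][v]`` is the sorted integer array of
    same-structure vertex indices within ``radius`` mm of vertex ``v``
    (always including ``v`` itself). Vertices of different structures are at
    infinite distance by construction: no neighbourhood ever crosses a
    region boundary.
    """

    def __init__(self, by_region: dict, radius: float):
        self.by_region = by_region
        self.radius = float(radius)

    def __getitem__(self, key):
        return self.by_region[key]

    def regions(self):
        return sorted(self.by_region)


def vertex_neighborhoods(atlas: AtlasTemplate, radius: float) -> Neighborhoods:
    """Compute per-vertex searchlight neighbourhoods within one structure.

    Distance is the Euclidean distance between template-space atlas vertex
    coordinates; vertices of different structures (or hemispheres) are
    treated as infinitely far apart.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    by_region: dict[tuple[str, str], list[np.ndarray]] = {}
    for key, coords in atlas.vertex_coords.items():
        tree = cKDTree(coords)
        lists = tree.query_ball_point(coords, r=radius)
        by_region[key] = [np.asarray(sorted(lst), dtype=np.int64) for lst in lists]
    return Neighborhoods(by_region, radius)


# ---------------------------------------------------------------------------
# Covariate tables
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """One row of the covariate table.

    ``dx`` is 0 for controls and 1 for patients; ``sex`` uses the {0, 1}
    coding declared in the run configuration and applied uniformly across
    sites. ``cpz`` (chlorpromazine dose equivalents, mg/day) and
    ``saps_total`` are optional and flagged missing with ``None`` — never
    imputed.
    """

    subject_id: str
    site_id: str
    dx: int
    age: float
    sex: int
    icv: float
    cpz: float | None = None
    saps_total: float | None = None

    def validate(self) -> "SubjectRecord":
        if self.dx not in (0, 1):
            raise ValueError(f"{self.subject_id}: dx must be 0 or 1, got {self.dx}")
        if self.sex not in (0, 1):
            raise ValueError(f"{self.subject_id}: sex must be 0 or 1, got {self.sex}")
        if not (self.age > 0):
            raise ValueError(f"{self.subject_id}: age must be positive")
        if not (self.icv > 0):
            raise ValueError(f"{self.subject_id}: icv must be positive")
        return self


DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "site_id": "site_id",
    "dx": "dx",
    "age": "age",
    "sex": "sex",
    "icv": "icv",
    "cpz": "cpz",
    "saps_total": "saps_total",
}


def read_covariates(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    sep: str | None = None) -> list[SubjectRecord]:
    """Read a delimited covariate table into validated records.

    The delimiter is inferred from the extension (.tsv → tab, otherwise
    comma) unless given. Missing optional fields (empty cells in the cpz /
    saps columns, or absent columns) become ``None``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype={cols["subject_id"]: str, cols["site_id"]: str})
    required = ["subject_id", "site_id", "dx", "age", "sex", "icv"]
    for key in required:
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[key]!r}")
    records = []
    for _, row in df.iterrows():
        def opt(key):
            name = cols[key]
            if name not in df.columns or pd.isna(row[name]):
                return None
            return float(row[name])

        records.append(SubjectRecord(
            subject_id=str(row[cols["subject_id"]]),
            site_id=str(row[cols["site_id"]]),
            dx=int(row[cols["dx"]]),
            age=float(row[cols["age"]]),
            sex=int(row[cols["sex"]]),
            icv=float(row[cols["icv"]]),
            cpz=opt("cpz"),
            saps_total=opt("saps_total"),
        ).validate())
    return records


def write_covariates(records: Sequence[SubjectRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame([{
        "subject_id": r.subject_id, "site_id": r.site_id, "dx": r.dx,
        "age": r.age, "sex": r.sex, "icv": r.icv,
        "cpz": "" if r.cpz is None else r.cpz,
        "saps_total": "" if r.saps_total is None else r.saps_total,
    } for r in records])
    df.to_csv(path, sep=sep, index=False)
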