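"""Triangulated surface meshes: data model, OBJ/GIFTI I/O, and geometric primitives.

All coordinates are in millimetres. Vertex indices are 0-based internally;
the OBJ reader/writer converts from/to the format's 1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceMesh",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "edge_list",
    "edge_lengths",
    "mean_edge_length",
    "triangle_areas",
    "total_area",
    "vertex_neighbors",
    "validate_mesh",
]

_MIN_TRIANGLE_AREA = 1e-12  # mm^2


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed."""


class MeshValidationError(ValueError):
    """Raised when a mesh violates structural invariants."""


@dataclass
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    triangles : (F, 3) int array
        Vertex-index triples, 0-based.
    name : str, optional
        Free-text label carried through I/O.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def n_edges(self) -> int:
        return edge_list(self).shape[0]

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    def validate(self) -> "ValidationReport":
        return validate_mesh(self)


@dataclass
class ValidationReport:
    """Outcome of structural mesh checks; collects violations instead of raising."""

    passed: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_mesh(mesh: SurfaceMesh) -> ValidationReport:
    """Check all SurfaceMesh invariants and report each violation with indices."""
    violations: list[str] = []
    V = mesh.n_vertices
    tri = mesh.triangles
    if V == 0:
        violations.append("mesh has no vertices")
    if tri.size:
        bad = np.where((tri < 0) | (tri >= V))[0]
        if bad.size:
            violations.append(
                f"triangles with out-of-range vertex index: {bad.tolist()}"
            )
        else:
            rep = np.where(
                (tri[:, 0] == tri[:, 1])
                | (tri[:, 1] == tri[:, 2])
                | (tri[:, 0] == tri[:, 2])
            )[0]
            if rep.size:
                violations.append(f"triangles with repeated vertex: {rep.tolist()}")
            areas = triangle_areas(mesh)
            degen = np.where(areas <= _MIN_TRIANGLE_AREA)[0]
            degen = np.setdiff1d(degen, rep)
            if degen.size:
                violations.append(f"zero-area triangles: {degen.tolist()}")
    if not np.isfinite(mesh.vertices).all():
        violations.append("non-finite vertex coordinates")
    return ValidationReport(passed=not violations, violations=violations)


def _require_valid(mesh: SurfaceMesh) -> None:
    report = validate_mesh(mesh)
    if not report:
        raise MeshValidationError("; ".join(report.violations))


def edge_list(mesh: SurfaceMesh) -> np.ndarray:
    """Unique undirected edges as an (E, 2) array of (low, high) vertex pairs."""
    tri = mesh.triangles
    if tri.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    e = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def edge_lengths(mesh: SurfaceMesh, edges: np.ndarray | None = None) -> np.ndarray:
    if edges is None:
        edges = edge_list(mesh)
    d = mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]]
    return np.linalg.norm(d, axis=1)


def mean_edge_length(mesh: SurfaceMesh) -> float:
    return float(edge_lengths(mesh).mean())


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-triangle areas in mm^2 (half cross-product magnitude)."""
    p = mesh.vertices[mesh.triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def total_area(mesh: SurfaceMesh) -> float:
    """Total surface area in mm^2 — the search-space area for resel counting."""
    return float(triangle_areas(mesh).sum())


def vertex_neighbors(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Adjacency: for each vertex, the sorted array of its one-ring neighbours."""
    edges = edge_list(mesh)
    both = np.concatenate([edges, edges[:, ::-1]])
    order = np.argsort(both[:, 0], kind="stable")
    both = both[order]
    splits = np.searchsorted(both[:, 0], np.arange(1, mesh.n_vertices))
    return [np.sort(a) for a in np.split(both[:, 1], splits)]


# ---------------------------------------------------------------------------
# I/O

def _read_obj(path: str) -> SurfaceMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex line")
                try:
                    verts.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
            elif tag == "f":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: face needs 3 vertices")
                try:
                    # OBJ faces are 1-based and may carry /vt/vn suffixes
                    idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
                faces.append(idx)
            # vn/vt/usemtl etc. ignored
    if not verts:
        raise MeshFormatError(f"{path}: no vertices found")
    mesh = SurfaceMesh(np.array(verts), np.array(faces).reshape(-1, 3))
    _require_valid(mesh)
    return mesh


def _write_obj(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        if mesh.name:
            fh.write(f"# {mesh.name}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def _read_gifti(path: str) -> SurfaceMesh:
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "GIFTI support requires nibabel (install the 'gifti' extra)"
        ) from exc
    img = nib.load(path)
    coords = tris = None
    for arr in img.darrays:
        intent = arr.intent
        if intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(arr.data, dtype=np.float64)
        elif intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(arr.data, dtype=np.int64)
    if coords is None or tris is None:
        raise MeshFormatError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    mesh = SurfaceMesh(coords, tris)
    _require_valid(mesh)
    return mesh


def _write_gifti(mesh: SurfaceMesh, path: str) -> None:
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "GIFTI support requires nibabel (install the 'gifti' extra)"
        ) from exc
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), path)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    return "gifti" if p.endswith((".gii", ".surf.gii")) else "obj"


def read_mesh(path: str, format: str | None = None) -> SurfaceMesh:
    """Read and validate a surface mesh from OBJ or GIFTI.

    Vertex order is preserved from the file. OBJ face indices are converted
    from the 1-based file convention to 0-based.
    """
    fmt = _infer_format(path, format)
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "gifti":
        return _read_gifti(path)
    raise ValueError(f"unknown mesh format: {fmt!r}")


def write_mesh(mesh: SurfaceMesh, path: str, format: str | None = None) -> str:
    """Write a mesh; round-trip through :func:`read_mesh` preserves topology
    exactly and coordinates to better than 1e-6 mm."""
    if mesh.n_vertices == 0 or mesh.n_triangles == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    _require_valid(mesh)
    fmt = _infer_format(path, format)
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "gifti":
        _write_gifti(mesh, path)
    else:
        raise ValueError(f"unknown mesh format: {fmt!r}")
    return str(path)
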