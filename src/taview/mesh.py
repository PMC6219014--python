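"""Synthetic heart/torso surface meshes, electrode placement and validation.

All geometry is triangulated closed surfaces in a right-handed coordinate
frame, millimetre units, torso centroid at the origin.  The heart is a pair of
closed ellipsoidal lobes (upper lobe = atria, lower lobe = ventricles) sitting
inside an ellipsoidal torso; this parametric stand-in replaces patient imaging
because the downstream inversion treats all geometry as uncertain and
estimates a lead-field error term anyway.

Region labels are small integers (`ATRIAL`, `VENTRICULAR`, `TORSO`), one per
vertex.  A vertex of the heart is ATRIAL iff its z-coordinate is >= the lobe
junction plane (ties go to the atria).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, GeometryError, InvalidArgumentError

ATRIAL = 0
VENTRICULAR = 1
TORSO = 2
LABEL_NAMES = {ATRIAL: "ATRIAL", VENTRICULAR: "VENTRICULAR", TORSO: "TORSO"}

#: Electrode layout for the 8 independent channels of the 12-lead system:
#: (name, azimuth in degrees measured from +x (anterior) toward +y (left),
#: height as a fraction of the torso z-extent).  The limb channels I and II
#: are represented by single equivalent surface electrodes; V1-V6 sweep the
#: precordium.  These fractions are configuration constants, not anatomy.
ELECTRODE_LAYOUT: tuple[tuple[str, float, float], ...] = (
    ("I", 110.0, 0.88),
    ("II", 235.0, 0.10),
    ("V1", -12.0, 0.62),
    ("V2", 12.0, 0.62),
    ("V3", 27.0, 0.60),
    ("V4", 42.0, 0.58),
    ("V5", 62.0, 0.58),
    ("V6", 82.0, 0.58),
)

# Default lobe geometry relative to `scale_mm` (semi-axes and centre offsets).
_ATRIAL_AXES = (0.42, 0.38, 0.32)
_ATRIAL_CENTER_Z = 0.40
_VENTRICULAR_AXES = (0.50, 0.45, 0.55)
_VENTRICULAR_CENTER_Z = -0.62
_JUNCTION_Z_FRAC = 0.05  # junction plane, in units of scale_mm


@dataclasses.dataclass(frozen=True)
class TriSurfaceMesh:
    """Closed triangulated surface with per-vertex region labels.

    Attributes
    ----------
    vertices : (n, 3) float array, mm.
    triangles : (m, 3) int array; counter-clockwise seen from outside, so
        triangle normals point away from the component centroid.
    region_label : (n,) int array with values in {ATRIAL, VENTRICULAR, TORSO}.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region_label: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        lab = np.asarray(self.region_label, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidArgumentError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise InvalidArgumentError("triangles must be (m, 3)")
        if lab.shape != (v.shape[0],):
            raise InvalidArgumentError("region_label must have one entry per vertex")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise InvalidArgumentError("triangle indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        object.__setattr__(self, "region_label", lab)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(norms > 0, norms, 1.0)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        fn = self.triangle_normals(normalized=False)  # area-weighted
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], fn)
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        return out / np.where(norms > 0, norms, 1.0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric patch area per vertex: one third of incident triangle areas."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], areas / 3.0)
        return out

    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs, shape (n_edges, 2)."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def vertex_components(self) -> tuple[int, np.ndarray]:
        """Connected components over the edge graph -> (count, labels)."""
        e = self.edges()
        n = self.n_vertices
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        return connected_components(adj, directed=False)


@dataclasses.dataclass(frozen=True)
class ElectrodeSet:
    """The 8 independent measurement channels of the standard 12-lead system."""

    names: tuple[str, ...]
    positions: np.ndarray  # (8, 3) mm, on the torso surface
    nearest_vertex: np.ndarray  # (8,) torso vertex indices

    def __post_init__(self) -> None:
        if len(self.names) != 8:
            raise InvalidArgumentError("exactly 8 electrodes required")
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(
            self, "nearest_vertex", np.asarray(self.nearest_vertex, dtype=np.int64)
        )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral lattice); deterministic."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _ellipsoid_mesh(n: int, semi_axes: Sequence[float], center: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Closed triangulated ellipsoid with exactly n vertices, outward CCW."""
    from scipy.spatial import ConvexHull

    if n < 4:
        raise InvalidArgumentError(f"need >= 4 vertices to triangulate, got {n}")
    pts = _fibonacci_sphere(n) * np.asarray(semi_axes, dtype=float)
    hull = ConvexHull(pts)
    tris = hull.simplices.copy()
    # orient every triangle outward (normal away from the centroid)
    centroid = pts.mean(axis=0)
    v = pts[tris]
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    face_centers = v.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, face_centers - centroid) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return pts + np.asarray(center, dtype=float), tris


def build_synthetic_heart(
    n_atrial_nodes: int, n_ventricular_nodes: int, scale_mm: float = 60.0
) -> TriSurfaceMesh:
    """Two-lobe heart surface: atrial ellipsoid above a ventricular ellipsoid.

    The lobes are adjacent closed components separated by the junction plane
    z = `_JUNCTION_Z_FRAC` * scale_mm; vertices with z >= the plane are
    labelled ATRIAL, the rest VENTRICULAR.
    """
    if n_atrial_nodes < 4 or n_ventricular_nodes < 4:
        raise InvalidArgumentError("node counts must be >= 4 to triangulate a lobe")
    s = float(scale_mm)
    va, ta = _ellipsoid_mesh(
        n_atrial_nodes, np.array(_ATRIAL_AXES) * s, (0.0, 0.0, _ATRIAL_CENTER_Z * s)
    )
    vv, tv = _ellipsoid_mesh(
        n_ventricular_nodes,
        np.array(_VENTRICULAR_AXES) * s,
        (0.0, 0.0, _VENTRICULAR_CENTER_Z * s),
    )
    vertices = np.vstack([va, vv])
    triangles = np.vstack([ta, tv + len(va)])
    junction_z = _JUNCTION_Z_FRAC * s
    labels = np.where(vertices[:, 2] >= junction_z, ATRIAL, VENTRICULAR)
    return TriSurfaceMesh(vertices, triangles, labels)


def build_synthetic_torso(n_nodes: int, scale_mm: float = 300.0) -> TriSurfaceMesh:
    """Closed ellipsoidal torso surface, centred at the origin, all TORSO."""
    if n_nodes < 4:
        raise InvalidArgumentError("node count must be >= 4 to triangulate the torso")
    s = float(scale_mm)
    v, t = _ellipsoid_mesh(n_nodes, (0.55 * s, 0.40 * s, 1.0 * s), (0.0, 0.0, 0.0))
    return TriSurfaceMesh(v, t, np.full(len(v), TORSO, dtype=np.int64))


# ---------------------------------------------------------------------------
# geometric queries
# ---------------------------------------------------------------------------


def solid_angles(mesh: TriSurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Winding number (total signed solid angle / 4pi) of each query point.

    Uses the van Oosterom-Strackee formula per triangle; ~1 inside a closed
    outward-oriented surface, ~0 outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.triangles]  # (m, 3, 3)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", np.cross(a, b), c)
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", a, c) * lb
        )
        out[i] = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
    return out


def points_inside(mesh: TriSurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Boolean inside test for a closed outward-oriented mesh."""
    return solid_angles(mesh, points) > 0.5


def place_standard_electrodes(torso: TriSurfaceMesh) -> ElectrodeSet:
    """Place the 8 independent channels at fixed fractional torso coordinates.

    For each (azimuth, height-fraction) entry of `ELECTRODE_LAYOUT` a
    horizontal ray is cast from the torso axis and intersected with the
    surface; the electrode sits at the intersection and is attached to its
    nearest torso vertex.  Deterministic for a given mesh, and equivariant
    under rigid translation of the mesh.
    """
    if not np.all(torso.region_label == TORSO):
        raise InvalidArgumentError("torso mesh must be labelled TORSO")
    v = torso.vertices
    lo, hi = v[:, 2].min(), v[:, 2].max()
    extent = np.ptp(v, axis=0)
    if np.any(extent <= 0):
        raise GeometryError("degenerate torso: zero extent along an axis")
    axis_xy = v[:, :2].mean(axis=0)
    names, positions, nearest = [], [], []
    for name, az_deg, h_frac in ELECTRODE_LAYOUT:
        z = lo + h_frac * (hi - lo)
        origin = np.array([axis_xy[0], axis_xy[1], z])
        az = np.deg2rad(az_deg)
        direction = np.array([np.cos(az), np.sin(az), 0.0])
        hit = _ray_surface_intersection(torso, origin, direction)
        idx = int(np.argmin(np.linalg.norm(v - hit, axis=1)))
        names.append(name)
        positions.append(hit)
        nearest.append(idx)
    return ElectrodeSet(tuple(names), np.array(positions), np.array(nearest))


def _ray_surface_intersection(
    mesh: TriSurfaceMesh, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Farthest intersection of a ray with the mesh (Moller-Trumbore, vectorized)."""
    tri = mesh.vertices[mesh.triangles]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    vpar = q @ direction * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hitmask = ok & (u >= -1e-9) & (vpar >= -1e-9) & (u + vpar <= 1 + 1e-9) & (t > 0)
    if not np.any(hitmask):
        raise GeometryError("electrode ray does not intersect the torso surface")
    tmax = t[hitmask].max()
    return origin + tmax * direction


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MeshReport:
    """Pure diagnostic report; never raises."""

    n_vertices: int
    n_edges: int
    n_triangles: int
    n_components: int
    is_manifold: bool
    boundary_edge_count: int
    euler_characteristics: tuple[int, ...]
    signed_volumes: tuple[float, ...]
    orientation_ok: bool
    label_counts: dict[str, int]
    labels_ok: bool

    @property
    def passed(self) -> bool:
        return (
            self.is_manifold
            and self.orientation_ok
            and self.labels_ok
            and all(chi == 2 for chi in self.euler_characteristics)
        )


def validate_mesh(mesh: TriSurfaceMesh) -> MeshReport:
    """Check closedness, orientation, Euler characteristic and label coverage."""
    t = mesh.triangles
    e_all = np.sort(
        np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
    )
    e_unique, counts = np.unique(e_all, axis=0, return_counts=True)
    boundary = int(np.sum(counts == 1))
    manifold = bool(np.all(counts == 2))

    n_comp, comp = mesh.vertex_components()
    chis, vols = [], []
    tri_comp = comp[t[:, 0]]
    for c in range(n_comp):
        nv = int(np.sum(comp == c))
        tri_mask = tri_comp == c
        nf = int(np.sum(tri_mask))
        ne = int(np.sum(comp[e_unique[:, 0]] == c))
        chis.append(nv - ne + nf)
        tc = mesh.vertices[t[tri_mask]]
        vols.append(
            float(np.sum(np.einsum("ij,ij->i", np.cross(tc[:, 0], tc[:, 1]), tc[:, 2])) / 6.0)
        )
    labels = mesh.region_label
    label_counts = {
        name: int(np.sum(labels == code)) for code, name in LABEL_NAMES.items()
    }
    labels_ok = bool(np.all(np.isin(labels, list(LABEL_NAMES))))
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_edges=len(e_unique),
        n_triangles=mesh.n_triangles,
        n_components=n_comp,
        is_manifold=manifold,
        boundary_edge_count=boundary,
        euler_characteristics=tuple(chis),
        signed_volumes=tuple(vols),
        orientation_ok=bool(all(v > 0 for v in vols)),
        label_counts=label_counts,
        labels_ok=labels_ok,
    )


# ---------------------------------------------------------------------------
# OFF / PLY ASCII I/O (labelled dialects)
# ---------------------------------------------------------------------------


def write_mesh(path: str | Path, mesh: TriSurfaceMesh) -> None:
    """Write labelled ASCII OFF (.off) or PLY (.ply); label as a vertex column."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        _write_off(path, mesh)
    elif path.suffix.lower() == ".ply":
        _write_ply(path, mesh)
    else:
        raise FormatError(f"unknown mesh extension {path.suffix!r} (use .off or .ply)")


def read_mesh(path: str | Path, labels_path: str | Path | None = None) -> TriSurfaceMesh:
    """Read labelled ASCII OFF/PLY; label-free files need a sidecar label file."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        v, t, lab = _read_off(path)
    elif path.suffix.lower() == ".ply":
        v, t, lab = _read_ply(path)
    else:
        raise FormatError(f"unknown mesh extension {path.suffix!r} (use .off or .ply)")
    if lab is None:
        if labels_path is None:
            raise FormatError(
                f"{path.name}: no label column and no label file supplied"
            )
        lab = np.loadtxt(labels_path, dtype=np.int64, ndmin=1)
        if lab.shape != (len(v),):
            raise FormatError("label file length does not match vertex count")
    return TriSurfaceMesh(v, t, lab)


def _write_off(path: Path, mesh: TriSurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for p, lab in zip(mesh.vertices, mesh.region_label):
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {int(lab)}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def _read_off(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    tokens_lines = [
        ln.split("#")[0].split()
        for ln in path.read_text().splitlines()
    ]
    tokens_lines = [t for t in tokens_lines if t]
    if not tokens_lines or tokens_lines[0][0] != "OFF":
        raise FormatError(f"{path.name}: missing OFF header")
    header = tokens_lines[1] if len(tokens_lines[0]) == 1 else tokens_lines[0][1:]
    body = tokens_lines[2:] if len(tokens_lines[0]) == 1 else tokens_lines[1:]
    try:
        nv, nf = int(header[0]), int(header[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path.name}: bad OFF count line") from exc
    if len(body) < nv + nf:
        raise FormatError(f"{path.name}: truncated OFF file")
    vrows = body[:nv]
    ncols = len(vrows[0])
    if ncols not in (3, 4) or any(len(r) != ncols for r in vrows):
        raise FormatError(f"{path.name}: vertex rows must have 3 or 4 columns")
    v = np.array([[float(x) for x in r[:3]] for r in vrows])
    lab = np.array([int(r[3]) for r in vrows]) if ncols == 4 else None
    tris = []
    for r in body[nv : nv + nf]:
        if int(r[0]) != 3:
            raise FormatError(f"{path.name}: only triangle faces are supported")
        tris.append([int(x) for x in r[1:4]])
    return v, np.array(tris, dtype=np.int64), lab


def _write_ply(path: Path, mesh: TriSurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property int region\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, lab in zip(mesh.vertices, mesh.region_label):
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {int(lab)}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path.name}: missing ply magic")
    nv = nf = None
    vprops: list[str] = []
    in_vertex = False
    i = 1
    for i, ln in enumerate(lines[1:], start=1):
        tok = ln.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise FormatError(f"{path.name}: only ASCII PLY is supported")
        if tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if tok[1] == "vertex":
                nv = int(tok[2])
            elif tok[1] == "face":
                nf = int(tok[2])
        elif tok[0] == "property" and in_vertex and tok[1] != "list":
            vprops.append(tok[2])
        elif tok[0] == "end_header":
            break
    if nv is None or nf is None:
        raise FormatError(f"{path.name}: PLY header lacks vertex/face elements")
    body = [ln.split() for ln in lines[i + 1 :] if ln.split()]
    if len(body) < nv + nf:
        raise FormatError(f"{path.name}: truncated PLY file")
    try:
        ix, iy, iz = (vprops.index(c) for c in ("x", "y", "z"))
    except ValueError as exc:
        raise FormatError(f"{path.name}: PLY vertices lack x/y/z") from exc
    v = np.array([[float(r[j]) for j in (ix, iy, iz)] for r in body[:nv]])
    lab = None
    if "region" in vprops:
        ir = vprops.index("region")
        lab = np.array([int(r[ir]) for r in body[:nv]])
    tris = []
    for r in body[nv : nv + nf]:
        if int(r[0]) != 3:
            raise FormatError(f"{path.name}: only triangle faces are supported")
        tris.append([int(x) for x in r[1:4]])
    return v, np.array(tris, dtype=np.int64), lab
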