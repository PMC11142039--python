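"""Triangle-mesh geometry for layered head phantoms.

Meshes are watertight, outward-oriented triangle surfaces stored as plain
vertex/face arrays (SI units, meters).  Per-facet quantities — centroid,
outward unit normal, area — are what the collocation BEM solver consumes:
the facet centroids are the collocation points, the areas weight the
piecewise-constant surface charge.

Selective 4-way subdivision may leave hanging (T-junction) vertices.  This
is deliberate: a facet-collocation solver does not require a conforming
mesh, and the refinement scheme replaces a triangle by its four congruent
midpoint children without touching the neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriangleMesh",
    "MeshGeometryError",
    "icosphere",
    "facet_geometry",
    "subdivide_facets",
    "read_mesh",
    "write_mesh",
]


class MeshGeometryError(ValueError):
    """Raised for degenerate or inconsistently oriented mesh geometry."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface with cached per-facet geometry.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in meters.
    faces : (F, 3) int array
        Vertex index triples, counter-clockwise seen from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _centroids: np.ndarray | None = field(default=None, repr=False)
    _normals: np.ndarray | None = field(default=None, repr=False)
    _areas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshGeometryError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshGeometryError("faces must be an (F, 3) array")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshGeometryError("faces reference out-of-range vertex indices")

    # -- basic quantities -------------------------------------------------

    @property
    def n_facets(self) -> int:
        return len(self.faces)

    def _compute_geometry(self) -> None:
        v = self.vertices
        f = self.faces
        p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        cross = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(cross, axis=1)
        bad = np.flatnonzero(norm <= 0.0)
        if bad.size:
            raise MeshGeometryError(f"degenerate (zero-area) facet at index {bad[0]}")
        self._areas = 0.5 * norm
        self._normals = cross / norm[:, None]
        self._centroids = (p0 + p1 + p2) / 3.0

    @property
    def facet_centroid(self) -> np.ndarray:
        if self._centroids is None:
            self._compute_geometry()
        return self._centroids

    @property
    def facet_normal(self) -> np.ndarray:
        if self._normals is None:
            self._compute_geometry()
        return self._normals

    @property
    def facet_area(self) -> np.ndarray:
        if self._areas is None:
            self._compute_geometry()
        return self._areas

    @property
    def total_area(self) -> float:
        return float(self.facet_area.sum())

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive for outward orientation."""
        v = self.vertices
        f = self.faces
        return float(
            np.einsum(
                "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
            ).sum()
            / 6.0
        )

    def is_closed(self, tol: float = 1e-9) -> bool:
        """Divergence-theorem closure check: sum of area-weighted normals."""
        resid = np.linalg.norm((self.facet_area[:, None] * self.facet_normal).sum(0))
        return resid <= tol * self.total_area

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def contains(self, points) -> np.ndarray:
        """Point-in-closed-surface test by the generalized winding number.

        Sums the signed solid angles (van Oosterom–Strackee) of all facets
        at each query point: ~4π inside, ~0 outside.  Exact for any closed
        oriented surface; points on the surface are not well-defined and
        classify by the 2π threshold.
        """
        points = np.atleast_2d(np.asarray(points, float))
        v = self.vertices
        f = self.faces
        winding = np.empty(len(points))
        chunk = max(1, int(4e6 // max(len(f), 1)))
        for s in range(0, len(points), chunk):
            p = points[s : s + chunk]
            r1 = v[f[:, 0]][None] - p[:, None]
            r2 = v[f[:, 1]][None] - p[:, None]
            r3 = v[f[:, 2]][None] - p[:, None]
            n1 = np.linalg.norm(r1, axis=2)
            n2 = np.linalg.norm(r2, axis=2)
            n3 = np.linalg.norm(r3, axis=2)
            det = np.einsum("pfk,pfk->pf", r1, np.cross(r2, r3))
            denom = (
                n1 * n2 * n3
                + np.einsum("pfk,pfk->pf", r1, r2) * n3
                + np.einsum("pfk,pfk->pf", r1, r3) * n2
                + np.einsum("pfk,pfk->pf", r2, r3) * n1
            )
            winding[s : s + chunk] = 2.0 * np.arctan2(det, denom).sum(axis=1)
        return winding > 2.0 * np.pi

    def typical_edge_length(self) -> np.ndarray:
        """Per-facet length scale (edge of the equal-area equilateral triangle)."""
        return np.sqrt(self.facet_area * 4.0 / np.sqrt(3.0))


def facet_geometry(mesh: TriangleMesh) -> TriangleMesh:
    """Force (re)computation of centroids, normals and areas.

    Returns the same mesh for chaining; raises :class:`MeshGeometryError`
    naming the first degenerate facet if any triangle has zero area.
    """
    mesh._compute_geometry()
    return mesh


# -- generation -----------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def icosphere(
    radius: float, n_subdiv: int = 0, center: np.ndarray | None = None
) -> TriangleMesh:
    """Geodesic sphere: subdivided icosahedron projected onto the sphere.

    Produces ``20 * 4**n_subdiv`` near-uniform facets, outward oriented.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if n_subdiv < 0:
        raise ValueError(f"n_subdiv must be >= 0, got {n_subdiv}")
    verts, faces = _icosahedron()
    for _ in range(n_subdiv):
        verts, faces = _subdivide_all_conforming(verts, faces)
        # re-project after every level so children stay on the sphere
        verts /= np.linalg.norm(verts, axis=1)[:, None]
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    verts = verts * radius
    if center is not None:
        verts = verts + np.asarray(center, dtype=np.float64)
    return TriangleMesh(verts, faces)


def _subdivide_all_conforming(
    verts: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Global midpoint subdivision with shared (conforming) edge vertices."""
    edge_mid: dict[tuple[int, int], int] = {}
    new_verts = [v for v in verts]

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = edge_mid.get(key)
        if idx is None:
            idx = len(new_verts)
            new_verts.append((verts[a] + verts[b]) / 2.0)
            edge_mid[key] = idx
        return idx

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces[4 * i : 4 * i + 4] = [
            [a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca],
        ]
    return np.asarray(new_verts), new_faces


def subdivide_facets(mesh: TriangleMesh, facet_indices) -> TriangleMesh:
    """Replace each selected facet by its four congruent midpoint children.

    Unselected facets are untouched and keep their relative order, followed
    by the children (4 per selected facet, replacing the parent in place is
    not attempted).  The result may be non-conforming: midpoint vertices are
    not shared with neighbouring unselected facets.  Planar facet area is
    conserved exactly.
    """
    idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(facet_indices))), dtype=np.int64)
    if idx.size == 0:
        return mesh.copy()
    if idx.min() < 0 or idx.max() >= mesh.n_facets:
        raise IndexError(
            f"facet index out of range: {idx.max() if idx.max() >= mesh.n_facets else idx.min()}"
        )
    v = mesh.vertices
    f = mesh.faces
    sel = f[idx]
    p0, p1, p2 = v[sel[:, 0]], v[sel[:, 1]], v[sel[:, 2]]
    m01 = (p0 + p1) / 2.0
    m12 = (p1 + p2) / 2.0
    m20 = (p2 + p0) / 2.0
    nv = len(v)
    k = len(idx)
    new_verts = np.vstack([v, m01, m12, m20])
    i01 = nv + np.arange(k)
    i12 = nv + k + np.arange(k)
    i20 = nv + 2 * k + np.arange(k)
    children = np.empty((4 * k, 3), dtype=np.int64)
    children[0::4] = np.column_stack([sel[:, 0], i01, i20])
    children[1::4] = np.column_stack([i01, sel[:, 1], i12])
    children[2::4] = np.column_stack([i20, i12, sel[:, 2]])
    children[3::4] = np.column_stack([i01, i12, i20])
    keep = np.ones(mesh.n_facets, dtype=bool)
    keep[idx] = False
    new_faces = np.vstack([f[keep], children])
    return TriangleMesh(new_verts, new_faces)


# -- I/O ------------------------------------------------------------------

_FORMATS = ("stl", "ply", "off")


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, fmt: str | None = None, reorient: bool = True) -> TriangleMesh:
    """Load an STL / PLY / OFF surface.

    Meshes are auto-reoriented so that the signed volume is positive
    (outward orientation) when ``reorient`` is set; a flipped file is
    therefore accepted silently but consistently.
    """
    fmt = _format_from_path(path, fmt)
    try:
        tm = _trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises heterogeneous parse errors
        raise MeshGeometryError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not hasattr(tm, "faces") or len(getattr(tm, "faces", ())) == 0:
        raise MeshGeometryError(f"no triangles found in {path} (empty or malformed file)")
    mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    if reorient and mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write an STL (binary), PLY (ascii) or OFF surface."""
    fmt = _format_from_path(path, fmt)
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = tm.export(file_type=fmt, **kwargs)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
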