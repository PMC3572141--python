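"""Cortical surface representation and graph machinery.

The distributed source model fixes one current dipole per vertex of a
triangulated cortical mesh, oriented along the local surface normal.  This
module carries the mesh container (:class:`TriSurface`), the edge-graph
adjacency used by the region-growing and smoothness machinery, geodesic
distances along the mesh, and a synthetic two-hemisphere cortex generator
used when no segmented anatomy is available.

Conventions
-----------
* positions are in mm, head-centered (origin = head center);
* vertex indices are 0-based everywhere;
* the two hemispheres are disconnected components of the edge graph, so no
  parcel, patch or geodesic path ever crosses the midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
import trimesh

__all__ = [
    "TriSurface",
    "Adjacency",
    "build_adjacency",
    "grow_patch",
    "geodesic_dist",
    "geodesic_from",
    "eccentricity",
    "synth_cortex",
    "UNREACHABLE",
]

#: Sentinel for a geodesic distance between hemispheres (never a large
#: finite number; batch-max substitution happens only in metric aggregation).
UNREACHABLE = np.inf

LEFT, RIGHT = "left", "right"


@dataclass
class TriSurface:
    """Triangulated two-hemisphere cortical surface.

    Parameters
    ----------
    vertices : (p, 3) float array
        Positions in mm, head-centered.
    faces : (F, 3) int array
        Triangle vertex index triples.
    normals : (p, 3) float array
        Unit dipole orientation per vertex (outward).
    hemisphere : (p,) str array
        Per-vertex label, ``"left"`` or ``"right"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    hemisphere: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on failure."""
        p = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= p):
            raise ValueError("face indices out of range")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals are not unit length")
        adj = build_adjacency(self)
        n_comp, labels = connected_components(adj.matrix, directed=False)
        hemi_ids = (self.hemisphere == RIGHT).astype(int)
        rows, cols = adj.matrix.nonzero()
        if np.any(hemi_ids[rows] != hemi_ids[cols]):
            raise ValueError("an edge joins the two hemispheres")
        # each hemisphere must be a single connected component
        for side in (0, 1):
            sub = labels[hemi_ids == side]
            if sub.size and np.unique(sub).size != 1:
                raise ValueError("a hemisphere is not connected")

    # ---- I/O ---------------------------------------------------------
    def save(self, path: str) -> None:
        """Write as ASCII PLY plus a JSON sidecar (units, conventions)."""
        mesh = trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )
        mesh.export(path, encoding="ascii")
        sidecar = {
            "units": "mm",
            "head_center": "origin",
            "hemisphere": self.hemisphere.tolist(),
            "normals": self.normals.tolist(),
            "meta": self.meta,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path: str) -> "TriSurface":
        mesh = trimesh.load_mesh(path, process=False)
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            vertices=np.asarray(mesh.vertices, float),
            faces=np.asarray(mesh.faces, np.int64),
            normals=np.asarray(sidecar["normals"], float),
            hemisphere=np.asarray(sidecar["hemisphere"]),
            meta=sidecar.get("meta", {}),
        )


@dataclass
class Adjacency:
    """Symmetric binary vertex adjacency of the mesh edge graph."""

    matrix: sp.csr_matrix
    degree: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


def build_adjacency(surface: TriSurface) -> Adjacency:
    """Binary p x p adjacency: (i, j) = 1 iff i and j share a mesh edge.

    Raises
    ------
    ValueError
        If a face is degenerate (repeated vertex) — names the offending face.
    """
    faces = surface.faces
    for k in range(len(faces)):
        if len(set(faces[k])) != 3:
            raise ValueError(f"degenerate face {k}: {faces[k].tolist()}")
    p = surface.n_vertices
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(len(i))
    a = sp.coo_matrix((data, (i, j)), shape=(p, p))
    a = a + a.T
    a = (a > 0).astype(float).tocsr()
    a.setdiag(0.0)
    a.eliminate_zeros()
    degree = np.asarray(a.sum(axis=1)).ravel()
    return Adjacency(matrix=a, degree=degree)


def grow_patch(
    surface: TriSurface, adjacency: Adjacency, seed: int, order: int
) -> np.ndarray:
    """All vertices within graph distance ``order`` of ``seed`` (BFS rings).

    The patch always contains the seed and is confined to the seed's
    hemisphere because the hemispheres are disconnected.
    """
    p = adjacency.n_vertices
    if not (0 <= seed < p):
        raise IndexError(f"seed {seed} out of range [0, {p})")
    if order < 0:
        raise ValueError("order must be non-negative")
    frontier = np.array([seed], dtype=np.int64)
    visited = np.zeros(p, dtype=bool)
    visited[seed] = True
    A = adjacency.matrix
    for _ in range(order):
        nxt = np.unique(A[frontier].nonzero()[1])
        nxt = nxt[~visited[nxt]]
        if nxt.size == 0:
            break
        visited[nxt] = True
        frontier = nxt
    return np.flatnonzero(visited)


def _edge_weighted_graph(surface: TriSurface, adjacency: Adjacency) -> sp.csr_matrix:
    g = adjacency.matrix.tocoo()
    w = np.linalg.norm(
        surface.vertices[g.row] - surface.vertices[g.col], axis=1
    )
    return sp.csr_matrix((w, (g.row, g.col)), shape=g.shape)


def geodesic_from(
    surface: TriSurface, adjacency: Adjacency, sources
) -> np.ndarray:
    """Geodesic distance (mm) from a vertex or vertex set to every vertex.

    Shortest paths over mesh edges weighted by Euclidean edge length;
    vertices in the other hemisphere get the :data:`UNREACHABLE` sentinel.
    """
    g = _edge_weighted_graph(surface, adjacency)
    d = dijkstra(g, directed=False, indices=np.atleast_1d(sources))
    return d.min(axis=0) if d.ndim == 2 else d


def geodesic_dist(
    surface: TriSurface, adjacency: Adjacency, i: int, j: int
) -> float:
    """Geodesic distance between two vertices, sentinel across hemispheres."""
    p = surface.n_vertices
    for k in (i, j):
        if not (0 <= k < p):
            raise IndexError(f"vertex {k} out of range [0, {p})")
    if adjacency is None:
        adjacency = build_adjacency(surface)
    return float(geodesic_from(surface, adjacency, i)[j])


def eccentricity(surface: TriSurface, vertex: int) -> float:
    """Distance (mm) of a vertex from the head center (the origin).

    A depth proxy: < 40 mm sub-cortical, 40-60 mm mesio-temporal,
    > 60 mm superficial.
    """
    if not (0 <= vertex < surface.n_vertices):
        raise IndexError(f"vertex {vertex} out of range")
    return float(np.linalg.norm(surface.vertices[vertex]))


# ---------------------------------------------------------------------------
# Synthetic anatomy
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * k + 1) / n
    theta = 2 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _smooth_field(points: np.ndarray, rng: np.random.Generator, n_modes: int = 24) -> np.ndarray:
    """Smooth pseudo-random scalar field on the unit sphere (sum of plane waves)."""
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    freqs = rng.uniform(2.0, 5.0, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    amps = rng.normal(size=n_modes) / np.sqrt(n_modes)
    f = np.zeros(len(points))
    for d, w, ph, a in zip(dirs, freqs, phases, amps):
        f += a * np.sin(w * points @ d + ph)
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def _hemisphere_mesh(
    n_vertices: int,
    side: str,
    fold_amplitude: float,
    target_edge_mm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One closed, folded ellipsoidal hemisphere surface.

    The base shape is an ellipsoid whose scale is set so that the mean edge
    length of the triangulation of ``n_vertices`` points matches
    ``target_edge_mm``; folding perturbs vertices radially by a smooth
    random field, emulating gyri and sulci (so vertex depth varies).
    """
    unit = _fibonacci_sphere(n_vertices)
    hull = trimesh.convex.convex_hull(unit)
    # convex hull of points on a sphere keeps all n vertices
    verts = np.asarray(hull.vertices, float)
    faces = np.asarray(hull.faces, np.int64)

    # mean edge of a triangulated sphere of radius R with n vertices:
    # total area 4*pi*R^2 = 2n * (sqrt(3)/4) * l^2  =>  R = l*sqrt(n*sqrt(3)/(8*pi))
    base_r = target_edge_mm * np.sqrt(n_vertices * np.sqrt(3.0) / (8 * np.pi))

    fold = fold_amplitude * _smooth_field(verts, rng)
    radii = base_r * (1.0 + fold)
    if np.any(radii <= 0.2 * base_r):
        raise ValueError(
            "fold_amplitude too large: radial perturbation collapses the surface"
        )
    pts = verts * radii[:, None]
    # ellipsoidal anisotropy: narrower medio-laterally (x), longer
    # antero-posteriorly (y), like a real hemisphere
    pts = pts * np.array([0.62, 1.05, 0.92])
    # shift laterally so the two hemispheres do not touch
    xmax = np.abs(pts[:, 0]).max()
    offset = xmax * 0.70 + 2.0
    pts[:, 0] += offset if side == RIGHT else -offset

    mesh = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
    normals = np.asarray(mesh.vertex_normals, float).copy()
    # orient outward relative to the hemisphere's own centroid
    centroid = pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, pts - centroid) < 0
    normals[flip] *= -1
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    # Sulcal orientation structure: at a ~7 mm decimation the true cortical
    # normal (gyral crowns vs sulcal walls) deviates strongly from the
    # smooth envelope normal, so dipole orientations are the envelope
    # normal tilted toward a smooth random tangent direction by a smooth
    # angular field (20-85 degrees).  Without this, a spherical MEG model
    # would silence every superficial crown source.
    tilt_dir = np.column_stack(
        [_smooth_field(verts, rng), _smooth_field(verts, rng), _smooth_field(verts, rng)]
    )
    tang = tilt_dir - np.einsum("ij,ij->i", tilt_dir, normals)[:, None] * normals
    tn = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = np.where(tn > 1e-12, tang / np.where(tn == 0, 1.0, tn), 0.0)
    psi_field = _smooth_field(verts, rng)  # in [-1, 1]
    psi = np.deg2rad(52.5 + 32.5 * psi_field)  # 20..85 degrees
    normals = np.cos(psi)[:, None] * normals + np.sin(psi)[:, None] * tang
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return pts, faces, normals


def synth_cortex(
    n_vertices_per_hemisphere: int = 1000,
    fold_amplitude: float = 0.18,
    target_edge_mm: float = 7.0,
    rng_seed: int = 0,
    min_eccentricity_mm: float = 30.0,
) -> TriSurface:
    """Synthetic two-hemisphere folded cortex, head-centered.

    Two disconnected closed ellipsoidal meshes with smooth radial folding,
    one per hemisphere, mirrored about the sagittal plane and centered on
    the origin.  Deterministic given ``rng_seed``.

    Parameters
    ----------
    n_vertices_per_hemisphere : int
        Requested vertex count per hemisphere (honored exactly by the
        Fibonacci-lattice tessellation); must be >= 100.
    fold_amplitude : float
        Relative amplitude of the radial folding field (0 disables folding).
    target_edge_mm : float
        Target mean edge length; 7 mm matches a typical decimated
        cortical mesh at ~4000 vertices.
    min_eccentricity_mm : float
        Soft lower bound on the distance of cortex from the head center
        (``r -> sqrt(r^2 + r_min^2)`` shell deformation).  Real cortex
        never approaches the head center — the deepest cortical surfaces
        (insular, mesial temporal) sit ~30-40 mm out, with central gray
        structures and ventricles inside.
    """
    if n_vertices_per_hemisphere < 100:
        raise ValueError("need at least 100 vertices per hemisphere")
    rng = np.random.default_rng(rng_seed)
    lv, lf, ln = _hemisphere_mesh(
        n_vertices_per_hemisphere, LEFT, fold_amplitude, target_edge_mm, rng
    )
    rv, rf, rn = _hemisphere_mesh(
        n_vertices_per_hemisphere, RIGHT, fold_amplitude, target_edge_mm, rng
    )
    nl = len(lv)
    vertices = np.vstack([lv, rv])
    # recenter so the head center is the origin
    vertices -= vertices.mean(axis=0)
    if min_eccentricity_mm > 0:
        r = np.linalg.norm(vertices, axis=1)
        r_new = np.sqrt(r**2 + min_eccentricity_mm**2)
        vertices = vertices * (r_new / np.maximum(r, 1e-12))[:, None]
    faces = np.vstack([lf, rf + nl])
    normals = np.vstack([ln, rn])
    hemisphere = np.array([LEFT] * nl + [RIGHT] * len(rv))
    return TriSurface(
        vertices=vertices,
        faces=faces,
        normals=normals,
        hemisphere=hemisphere,
        meta={
            "generator": "synth_cortex",
            "rng_seed": rng_seed,
            "fold_amplitude": fold_amplitude,
            "target_edge_mm": target_edge_mm,
        },
    )


def mean_edge_length(surface: TriSurface) -> float:
    adj = build_adjacency(surface)
    g = adj.matrix.tocoo()
    keep = g.row < g.col
    w = np.linalg.norm(
        surface.vertices[g.row[keep]] - surface.vertices[g.col[keep]], axis=1
    )
    return float(w.mean())


def vertex_areas(surface: TriSurface) -> np.ndarray:
    """Per-vertex area (mm^2): one third of each incident triangle's area."""
    v = surface.vertices
    f = surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(surface.n_vertices)
    for c in range(3):
        np.add.at(areas, f[:, c], tri_area / 3.0)
    return areas
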