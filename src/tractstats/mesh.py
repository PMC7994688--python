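"""Triangulated medial skeleton sheets.

A :class:`SkeletonMesh` is the medial surface of one white-matter tract:
world-space vertices, a triangulation, a unit normal per vertex, and the
half-thickness (distance from the medial sheet to the tract boundary along
the normal).  All downstream statistics — metric projection, vertex area
weights, cluster extraction — consume this structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import MeshError, UnknownTractError

#: The eleven tracts analysed by the pipeline.
TRACT_NAMES = (
    "CC",
    "CST_L", "CST_R",
    "IFO_L", "IFO_R",
    "ILF_L", "ILF_R",
    "SLF_L", "SLF_R",
    "UNC_L", "UNC_R",
)

_NORMAL_TOL = 1e-6


@dataclass
class SkeletonMesh:
    """Connected, manifold triangulated medial sheet of a single tract.

    Parameters
    ----------
    name : str
        Tract name; by convention one of :data:`TRACT_NAMES` but arbitrary
        names are accepted so externally produced meshes can be analysed.
    vertices : (V, 3) float array
        World coordinates in millimetres.
    triangles : (T, 3) int array
        Vertex index triples.
    normals : (V, 3) float array
        Unit normals.
    half_thickness : (V,) float array
        Strictly positive distance (mm) from the sheet to the tract
        boundary along the +/- normal.
    """

    name: str
    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray
    half_thickness: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.intp)
        self.normals = np.asarray(self.normals, dtype=float)
        self.half_thickness = np.asarray(self.half_thickness, dtype=float)
        v = self.n_vertices
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (T, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= v
        ):
            raise MeshError("triangle indices out of range")
        if self.normals.shape != (v, 3):
            raise MeshError("normals must be (V, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > _NORMAL_TOL):
            raise MeshError("normals must be unit length")
        if self.half_thickness.shape != (v,):
            raise MeshError("half_thickness must be (V,)")
        if np.any(self.half_thickness <= 0):
            raise MeshError("half_thickness must be strictly positive")
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        if v and n_comp != 1:
            raise MeshError(f"mesh is disconnected ({n_comp} components)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:, 0] < e[:, 1]."""
        if self._edges is None:
            t = self.triangles
            pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
            pairs = np.sort(pairs, axis=1)
            self._edges = np.unique(pairs, axis=0)
        return self._edges

    def adjacency(self) -> csr_matrix:
        """Boolean vertex adjacency under shared triangle edges."""
        e = self.edges()
        v = self.n_vertices
        row = np.concatenate([e[:, 0], e[:, 1]])
        col = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix(
            (np.ones(len(row), dtype=bool), (row, col)), shape=(v, v)
        )

    def edge_length_graph(self) -> csr_matrix:
        """Sparse graph weighted by Euclidean edge length (mm)."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        v = self.n_vertices
        row = np.concatenate([e[:, 0], e[:, 1]])
        col = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((np.concatenate([w, w]), (row, col)), shape=(v, v))

    def geodesic_distances(self, source: int) -> np.ndarray:
        """Shortest-path distance (mm) from ``source`` to every vertex.

        Edge-graph Dijkstra, not exact surface geodesics; adequate at the
        mesh resolutions used here.
        """
        if not 0 <= source < self.n_vertices:
            raise MeshError(f"source vertex {source} out of range")
        return dijkstra(self.edge_length_graph(), directed=False, indices=source)

    def central_vertex(self) -> int:
        """Vertex closest to the centroid (a canonical disk centre)."""
        c = self.vertices.mean(axis=0)
        return int(np.argmin(np.linalg.norm(self.vertices - c, axis=1)))


def check_tract_names(names) -> list[str]:
    """Validate tract names against the study vocabulary."""
    names = list(names)
    for n in names:
        if n not in TRACT_NAMES:
            raise UnknownTractError(n)
    return names


def geodesic_disk(mesh: SkeletonMesh, center: int, radius: float) -> np.ndarray:
    """Sorted indices of vertices within geodesic ``radius`` mm of ``center``."""
    if radius <= 0:
        raise MeshError("disk radius must be positive")
    d = mesh.geodesic_distances(center)
    return np.flatnonzero(d <= radius)

def radius_for_fraction(mesh: SkeletonMesh, center: int, fraction: float) -> float:
    """Geodesic radius whose disk captures about ``fraction`` of the vertices."""
    if not 0 < fraction <= 1:
        raise MeshError("fraction must be in (0, 1]")
    d = np.sort(mesh.geodesic_distances(center))
    k = max(1, int(round(fraction * mesh.n_vertices)))
    return float(d[min(k, len(d)) - 1])
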