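"""Triangulated gray–white interface meshes.

The mesh is the substrate for cortical-unit parcellation, surface map
smoothing, and cluster detection.  Vertices live in world millimetres (RAS);
all "geodesic" distances in this package are graph geodesics along mesh
edges, which is accurate to a few percent at the patch scales used here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra


@dataclass
class CorticalMesh:
    """Triangle mesh with cached areas, normals and the edge-length graph.

    Parameters
    ----------
    vertices : (V, 3) float array, world mm
    faces : (F, 3) int array of vertex indices (consistent winding)
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices exceed vertex count")

    # -- geometry -----------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def face_normals(self) -> np.ndarray:
        """(F, 3) unit normals following the face winding."""
        if "face_normals" not in self._cache:
            v = self.vertices
            e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            n = np.cross(e1, e2)
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["face_normals"] = n / norm
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            self._cache["face_areas"] = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        return self._cache["face_areas"]

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area: one third of each incident face's area.

        Sums exactly to the total surface area.
        """
        if "vertex_areas" not in self._cache:
            va = np.zeros(self.n_vertices)
            np.add.at(va, self.faces.ravel(), np.repeat(self.face_areas / 3.0, 3))
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def vertex_normals(self) -> np.ndarray:
        """(V, 3) unit normals, area-weighted average of incident faces."""
        if "vertex_normals" not in self._cache:
            vn = np.zeros_like(self.vertices)
            w = (self.face_normals * self.face_areas[:, None])
            for k in range(3):
                np.add.at(vn, self.faces[:, k], w)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm
        return self._cache["vertex_normals"]

    # -- graph --------------------------------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges, each with i < j."""
        if "edges" not in self._cache:
            f = self.faces
            e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def edge_lengths(self) -> np.ndarray:
        if "edge_lengths" not in self._cache:
            e = self.edges
            self._cache["edge_lengths"] = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
        return self._cache["edge_lengths"]

    @property
    def graph(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of Euclidean edge lengths."""
        if "graph" not in self._cache:
            e, w = self.edges, self.edge_lengths
            n = self.n_vertices
            g = sparse.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n),
            )
            self._cache["graph"] = g.tocsr()
        return self._cache["graph"]

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Unweighted (0/1) vertex adjacency."""
        if "adjacency" not in self._cache:
            a = self.graph.copy()
            a.data[:] = 1.0
            self._cache["adjacency"] = a
        return self._cache["adjacency"]

    def vertex_components(self) -> tuple[int, np.ndarray]:
        """Connected components of the vertex graph."""
        return connected_components(self.graph, directed=False)

    def geodesic_from(self, sources, limit: float = np.inf) -> np.ndarray:
        """Graph-geodesic distance from the nearest of `sources` to every vertex."""
        return dijkstra(self.graph, directed=False, indices=sources,
                        min_only=np.ndim(sources) > 0 and len(np.atleast_1d(sources)) > 1,
                        limit=limit)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CorticalMesh":
        """Rigidly moved copy (used to check parcellation invariance)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return CorticalMesh(v, self.faces.copy())


def sphere_mesh(subdivisions: int = 4, radius: float = 1.0) -> CorticalMesh:
    """Icosphere test mesh (2562 vertices at subdivisions=4)."""
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return CorticalMesh(np.asarray(m.vertices), np.asarray(m.faces))
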