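"""Cortical-unit parcellation and subcortical voxel-layer masks.

The gray–white interface mesh is tiled into K contiguous, near-equal-area
cortical units (CUs) by farthest-point sampling followed by geodesic-Voronoi
labeling on the mesh edge graph; deterministic given the seed.  Each CU's
"subcortical voxel layer" — the diffusion-grid voxels immediately beneath
the patch — is then located by sampling along inward vertex normals, with a
uniqueness rule so no voxel is counted by two CUs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from .mesh import CorticalMesh

log = logging.getLogger(__name__)


@dataclass
class Parcellation:
    """Per-vertex CU labels in 0..K-1 plus the seed vertex of each CU."""

    labels: np.ndarray  # (V,) int
    K: int
    seeds: np.ndarray  # (K,) seed vertex index per CU

    def cu_vertices(self, cu_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cu_id)

    def cu_areas(self, mesh: CorticalMesh) -> np.ndarray:
        """Per-CU surface area (sum of member vertex areas), mm^2."""
        return np.bincount(self.labels, weights=mesh.vertex_areas, minlength=self.K)


@dataclass
class CUMask:
    """Voxel indices (diffusion grid) claimed by one CU, and their volume."""

    cu_id: int
    voxels: np.ndarray  # (n, 3) int indices
    volume_mm3: float

    @property
    def flagged(self) -> bool:
        """True when the CU captured no voxels and must be excluded downstream."""
        return len(self.voxels) == 0


def _fps_seeds(mesh: CorticalMesh, vertices: np.ndarray, k: int,
               first: int) -> np.ndarray:
    """Farthest-point sampling restricted to `vertices`, starting at `first`."""
    seeds = [first]
    dist = dijkstra(mesh.graph, directed=False, indices=first)
    sub = np.asarray(vertices)
    for _ in range(1, k):
        # round before argmax so exact-symmetry ties resolve by vertex index,
        # stable under ~1e-12 perturbations (e.g. rigid motion of the mesh)
        nxt = sub[np.argmax(np.round(dist[sub], 8))]
        seeds.append(int(nxt))
        d = dijkstra(mesh.graph, directed=False, indices=nxt)
        dist = np.minimum(dist, d)
    return np.asarray(seeds)


def _repair_contiguity(mesh: CorticalMesh, labels: np.ndarray) -> np.ndarray:
    """Reassign stray components of any label to the dominant neighboring label.

    Geodesic Voronoi cells from a single shortest-path forest are already
    connected; this pass guards the ties and disconnected-mesh edge cases.
    """
    labels = labels.copy()
    adj = mesh.adjacency
    for _ in range(20):
        changed = False
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) <= 1:
                continue
            sub = adj[members][:, members]
            ncomp, comp = connected_components(sub, directed=False)
            if ncomp == 1:
                continue
            # keep the largest component, push the rest to their neighbors
            sizes = np.bincount(comp)
            keep = np.argmax(sizes)
            for c in range(ncomp):
                if c == keep:
                    continue
                stray = members[comp == c]
                neigh = adj[stray].nonzero()[1]
                neigh_labs = labels[neigh]
                neigh_labs = neigh_labs[neigh_labs != lab]
                if len(neigh_labs) == 0:
                    continue
                vals, counts = np.unique(neigh_labs, return_counts=True)
                labels[stray] = vals[np.argmax(counts)]
                changed = True
        if not changed:
            break
    return labels


def parcellate(mesh: CorticalMesh, K: int, rng_seed: int = 0) -> Parcellation:
    """Partition the mesh into K contiguous, near-equal-area cortical units.

    Farthest-point sampling picks K well-spread seed vertices (the first
    chosen by ``rng_seed``); every vertex is then labeled by its
    graph-geodesically nearest seed.  Disconnected meshes get seeds allocated
    per component in proportion to vertex count.
    """
    nv = mesh.n_vertices
    if K > nv:
        raise ValueError(f"K={K} exceeds vertex count {nv}")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng_seed)

    ncomp, comp = mesh.vertex_components()
    comp_sizes = np.bincount(comp)
    # proportional allocation, at least one CU per component
    alloc = np.maximum(1, np.floor(K * comp_sizes / nv).astype(int))
    while alloc.sum() > K:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < K:
        alloc[np.argmax(comp_sizes / alloc)] += 1

    all_seeds: list[int] = []
    for c in range(ncomp):
        verts = np.flatnonzero(comp == c)
        first = int(verts[rng.integers(len(verts))])
        all_seeds.extend(_fps_seeds(mesh, verts, alloc[c], first))
    seeds = np.asarray(all_seeds)

    _, _, sources = dijkstra(mesh.graph, directed=False, indices=seeds,
                             min_only=True, return_predecessors=True)
    seed_rank = {int(s): i for i, s in enumerate(seeds)}
    labels = np.array([seed_rank[int(s)] for s in sources])
    labels = _repair_contiguity(mesh, labels)
    return Parcellation(labels=labels, K=K, seeds=seeds)


def cu_voxel_layer(parc: Parcellation, mesh: CorticalMesh,
                   affine: np.ndarray, grid_shape: tuple[int, int, int],
                   depth_mm: float = 2.0) -> list[CUMask]:
    """Locate each CU's subcortical voxel layer in the diffusion grid.

    From every vertex, points are sampled along the inward normal (opposite
    the mesh's outward normals) from the surface down to ``depth_mm`` at
    sub-voxel spacing; a voxel whose center is hit is claimed for the
    vertex's CU.  A voxel claimed by several CUs goes to the CU whose
    claiming surface vertex is nearest (ties to the lower CU id).  CUs that
    capture no voxel are flagged and must be excluded from statistics.
    """
    affine = np.asarray(affine, float)
    inv = np.linalg.inv(affine)
    shape = np.asarray(grid_shape)
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    pitch = np.min(np.abs(np.diag(affine[:3, :3])))

    claims: dict[tuple[int, int, int], tuple[float, int]] = {}
    if depth_mm > 0:
        n_steps = max(int(np.ceil(depth_mm / (pitch / 2.0))) + 1, 2)
        ts = np.linspace(0.0, depth_mm, n_steps)
        inward = -mesh.vertex_normals
        for vidx in range(mesh.n_vertices):
            cu = int(parc.labels[vidx])
            base = mesh.vertices[vidx]
            pts = base[None, :] + ts[:, None] * inward[vidx]
            vox = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            for v in np.unique(vox[ok], axis=0):
                center = v @ affine[:3, :3].T + affine[:3, 3]
                d = float(np.linalg.norm(center - base))
                key = tuple(int(x) for x in v)
                old = claims.get(key)
                if old is None or (d, cu) < old:
                    claims[key] = (d, cu)

    per_cu: dict[int, list[tuple[int, int, int]]] = {c: [] for c in range(parc.K)}
    for vox, (_, cu) in claims.items():
        per_cu[cu].append(vox)

    masks = []
    for cu in range(parc.K):
        voxels = np.asarray(sorted(per_cu[cu]), dtype=int).reshape(-1, 3)
        m = CUMask(cu_id=cu, voxels=voxels, volume_mm3=len(voxels) * voxel_volume)
        if m.flagged:
            log.warning("CU %d captured no voxels at depth %.2f mm; flagged", cu, depth_mm)
        masks.append(m)
    return masks
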