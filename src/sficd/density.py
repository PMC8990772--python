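"""Short-range fiber connectivity density (SFiCD) maps.

For each cortical unit (CU), SFiCD is the sum of the mean FA of every
short-range fiber terminating in the CU's subcortical voxel layer, divided
by the layer's volume (mm^-3).  Per-CU values are projected to a per-vertex
surface map, optionally carried to a template surface through a vertex
correspondence, and smoothed with a geodesic Gaussian kernel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .mesh import CorticalMesh
from .parcellation import CUMask, Parcellation
from .tracking import Tractogram

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class SFiCDMap:
    """Per-CU and per-vertex SFiCD values (mm^-3); NaN marks flagged CUs."""

    cu_values: np.ndarray  # (K,), NaN where flagged
    vertex_values: np.ndarray  # (V,), NaN where flagged
    subject_id: str = ""
    smoothed_fwhm: float = 0.0


def assign_fibers(t: Tractogram, masks: list[CUMask],
                  affine: np.ndarray) -> dict[int, list[int]]:
    """Assign each fiber to the CUs its terminal points fall in.

    A fiber connects to a CU iff either endpoint's voxel belongs to the CU's
    mask; a fiber spanning two CUs is listed under both, a fiber with both
    endpoints in one CU is listed once, and fibers touching no mask are left
    unassigned.
    """
    inv = np.linalg.inv(np.asarray(affine, float))
    voxel_to_cu: dict[tuple[int, int, int], int] = {}
    for m in masks:
        for v in m.voxels:
            voxel_to_cu[tuple(int(x) for x in v)] = m.cu_id

    out: dict[int, list[int]] = {m.cu_id: [] for m in masks}
    if len(t) == 0:
        return out
    eps = t.endpoints()  # (n, 2, 3)
    flat = eps.reshape(-1, 3)
    vox = np.rint(flat @ inv[:3, :3].T + inv[:3, 3]).astype(int).reshape(-1, 2, 3)
    for i in range(len(t)):
        cus = set()
        for e in range(2):
            cu = voxel_to_cu.get(tuple(vox[i, e]))
            if cu is not None:
                cus.add(cu)
        for cu in cus:
            out[cu].append(i)
    return out


def compute_sficd(mean_fas, volume_mm3: float) -> float:
    """SFiCD = sum of per-fiber mean FA / CU volume; requires volume > 0."""
    if volume_mm3 <= 0:
        raise ValueError("CU volume must be > 0 (flagged CU)")
    return float(np.sum(mean_fas)) / float(volume_mm3)


def sficd_per_cu(t: Tractogram, masks: list[CUMask],
                 affine: np.ndarray) -> pd.DataFrame:
    """Per-CU table: fiber count, FA sum, layer volume, SFiCD (NaN if flagged)."""
    assigned = assign_fibers(t, masks, affine)
    fas = t.mean_fas if len(t) else np.empty(0)
    rows = []
    for m in masks:
        idx = assigned[m.cu_id]
        sum_fa = float(fas[idx].sum()) if idx else 0.0
        rows.append({
            "cu_id": m.cu_id,
            "n_fibers": len(idx),
            "sum_fa": sum_fa,
            "volume_mm3": m.volume_mm3,
            "sficd": np.nan if m.flagged else compute_sficd(fas[idx], m.volume_mm3),
        })
    return pd.DataFrame(rows)


def project_to_vertices(parc: Parcellation, cu_values: np.ndarray) -> np.ndarray:
    """Piecewise-constant per-vertex map from per-CU values (NaN propagates)."""
    cu_values = np.asarray(cu_values, float)
    if len(cu_values) != parc.K:
        raise ValueError("cu_values length must equal K")
    return cu_values[parc.labels]


def normalize_to_template(vertex_values: np.ndarray,
                          correspondence: np.ndarray) -> np.ndarray:
    """Carry a subject map to template space.

    ``correspondence[v]`` is the subject vertex corresponding to template
    vertex ``v`` (identity on shared synthetic templates; a real spherical
    registration must be supplied externally).  Missing markers propagate.
    """
    if correspondence is None:
        raise ValueError("a subject->template vertex correspondence is required")
    corr = np.asarray(correspondence)
    vals = np.asarray(vertex_values, float)
    if corr.min() < 0 or corr.max() >= len(vals):
        raise ValueError("correspondence indexes outside the subject map")
    return vals[corr]


def smoothing_operator(mesh: CorticalMesh, fwhm_mm: float,
                       truncate_sigmas: float = 2.5) -> sparse.csr_matrix:
    """Row-stochastic geodesic Gaussian smoothing matrix.

    Weights w(v,u) ~ exp(-d(v,u)^2 / 2 sigma^2), truncated at a
    ``truncate_sigmas``*sigma graph-geodesic radius (<1% kernel mass lost
    before renormalization) and renormalized to sum to one per row.  The
    graph search delimits each neighborhood, but d(v,u) itself is the
    Euclidean distance between the vertices: at kernel scale the surface is
    near-flat, so this tracks the true geodesic far better than summed edge
    lengths, whose lattice inflation (~10%) would otherwise narrow the
    effective kernel below the nominal FWHM.  fwhm 0 returns the identity.
    """
    nv = mesh.n_vertices
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return sparse.identity(nv, format="csr")
    key = ("smoothing_operator", round(float(fwhm_mm), 6), truncate_sigmas)
    if key in mesh._cache:
        return mesh._cache[key]
    sigma = fwhm_mm * FWHM_TO_SIGMA
    limit = truncate_sigmas * sigma
    blocks = []
    chunk = 512
    for start in range(0, nv, chunk):
        idx = np.arange(start, min(start + chunk, nv))
        d = dijkstra(mesh.graph, directed=False, indices=idx, limit=limit)
        reached = np.isfinite(d)
        rows, cols = np.nonzero(reached)
        d_euc = np.linalg.norm(mesh.vertices[idx[rows]] - mesh.vertices[cols],
                               axis=1)
        w = np.zeros_like(d)
        w[rows, cols] = np.exp(-0.5 * (d_euc / sigma) ** 2)
        blocks.append(sparse.csr_matrix(w))
    W = sparse.vstack(blocks).tocsr()
    norm = np.asarray(W.sum(axis=1)).ravel()
    norm[norm == 0] = 1.0
    W = (sparse.diags(1.0 / norm) @ W).tocsr()
    mesh._cache[key] = W
    return W


def smooth_surface(vertex_values: np.ndarray, mesh: CorticalMesh,
                   fwhm_mm: float = 15.0,
                   operator: sparse.csr_matrix | None = None) -> np.ndarray:
    """Geodesic Gaussian smoothing with missing-value (NaN) exclusion.

    Missing vertices contribute nothing and weights are renormalized over
    the observed neighbors; a missing vertex stays missing in the output.
    Pass a precomputed ``operator`` to amortize the geodesic kernel across
    many maps on the same mesh.
    """
    vals = np.asarray(vertex_values, float)
    if operator is None:
        operator = smoothing_operator(mesh, fwhm_mm)
    missing = np.isnan(vals)
    if not missing.any():
        out = operator @ vals
    else:
        filled = np.where(missing, 0.0, vals)
        wsum = operator @ (~missing).astype(float)
        out = np.divide(operator @ filled, wsum,
                        out=np.full_like(vals, np.nan), where=wsum > 0)
        out[missing] = np.nan
    return out


def subject_sficd_map(t: Tractogram, parc: Parcellation, masks: list[CUMask],
                      mesh: CorticalMesh, affine: np.ndarray,
                      fwhm_mm: float = 15.0, subject_id: str = "",
                      operator: sparse.csr_matrix | None = None) -> tuple[SFiCDMap, pd.DataFrame]:
    """Full per-subject map: per-CU SFiCD -> vertex projection -> smoothing."""
    table = sficd_per_cu(t, masks, affine)
    cu_values = table["sficd"].to_numpy()
    vertex = project_to_vertices(parc, cu_values)
    if fwhm_mm > 0:
        vertex = smooth_surface(vertex, mesh, fwhm_mm, operator=operator)
    return SFiCDMap(cu_values=cu_values, vertex_values=vertex,
                    subject_id=subject_id, smoothed_fwhm=fwhm_mm), table
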