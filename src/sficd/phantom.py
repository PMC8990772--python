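"""Synthetic inputs with analytic ground truth.

Three generators stand in for data that real studies obtain from the scanner
and FreeSurfer:

* ``generate_diffusion_field`` — a diffusion grid containing U-shaped fiber
  bundles modelled as circular-arc tubes of known endpoints, length and FA.
  Circular arcs (chord + sagitta) were chosen because their length has a
  closed form, giving every tracking test an analytic oracle.
* ``generate_sheet_mesh`` — a triangulated sheet standing in for the
  gray–white interface, optionally undulated to mimic gyri.
* ``generate_cohort_maps`` — multi-subject vertexwise SFiCD maps with
  injected group offsets, interaction slopes and longitudinal rates plus
  spatially smooth noise, driving the statistics stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .field import DiffusionField
from .mesh import CorticalMesh


# ---------------------------------------------------------------------------
# circular-arc bundles
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """A U-fiber bundle: a circular-arc tube joining two cortical endpoints.

    The arc lies in the plane spanned by the chord and ``bulge``; its sagitta
    (maximum deviation from the chord, towards ``bulge``) is ``arc_depth``.
    ``arc_depth = 0`` degenerates to a straight segment.
    """

    endpoint_a: tuple[float, float, float]
    endpoint_b: tuple[float, float, float]
    arc_depth: float  # sagitta, mm
    tube_radius: float  # mm
    fa_inside: float
    id: str = "bundle"
    bulge: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError(f"bundle {self.id}: tube_radius must be > 0")
        if not (0 < self.fa_inside <= 1):
            raise ValueError(f"bundle {self.id}: fa_inside must be in (0, 1]")
        if self.arc_depth < 0:
            raise ValueError(f"bundle {self.id}: arc_depth must be >= 0")

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(np.subtract(self.endpoint_b, self.endpoint_a)))

    @property
    def arc_length(self) -> float:
        """Closed-form arc length from chord c and sagitta s.

        R = (c^2/4 + s^2) / (2 s); the half-angle is arcsin(c / 2R) for the
        minor arc (s <= c/2) and its supplement for the major arc; a zero
        sagitta is the straight chord.
        """
        c, s = self.chord, self.arc_depth
        if s == 0:
            return c
        radius = (c * c / 4.0 + s * s) / (2.0 * s)
        half = np.arcsin(min(c / (2.0 * radius), 1.0))
        if s > c / 2.0:
            half = np.pi - half
        return float(2.0 * radius * half)

    def sample(self, spacing: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
        """Polyline points along the arc and unit tangents (A -> B).

        Points are spaced <= `spacing` mm along the arc.
        """
        a = np.asarray(self.endpoint_a, float)
        b = np.asarray(self.endpoint_b, float)
        n = max(int(np.ceil(self.arc_length / spacing)) + 1, 2)
        if self.arc_depth == 0:
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts = a + t * (b - a)
            tan = np.tile((b - a) / self.chord, (n, 1))
            return pts, tan
        c, s = self.chord, self.arc_depth
        u = (b - a) / c
        d = np.asarray(self.bulge, float)
        d = d - (d @ u) * u  # orthogonalize against the chord
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            raise ValueError(f"bundle {self.id}: bulge is parallel to the chord")
        d /= nd
        radius = (c * c / 4.0 + s * s) / (2.0 * s)
        half = np.arcsin(min(c / (2.0 * radius), 1.0))
        if s > c / 2.0:
            half = np.pi - half
        center = (a + b) / 2.0 + (s - radius) * d
        # theta sweeps pi/2+half (at A) -> pi/2-half (at B) through the apex
        theta = np.pi / 2.0 + half - np.linspace(0.0, 2.0 * half, n)
        pts = center + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * d)
        tan = np.sin(theta)[:, None] * u - np.cos(theta)[:, None] * d
        return pts, tan


@dataclass
class PhantomSpec:
    """Grid geometry, bundle list, and noise levels for a diffusion phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    bundles: list[BundleSpec]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fa_background: float = 0.05
    noise_sd_fa: float = 0.0
    noise_sd_dir_deg: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fa_background < 0 or self.noise_sd_fa < 0 or self.noise_sd_dir_deg < 0:
            raise ValueError("noise parameters and background FA must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotate_about_random_axes(rng: np.random.Generator, vecs: np.ndarray,
                              sd_deg: float) -> np.ndarray:
    """Rotate each vector by N(0, sd) degrees about an independent random axis.

    Rotation (rather than additive perturbation) keeps unit norm exact.
    """
    n = len(vecs)
    angles = np.deg2rad(rng.normal(0.0, sd_deg, n))
    axes = _random_unit_vectors(rng, n)
    cos, sin = np.cos(angles)[:, None], np.sin(angles)[:, None]
    dot = np.sum(axes * vecs, axis=1, keepdims=True)
    return (vecs * cos + np.cross(axes, vecs) * sin + axes * dot * (1.0 - cos))


def generate_diffusion_field(spec: PhantomSpec) -> tuple[DiffusionField, pd.DataFrame]:
    """Voxelize the bundles of `spec` into an FA + direction field.

    Every voxel whose center lies within ``tube_radius`` of a bundle's arc
    gets FA ``fa_inside`` and the local arc tangent as direction; all other
    voxels get ``fa_background`` and a random unit direction.  Direction signs
    are randomized voxelwise (diffusion is axial), so the tracker must handle
    antipodal symmetry.  Returns the field and a ground-truth table with one
    row per bundle (id, endpoints, closed-form arc length, FA).
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.grid_shape)
    affine = spec.affine
    nvox = int(np.prod(shape))

    fa = np.full(shape, spec.fa_background, dtype=float)
    dirs = _random_unit_vectors(rng, nvox).reshape(shape + (3,))

    centers_idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                       indexing="ij"), axis=-1).reshape(-1, 3)
    centers = centers_idx @ affine[:3, :3].T + affine[:3, 3]
    tree = cKDTree(centers)
    lo = affine[:3, 3] - 0.5 * np.abs(np.diag(affine[:3, :3]))
    hi = (np.array(shape) - 0.5) @ np.abs(affine[:3, :3].T) + affine[:3, 3]

    rows = []
    claimed = {}  # flat voxel index -> (distance to arc, bundle order)
    for k, b in enumerate(spec.bundles):
        pts, tans = b.sample(spacing=min(spec.voxel_size) / 4.0)
        if np.any(pts - b.tube_radius < lo) or np.any(pts + b.tube_radius > hi):
            raise ValueError(f"bundle {b.id!r} extends outside the grid")
        hits = tree.query_ball_point(pts, b.tube_radius)
        for j, vox_list in enumerate(hits):
            for v in vox_list:
                d = np.linalg.norm(centers[v] - pts[j])
                if v not in claimed or d < claimed[v][0]:
                    claimed[v] = (d, k, tans[j])
        rows.append({
            "bundle_id": b.id,
            "ax": b.endpoint_a[0], "ay": b.endpoint_a[1], "az": b.endpoint_a[2],
            "bx": b.endpoint_b[0], "by": b.endpoint_b[1], "bz": b.endpoint_b[2],
            "arc_length_mm": b.arc_length,
            "fa_inside": b.fa_inside,
        })

    flat_fa = fa.reshape(-1)
    flat_dirs = dirs.reshape(-1, 3)
    for v, (_, k, tan) in claimed.items():
        flat_fa[v] = spec.bundles[k].fa_inside
        flat_dirs[v] = tan

    if spec.noise_sd_fa > 0:
        flat_fa += rng.normal(0.0, spec.noise_sd_fa, nvox)
        np.clip(flat_fa, 0.0, 1.0, out=flat_fa)
    if spec.noise_sd_dir_deg > 0:
        flat_dirs[:] = _rotate_about_random_axes(rng, flat_dirs, spec.noise_sd_dir_deg)
    # axial symmetry: randomize the stored sign voxelwise
    signs = rng.choice([-1.0, 1.0], nvox)
    flat_dirs *= signs[:, None]

    field = DiffusionField(fa, dirs, affine)
    return field, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sheet mesh
# ---------------------------------------------------------------------------

def generate_sheet_mesh(extent_mm: tuple[float, float],
                        vertex_spacing_mm: float,
                        undulation_amplitude_mm: float = 0.0,
                        undulation_period_mm: float = 10.0,
                        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                        ) -> CorticalMesh:
    """Regular triangulated sheet in the x-y plane, normals towards +z.

    ``undulation_amplitude_mm`` adds z = A sin(2*pi*x / period) to mimic a
    gyrified surface; amplitude 0 gives a flat sheet of area
    extent_x * extent_y exactly.
    """
    if vertex_spacing_mm <= 0:
        raise ValueError("vertex_spacing_mm must be > 0")
    ex, ey = extent_mm
    if ex <= 0 or ey <= 0:
        raise ValueError("extent must be positive in both directions")
    nx = int(round(ex / vertex_spacing_mm)) + 1
    ny = int(round(ey / vertex_spacing_mm)) + 1
    if nx < 2 or ny < 2:
        raise ValueError("extent too small for the requested spacing")
    x = np.linspace(0.0, ex, nx) + origin[0]
    y = np.linspace(0.0, ey, ny) + origin[1]
    xx, yy = np.meshgrid(x, y, indexing="ij")
    zz = origin[2] + undulation_amplitude_mm * np.sin(
        2.0 * np.pi * (xx - origin[0]) / undulation_period_mm)
    verts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            # CCW seen from +z so normals point up
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return CorticalMesh(verts, np.asarray(faces))


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a two-group, two-timepoint synthetic SFiCD cohort.

    Per-vertex subject maps are
    ``baseline + group*effect + group*moderator_hi*interaction + months*rate
    + smooth noise``; the moderator is a serum homocysteine value binarized
    at the cohort median, as the statistics stage expects.  Covariate
    distributions default to an older-adult cohort (age ~74 y, education
    ~5 y, TIV ~1.46e6 mm^3, homocysteine median ~17 umol/L) followed over
    27 months.
    """

    n_per_group: int = 20
    mesh: CorticalMesh | None = None
    baseline_mean_map: np.ndarray | None = None
    effect_map: np.ndarray | None = None
    interaction_map: np.ndarray | None = None
    rate_map: np.ndarray | None = None
    noise_sd: float = 0.05
    noise_fwhm: float = 6.0
    followup_months: float = 27.0
    rng_seed: int = 0
    covariate_params: dict = dfield(default_factory=lambda: {
        "age_mean": 74.0, "age_sd": 3.5,
        "education_mean": 5.0, "education_sd": 3.0,
        "tiv_mean": 1.46e6, "tiv_sd": 1.2e5,
        "hcy_log_mean": np.log(17.0), "hcy_log_sd": 0.3,
    })

    def _resolve(self, m: np.ndarray | None, nv: int) -> np.ndarray:
        if m is None:
            return np.zeros(nv)
        m = np.asarray(m, float)
        if m.shape != (nv,):
            raise ValueError("all maps must share the template vertex count")
        return m


def generate_cohort_maps(spec: CohortSpec) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate per-subject vertexwise maps at two timepoints plus the design.

    Returns ``(maps, design)`` where ``maps["t0"]`` and ``maps["t1"]`` are
    (n_subjects, n_vertices) arrays and the design table records group,
    covariates, homocysteine and its median split, and follow-up months.
    Fully reproducible from ``spec.rng_seed``.
    """
    if spec.mesh is None:
        raise ValueError("CohortSpec.mesh is required")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nv = spec.mesh.n_vertices
    baseline = spec._resolve(spec.baseline_mean_map, nv)
    effect = spec._resolve(spec.effect_map, nv)
    interaction = spec._resolve(spec.interaction_map, nv)
    rate = spec._resolve(spec.rate_map, nv)

    rng = np.random.default_rng(spec.rng_seed)
    n = 2 * spec.n_per_group
    group = np.repeat([0, 1], spec.n_per_group)
    cp = spec.covariate_params
    age = rng.normal(cp["age_mean"], cp["age_sd"], n)
    sex = rng.integers(0, 2, n)
    education = np.clip(rng.normal(cp["education_mean"], cp["education_sd"], n), 0, None)
    tiv = rng.normal(cp["tiv_mean"], cp["tiv_sd"], n)
    hcy = rng.lognormal(cp["hcy_log_mean"], cp["hcy_log_sd"], n)
    hcy_hi = (hcy > np.median(hcy)).astype(int)  # ties fall to the low group

    smooth_op = None
    if spec.noise_sd > 0 and spec.noise_fwhm > 0:
        from .density import smoothing_operator
        smooth_op = smoothing_operator(spec.mesh, spec.noise_fwhm)

    def noise_block() -> np.ndarray:
        if spec.noise_sd == 0:
            return np.zeros((n, nv))
        white = rng.standard_normal((n, nv))
        if smooth_op is None:
            return spec.noise_sd * white
        sm = (smooth_op @ white.T).T
        sd = sm.std()
        return spec.noise_sd * sm / (sd if sd > 0 else 1.0)

    fixed = (baseline[None, :]
             + group[:, None] * effect[None, :]
             + (group * hcy_hi)[:, None] * interaction[None, :])
    t0 = fixed + noise_block()
    t1 = fixed + spec.followup_months * rate[None, :] + noise_block()

    design = pd.DataFrame({
        "subject": [f"sub-{i:03d}" for i in range(n)],
        "group": group,
        "age": age,
        "sex": sex,
        "education": education,
        "tiv": tiv,
        "homocysteine": hcy,
        "homocysteine_high": hcy_hi,
        "followup_months": spec.followup_months,
    })
    return {"t0": t0, "t1": t1}, design
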