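"""Shared fixtures: analytic phantoms, meshes, and smoothing operators.

Everything is generated in memory at fixed seeds; session scope amortizes
the geodesic-kernel construction, which dominates fixture cost.
"""
import numpy as np
import pytest

import sficd


@pytest.fixture(scope="session")
def straight_bundle():
    """12 mm straight bundle along +x through voxel centers; thin tube."""
    b = sficd.BundleSpec(endpoint_a=(6, 10, 8), endpoint_b=(18, 10, 8),
                         arc_depth=0.0, tube_radius=0.6, fa_inside=0.8, id="s12")
    spec = sficd.PhantomSpec(grid_shape=(24, 20, 16), voxel_size=(1, 1, 1),
                             bundles=[b], fa_background=0.05, rng_seed=7)
    field, truth = sficd.generate_diffusion_field(spec)
    return field, truth, b


@pytest.fixture(scope="session")
def semicircle_bundle():
    """Semicircular bundle: chord 10 mm, sagitta 5 mm, arc length 5*pi."""
    b = sficd.BundleSpec(endpoint_a=(5, 10, 6), endpoint_b=(15, 10, 6),
                         arc_depth=5.0, tube_radius=1.0, fa_inside=0.8,
                         bulge=(0, 0, -1), id="semi")
    spec = sficd.PhantomSpec(grid_shape=(80, 80, 40),
                             voxel_size=(0.25, 0.25, 0.25),
                             bundles=[b], fa_background=0.05, rng_seed=7)
    field, truth = sficd.generate_diffusion_field(spec)
    return field, truth, b


@pytest.fixture(scope="session")
def sphere20():
    """Icosphere of radius 20 mm, 2562 vertices."""
    return sficd.sphere_mesh(subdivisions=4, radius=20.0)


@pytest.fixture(scope="session")
def sheet40():
    """40x40 mm flat sheet at 1 mm spacing (smoothing-scale tests)."""
    return sficd.generate_sheet_mesh((40, 40), 1.0)


@pytest.fixture(scope="session")
def stats_mesh():
    """39x39 mm sheet at 1.5 mm spacing: the cohort-statistics template."""
    return sficd.generate_sheet_mesh((39, 39), 1.5)


@pytest.fixture(scope="session")
def tiny_mesh():
    """10x10 mm sheet at 2 mm spacing (fast Monte Carlo loops)."""
    return sficd.generate_sheet_mesh((10, 10), 2.0)


def vortex_field(extent_mm: float, voxel_mm: float, n_slices: int = 4):
    """Tangential (vortex) direction field around the grid center, FA 0.8.

    Tracking from a seed at radius r turns by ~atan(step/r) per step, giving
    an analytic handle on the turning-angle stopping rule.
    """
    n = int(round(extent_mm / voxel_mm))
    shape = (n, n, n_slices)
    aff = np.diag([voxel_mm] * 3 + [1.0])
    cx = cy = extent_mm / 2.0
    ii, jj, _ = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dx, dy = ii * voxel_mm - cx, jj * voxel_mm - cy
    r = np.hypot(dx, dy)
    r[r == 0] = 1.0
    dirs = np.stack([-dy / r, dx / r, np.zeros_like(dx)], axis=-1)
    return sficd.DiffusionField(np.full(shape, 0.8), dirs, aff), (cx, cy)
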