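"""SFiCD computation, surface projection, template transfer, smoothing."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sficd


def make_tractogram(endpoint_pairs, fas):
    lines = []
    for (a, b), fa in zip(endpoint_pairs, fas):
        pts = np.array([a, b], float)
        lines.append(sficd.Streamline(points=pts,
                                      length=float(np.linalg.norm(pts[1] - pts[0])),
                                      mean_fa=fa))
    return sficd.Tractogram(streamlines=lines)


def box_mask(cu_id, x0, x1, y0, y1, z0, z1):
    vox = np.array([[i, j, k] for i in range(x0, x1)
                    for j in range(y0, y1) for k in range(z0, z1)])
    return sficd.CUMask(cu_id=cu_id, voxels=vox, volume_mm3=float(len(vox)))


class TestComputeSficd:
    def test_printed_formula(self):
        assert sficd.compute_sficd([0.5, 0.3, 0.2], 2.0) == pytest.approx(0.5)

    def test_empty_sum_is_zero(self):
        assert sficd.compute_sficd([], 4.0) == 0.0

    def test_single_fiber(self):
        assert sficd.compute_sficd([0.14], 1.0) == pytest.approx(0.14)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            sficd.compute_sficd([0.5], 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(fas=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20),
           vol=st.floats(0.5, 100.0), c=st.floats(0.1, 5.0))
    def test_homogeneity_in_fa(self, fas, vol, c):
        """Scaling every fiber FA by c scales SFiCD by c."""
        assert sficd.compute_sficd(np.array(fas) * c, vol) == pytest.approx(
            c * sficd.compute_sficd(fas, vol), rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(fas=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20),
           vol=st.floats(0.5, 100.0), c=st.floats(0.1, 5.0))
    def test_inverse_proportionality_in_volume(self, fas, vol, c):
        assert sficd.compute_sficd(fas, vol * c) == pytest.approx(
            sficd.compute_sficd(fas, vol) / c, rel=1e-12)


class TestAssignFibers:
    def setup_method(self):
        self.masks = [box_mask(0, 0, 4, 0, 4, 0, 2), box_mask(1, 10, 14, 0, 4, 0, 2)]
        self.affine = np.eye(4)

    def test_fiber_spanning_two_cus_listed_under_both(self):
        t = make_tractogram([((1, 1, 0), (11, 1, 0))], [0.5])
        out = sficd.assign_fibers(t, self.masks, self.affine)
        assert out[0] == [0] and out[1] == [0]

    def test_loop_fiber_listed_once(self):
        t = make_tractogram([((1, 1, 0), (2, 2, 1))], [0.5])
        out = sficd.assign_fibers(t, self.masks, self.affine)
        assert out[0] == [0] and out[1] == []

    def test_untouched_fiber_unassigned(self):
        t = make_tractogram([((20, 20, 0), (30, 20, 0))], [0.5])
        out = sficd.assign_fibers(t, self.masks, self.affine)
        assert out[0] == [] and out[1] == []

    def test_per_cu_table(self):
        t = make_tractogram([((1, 1, 0), (11, 1, 0)), ((1, 2, 0), (2, 2, 0))],
                            [0.5, 0.3])
        tbl = sficd.sficd_per_cu(t, self.masks, self.affine)
        r0 = tbl[tbl.cu_id == 0].iloc[0]
        r1 = tbl[tbl.cu_id == 1].iloc[0]
        assert r0.n_fibers == 2 and r0.sum_fa == pytest.approx(0.8)
        assert r1.n_fibers == 1 and r1.sum_fa == pytest.approx(0.5)
        assert r0.sficd == pytest.approx(0.8 / 32.0)


class TestProjection:
    def test_k1_constant_map(self, tiny_mesh):
        parc = sficd.parcellate(tiny_mesh, 1)
        assert np.allclose(sficd.project_to_vertices(parc, [0.7]), 0.7)

    def test_piecewise_constant_by_cu(self, tiny_mesh):
        parc = sficd.parcellate(tiny_mesh, 4, rng_seed=0)
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        vmap = sficd.project_to_vertices(parc, vals)
        for cu in range(4):
            assert np.all(vmap[parc.labels == cu] == vals[cu])

    def test_flagged_cu_marks_vertices_missing(self, tiny_mesh):
        parc = sficd.parcellate(tiny_mesh, 4, rng_seed=0)
        vals = np.array([1.0, np.nan, 3.0, 4.0])
        vmap = sficd.project_to_vertices(parc, vals)
        assert np.all(np.isnan(vmap[parc.labels == 1]))
        assert not np.any(np.isnan(vmap[parc.labels != 1]))


class TestTemplateTransfer:
    def test_identity_correspondence_unchanged(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(sficd.normalize_to_template(v, np.arange(3)), v)

    def test_permutation_correspondence(self):
        v = np.array([1.0, 2.0, 3.0])
        out = sficd.normalize_to_template(v, np.array([2, 0, 1]))
        assert np.array_equal(out, [3.0, 1.0, 2.0])

    def test_missing_markers_propagate(self):
        v = np.array([1.0, np.nan, 3.0])
        out = sficd.normalize_to_template(v, np.array([1, 1, 2]))
        assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 3.0

    def test_missing_correspondence_rejected(self):
        with pytest.raises(ValueError):
            sficd.normalize_to_template(np.ones(3), None)


class TestSmoothing:
    def test_constant_map_is_fixed_point(self, sheet40):
        vals = np.full(sheet40.n_vertices, 0.37)
        out = sficd.smooth_surface(vals, sheet40, fwhm_mm=15.0)
        assert np.abs(out - 0.37).max() < 1e-12

    def test_fwhm_zero_is_identity(self, sheet40):
        rng = np.random.default_rng(0)
        vals = rng.random(sheet40.n_vertices)
        assert np.array_equal(sficd.smooth_surface(vals, sheet40, 0.0), vals)

    def test_linear_and_bounded(self, sheet40):
        rng = np.random.default_rng(1)
        W = sficd.smoothing_operator(sheet40, 10.0)
        a = rng.random(sheet40.n_vertices)
        b = rng.random(sheet40.n_vertices)
        sa = sficd.smooth_surface(a, sheet40, operator=W)
        sb = sficd.smooth_surface(b, sheet40, operator=W)
        sab = sficd.smooth_surface(2 * a + b, sheet40, operator=W)
        assert np.allclose(sab, 2 * sa + sb, atol=1e-10)
        assert sa.max() <= a.max() + 1e-12 and sa.min() >= a.min() - 1e-12

    def test_missing_vertices_excluded_and_renormalized(self, sheet40):
        vals = np.full(sheet40.n_vertices, 2.0)
        vals[100:120] = np.nan
        out = sficd.smooth_surface(vals, sheet40, fwhm_mm=10.0)
        assert np.all(np.isnan(out[100:120]))
        ok = ~np.isnan(vals)
        assert np.allclose(out[ok], 2.0, atol=1e-12)

    def test_impulse_response_fwhm_calibrated(self):
        """Measured impulse-response FWHM on a fine sheet = 15 mm +/- 10%."""
        big = sficd.generate_sheet_mesh((60, 60), 1.0)
        center = big.n_vertices // 2
        imp = np.zeros(big.n_vertices)
        imp[center] = 1.0
        resp = sficd.smooth_surface(imp, big, fwhm_mm=15.0)
        c = big.vertices[center]
        row = np.isclose(big.vertices[:, 1], c[1])
        xs, ys = big.vertices[row, 0], resp[row]
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        half = resp.max() / 2.0
        above = np.flatnonzero(ys >= half)
        i0, i1 = above[0], above[-1]
        left = np.interp(half, [ys[i0 - 1], ys[i0]], [xs[i0 - 1], xs[i0]])
        right = np.interp(half, [ys[i1 + 1], ys[i1]], [xs[i1 + 1], xs[i1]])
        assert (right - left) == pytest.approx(15.0, rel=0.10)


class TestEndToEndDensity:
    def test_fa_ratio_recovered(self):
        """Bundles of FA 0.6 vs 0.4 in equal-volume CUs: SFiCD ratio 1.5."""
        mk = lambda y, fa, bid: sficd.BundleSpec(
            endpoint_a=(6, y, 8), endpoint_b=(18, y, 8), arc_depth=0.0,
            tube_radius=0.6, fa_inside=fa, id=bid)
        spec = sficd.PhantomSpec(grid_shape=(24, 20, 16), voxel_size=(1, 1, 1),
                                 bundles=[mk(6, 0.6, "hi"), mk(14, 0.4, "lo")],
                                 fa_background=0.05, rng_seed=2)
        field, _ = sficd.generate_diffusion_field(spec)
        t = sficd.track_short_range(field)
        masks = [
            sficd.CUMask(cu_id=0, voxels=np.array(
                [[i, j, k] for i in list(range(4, 9)) + list(range(16, 21))
                 for j in (5, 6, 7) for k in (7, 8, 9)]), volume_mm3=90.0),
            sficd.CUMask(cu_id=1, voxels=np.array(
                [[i, j, k] for i in list(range(4, 9)) + list(range(16, 21))
                 for j in (13, 14, 15) for k in (7, 8, 9)]), volume_mm3=90.0),
        ]
        tbl = sficd.sficd_per_cu(t, masks, field.affine)
        hi = float(tbl.loc[tbl.cu_id == 0, "sficd"].iloc[0])
        lo = float(tbl.loc[tbl.cu_id == 1, "sficd"].iloc[0])
        assert hi > 0 and lo > 0
        assert hi / lo == pytest.approx(1.5, rel=0.10)
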