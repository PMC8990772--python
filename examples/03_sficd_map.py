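"""Compute a whole-surface SFiCD map for one synthetic subject.

SFiCD for a cortical unit is the sum of the mean FA of the short-range
fibers terminating in its subcortical voxel layer, divided by the layer
volume (mm^-3).  The per-CU values are projected to the vertices and
smoothed with a 6 mm geodesic Gaussian kernel (15 mm is the default for
brain-scale meshes; this sheet is only 38 mm wide).
"""
import numpy as np

import sficd

z = 8.0
bundles = [
    sficd.BundleSpec(endpoint_a=(10, 14, z), endpoint_b=(22, 14, z),
                     arc_depth=4.0, tube_radius=1.2, fa_inside=0.6, id="u1"),
    sficd.BundleSpec(endpoint_a=(14, 26, z), endpoint_b=(26, 26, z),
                     arc_depth=4.0, tube_radius=1.2, fa_inside=0.4, id="u2"),
]
spec = sficd.PhantomSpec(grid_shape=(40, 40, 16), voxel_size=(1, 1, 1),
                         bundles=bundles, fa_background=0.05, rng_seed=0)
field, _ = sficd.generate_diffusion_field(spec)
tracks = sficd.track_short_range(field)

mesh = sficd.generate_sheet_mesh((38, 38), 1.9, origin=(0.5, 0.5, 12.0))
parc = sficd.parcellate(mesh, K=64, rng_seed=0)
masks = sficd.cu_voxel_layer(parc, mesh, field.affine, field.shape, depth_mm=4.0)

smap, table = sficd.subject_sficd_map(tracks, parc, masks, mesh, field.affine,
                                      fwhm_mm=6.0, subject_id="sub-000")
hit = table[table.n_fibers > 0]
print("CUs receiving fibers:")
print(hit.to_string(index=False))
print(f"\nvertex map: {np.nanmax(smap.vertex_values):.4f} mm^-3 peak after "
      f"{smap.smoothed_fwhm:.0f} mm smoothing")
print("-> the CU above the FA-0.6 bundle carries ~1.5x the SFiCD of the")
print("   FA-0.4 bundle's CU when fiber counts and volumes match")
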