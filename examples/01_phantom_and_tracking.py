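"""Build a diffusion phantom with two U-fiber bundles and track it.

Bundles are circular-arc tubes with closed-form length, so the printed
"truth" column is analytic; the tracker should recover each length to
within about a step plus the seed's offset inside the tube.
"""
import numpy as np

import sficd

bundles = [
    sficd.BundleSpec(endpoint_a=(6, 10, 8), endpoint_b=(18, 10, 8),
                     arc_depth=0.0, tube_radius=0.6, fa_inside=0.8, id="straight"),
    sficd.BundleSpec(endpoint_a=(8, 24, 10), endpoint_b=(20, 24, 10),
                     arc_depth=4.0, tube_radius=1.0, fa_inside=0.6, id="u-arc"),
]
spec = sficd.PhantomSpec(grid_shape=(28, 32, 16), voxel_size=(1, 1, 1),
                         bundles=bundles, fa_background=0.05, rng_seed=0)
field, truth = sficd.generate_diffusion_field(spec)
print("ground truth (closed-form arc lengths):")
print(truth[["bundle_id", "arc_length_mm", "fa_inside"]].to_string(index=False))

tracks = sficd.track_volume(field)                 # one seed per supra-FA voxel
kept = sficd.filter_by_length(tracks, 10, 65)      # the short-range window
print(f"\n{len(tracks)} streamlines tracked, {len(kept)} in the 10-65 mm window")
print(f"recovered lengths: median {np.median(kept.lengths):.2f} mm, "
      f"range {kept.lengths.min():.2f}-{kept.lengths.max():.2f} mm")
print("-> each bundle's fibers cluster at its analytic length; fragments")
print("   shorter than 10 mm (false tracts at tube edges) were filtered out")
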