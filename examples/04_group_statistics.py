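"""Group comparison of vertexwise SFiCD maps with cluster correction.

A synthetic cohort carries a +0.1 mm^-3 group effect inside an 8 mm disc.
The DODS GLM (per-group intercepts and per-group slopes for age, sex,
education and intracranial volume) tests the offset contrast; supra-
threshold clusters are tested against 1000 smoothed Gaussian null maps.
"""
import numpy as np

import sficd

mesh = sficd.generate_sheet_mesh((39, 39), 1.5)
d = np.linalg.norm(mesh.vertices[:, :2] - 19.5, axis=1)
effect = np.where(d <= 8.0, 0.1, 0.0)

spec = sficd.CohortSpec(mesh=mesh, n_per_group=20, noise_sd=0.05,
                        noise_fwhm=6.0, effect_map=effect, rng_seed=7)
maps, design = sficd.generate_cohort_maps(spec)
print(design[["subject", "group", "age", "homocysteine"]].head(4).to_string(index=False))

X = sficd.build_dods_design(design, covariates=("age", "sex", "education", "tiv"))
res = sficd.fit_glm_vertexwise(maps["t0"], X, "group_offset")
print(f"\npeak |t| = {np.nanmax(np.abs(res.t)):.2f} "
      f"({int((res.p < 0.01).sum())} vertices at p < 0.01)")

report = sficd.cluster_correct_montecarlo(res, mesh, vertex_p=0.01,
                                          cluster_p=0.01, n_iter=1000,
                                          rng_seed=11)
print(f"residual smoothness estimate: {report.fwhm_mm:.1f} mm FWHM")
print(report.table().to_string(index=False))
sig = report.significant
overlap = any((d[c.vertices] <= 8.0).any() for c in sig)
print(f"\n{len(sig)} cluster(s) survive Monte Carlo correction at p < 0.01; "
      f"overlap with the injected disc: {overlap}")
print("-> the pipeline recovers where the group difference was planted,")
print("   not just that one exists somewhere")
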