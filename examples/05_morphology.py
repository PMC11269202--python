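"""Fibril morphometry: widths, branch points and striation spacing.

Measures maximum caliper diameters of planted filaments (tau-like ~15 nm vs
beta-amyloid-like ~6 nm), detects the branch point of a Y-shaped fibril by
3D skeletonisation, and recovers the internal layer spacing of a striated
cuboidal particle by 1D Fourier analysis.
"""

import numpy as np

from filtomo import morphology as M, scene as S

sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)

# widths of the two filament families
for tid in ("phf_like", "abeta_fibril"):
    vol = S.render_template_reference(tid, 32, 9.52,
                                      twist_rate=2.5 if tid == "phf_like" else 0.0)
    d = M.max_diameter(vol, (15.5, 15.5, 16), (0, 0, 1), 9.52)
    print(f"{tid}: max caliper diameter {d:.1f} nm")

# a branched beta-amyloid fibril
parent = S.FilamentSpec((20, 45, 20), (70, 45, 70),
                        template_id="abeta_fibril", twist_rate=0.0)
child = S.make_branch(parent, arc_nm=35.0, angle_deg=35.0, length_nm=30.0,
                      azimuth_deg=90.0)
parent.branches = [(35.0, 35.0, child)]
vol = S.render_filament(parent, sc)
counts = M.detect_branches(vol, threshold=0.3 * vol.max())
pct, frac = M.branch_fraction(sum(c > 0 for c in counts), len(counts))
print(f"branch points per object: {counts}; "
      f"branched fraction {pct}% ({frac})")
print(f"(worked example: 17 of 51 fibrils branched = "
      f"{M.branch_fraction(17, 51)[0]}%)")

# striation spacing of a cuboidal particle at snr 1
sc2 = S.SceneSpec(volume_shape=(64, 64, 64), voxel_size=9.52, snr=1.0, seed=5)
sc2.particles = [S.CuboidParticleSpec(center=(30, 30, 30),
                                      edge_lengths=(45, 45, 45),
                                      layer_normal=(1, 0, 0),
                                      layer_spacing=2.5)]
sim = S.build_scene(sc2)
res = M.striation_spacing(sim.volume.astype(float), (slice(9, 55),) * 3,
                          (1, 0, 0), 9.52)
print(f"striation spacing: {res.spacing_nm:.2f} nm "
      f"(planted 2.5 nm; spectral peak {res.peak_snr:.0f}x median level)")
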