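"""Missing-wedge-aware subtomogram alignment and averaging of a cluster.

Simulates a 10-filament PHF-like cluster at snr 1, picks it from ground
truth with randomised head/tail (so polarity is unknown), aligns 24^3
subvolumes in restricted mode (spin about the axis + flip + axial shift)
against a rendered template reference, and reports the half-map FSC and the
helical twist measured from the average.
"""

import numpy as np

from filtomo import align as A, fsc as F, helix as H, picking as P, scene as S

spec = S.standard_test_scene(seed=7, n_filaments=10, n_opposite=3,
                             shape=(128, 128, 128))
sim = S.build_scene(spec)

contours = P.contours_from_ground_truth(sim.ground_truth, spec.voxel_nm, seed=1)
records = []
for tube_id, c in enumerate(contours, start=1):
    records.extend(P.add_points_along_axis(P.stalk_init(c, tube_id), spacing=4.0))
table = P.ParticleTable(records=records, voxel_size_a=spec.voxel_size,
                        volume_shape=sim.volume.shape)

stack = A.extract_subvolumes(sim.volume, table, 24)
reference = S.render_template_reference("phf_like", 24, spec.voxel_size)
params = A.AlignmentParams(max_iterations=5)
refined, avg = A.align_iterate(stack, table, params, mode="restricted",
                               tilts=spec.tilts, reference=reference)

curve = F.fsc(avg.half_map_a, avg.half_map_b, mask=avg.mask,
              voxel_size_a=spec.voxel_size)
tw = H.measure_twist_from_average(avg.map, voxel_size_a=spec.voxel_size)

print(f"aligned {len(stack)} segments from {len(contours)} filaments")
flag = "" if curve.crossed else " (curve never drops below 0.143: "\
    "resolution is sampling-limited at Nyquist)"
print(f"half-map FSC 0.143 resolution: {curve.resolution_a:.1f} A{flag}")
print(f"measured twist: {tw.twist_deg_per_nm:.2f} deg/nm -> crossover "
      f"{tw.crossover_nm:.1f} nm (planted: 2.5 deg/nm, 72 nm)")
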