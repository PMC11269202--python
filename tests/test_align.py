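"""Subvolume extraction, wedge-constrained scoring, alignment, symmetry."""

import numpy as np
import pytest

from filtomo import align as A, geometry, picking as P, scene as S
from filtomo.fsc import fsc
from filtomo.helix import HelicalParams


def table_from_ground_truth(sim, spacing=4.0, perturb_psi=0.0, perturb_axis=0.0,
                            seed=0):
    """Particle table built directly from planted segment orientations."""
    rng = np.random.default_rng(seed)
    recs = []
    for row in sim.ground_truth.itertuples():
        if row.track_length_vox % spacing != 0:
            continue
        euler = (row.rot_deg, row.tilt_deg, row.psi_deg)
        if perturb_psi or perturb_axis:
            m = geometry.euler_to_matrix(*euler)
            dpsi = rng.uniform(-perturb_psi, perturb_psi)
            drot = rng.uniform(-perturb_axis, perturb_axis)
            dtilt = rng.uniform(-perturb_axis, perturb_axis)
            m = m @ geometry.euler_to_matrix(drot, dtilt, dpsi)
            euler = geometry.matrix_to_euler(m)
        recs.append(P.SegmentRecord(
            position=(row.x_vox, row.y_vox, row.z_vox), euler=euler,
            tube_id=int(row.tube_id), track_length=float(row.track_length_vox),
        ))
    return P.ParticleTable(records=recs, voxel_size_a=sim.scene.voxel_size,
                           volume_shape=sim.volume.shape)


class TestExtract:
    def test_center_record_is_central_crop(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(64, 64, 64))
        table = P.ParticleTable(records=[P.SegmentRecord(
            position=(32, 32, 32), euler=(0, 0, 0))])
        stack = A.extract_subvolumes(vol, table, 16)
        assert len(stack) == 1 and stack.n_skipped == 0
        np.testing.assert_array_equal(stack.data[0], vol[24:40, 24:40, 24:40])

    def test_edge_record_skipped(self):
        vol = np.zeros((64, 64, 64))
        table = P.ParticleTable(records=[
            P.SegmentRecord(position=(3, 32, 32), euler=(0, 0, 0)),
            P.SegmentRecord(position=(32, 32, 32), euler=(0, 0, 0)),
        ])
        stack = A.extract_subvolumes(vol, table, 16)
        assert stack.n_skipped == 1 and len(stack) == 1

    def test_box_larger_than_volume_rejected(self):
        with pytest.raises(ValueError, match="box"):
            A.extract_subvolumes(np.zeros((8, 8, 8)), P.ParticleTable(records=[]), 16)

    def test_planted_segments_are_centred_on_the_axis(self):
        # noiseless scene: the density peak of each subvolume sits on the
        # filament axis through the box centre (peak offset perpendicular to
        # the axis stays within ~2 voxels)
        spec = S.standard_test_scene(seed=29, n_filaments=5, n_opposite=0,
                                     shape=(96, 96, 96), snr=np.inf)
        sim = S.build_scene(spec)
        table = table_from_ground_truth(sim, spacing=8.0)
        stack = A.extract_subvolumes(sim.volume, table, 16)
        from scipy import ndimage

        offs = []
        grids = np.meshgrid(*[np.arange(16)] * 3, indexing="ij")
        for sub, i in zip(stack.data, stack.kept_indices):
            sm = ndimage.gaussian_filter(sub, 1.0)
            tot = sm.sum()
            com = np.array([(g * sm).sum() / tot for g in grids])[::-1]
            rel = com - 7.5  # (x, y, z) offset from the box centre
            d = geometry.direction_from_euler(*table.records[i].euler)
            perp = rel - (rel @ d) * d
            offs.append(np.linalg.norm(perp))
        assert np.median(offs) <= 2.0


class TestConstrainedCC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(24, 24, 24))
        assert A.constrained_cc(v, v) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_scores_near_zero(self):
        scores = []
        mask = S.wedge_mask((64, 64, 64))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(64, 64, 64))
            b = rng.normal(size=(64, 64, 64)) if True else a
            rng2 = np.random.default_rng(10_000 + seed)
            b = rng2.normal(size=(64, 64, 64))
            scores.append(abs(A.constrained_cc(a, b, mask)))
        assert np.quantile(scores, 0.99) < 0.05

    def test_full_mask_reduces_to_plain_ncc(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(16, 16, 16))
        b = rng.normal(size=(16, 16, 16)) + 0.3 * a
        plain = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        full = A.constrained_cc(a, b, np.ones_like(a, dtype=bool))
        assert full == pytest.approx(plain, abs=1e-9)

    def test_wedge_honesty(self):
        # a volume and its wedge-filtered copy agree perfectly inside the
        # wedge, but plain correlation penalises the missing region
        rng = np.random.default_rng(2)
        v = rng.normal(size=(32, 32, 32))
        filt, mask = S.apply_missing_wedge(v)
        assert A.constrained_cc(v, filt, mask) == pytest.approx(1.0, abs=1e-6)
        assert A.constrained_cc(v, filt) < 0.95

    def test_empty_support_rejected(self):
        v = np.ones((8, 8, 8))
        with pytest.raises(ValueError, match="support"):
            A.constrained_cc(v, v, np.zeros_like(v, dtype=bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            A.constrained_cc(np.zeros((8, 8, 8)), np.zeros((9, 9, 9)))


class TestAverage:
    def test_average_of_identical_subvolumes_is_the_subvolume(self):
        rng = np.random.default_rng(3)
        sub = rng.normal(size=(16, 16, 16))
        recs = [P.SegmentRecord(position=(32, 32, 32), euler=(0, 0, 0),
                                tube_id=t, track_length=0.0) for t in (1, 2, 3, 4)]
        table = P.ParticleTable(records=recs)
        stack = A.SubvolumeStack(data=np.stack([sub] * 4),
                                 kept_indices=np.arange(4), n_skipped=0)
        avg = A.average_map(stack, table, tilts=None)
        np.testing.assert_allclose(avg.map, sub, atol=1e-9)
        np.testing.assert_allclose(avg.map, 0.5 * (avg.half_map_a + avg.half_map_b),
                                   atol=1e-9)
        assert avg.n_contributing == 4

    def test_half_sets_split_whole_tubes(self):
        recs = [P.SegmentRecord(position=(32, 32, 32), euler=(0, 0, 0),
                                tube_id=t, track_length=0.0)
                for t in (1, 1, 2, 2, 3, 3)]
        table = P.ParticleTable(records=recs)
        data = np.zeros((6, 8, 8, 8))
        data[[0, 1]] = 1.0  # tube 1
        data[[2, 3]] = 2.0  # tube 2
        data[[4, 5]] = 3.0  # tube 3
        stack = A.SubvolumeStack(data=data, kept_indices=np.arange(6), n_skipped=0)
        avg = A.average_map(stack, table, tilts=None)
        # odd tubes (1, 3) -> half A; even tube 2 -> half B: means 2.0 / 2.0
        assert avg.half_map_a.mean() == pytest.approx(2.0, abs=1e-9)
        assert avg.half_map_b.mean() == pytest.approx(2.0, abs=1e-9)


class TestAlignIterate:
    def test_zero_iterations_leaves_table_unchanged(self, small_cluster_sim):
        spec, sim = small_cluster_sim
        table = table_from_ground_truth(sim, spacing=8.0)
        stack = A.extract_subvolumes(sim.volume, table, 16)
        params = A.AlignmentParams(max_iterations=0, mask_radius_vox=6)
        refined, avg = A.align_iterate(stack, table, params, tilts=spec.tilts)
        for a, b in zip(refined.records, table.records):
            assert a.euler == b.euler and a.position == b.position

    def test_restricted_recovers_perturbed_spin(self):
        # noiseless axial cluster; spins perturbed by half the grid step must
        # come back to within one step of truth
        spec = S.standard_test_scene(seed=13, n_filaments=5, n_opposite=0,
                                     shape=(96, 96, 96), snr=np.inf)
        sim = S.build_scene(spec)
        table = table_from_ground_truth(sim, spacing=4.0, perturb_psi=6.0, seed=1)
        truth = table_from_ground_truth(sim, spacing=4.0)
        stack = A.extract_subvolumes(sim.volume, table, 24)
        params = A.AlignmentParams(max_iterations=2, psi_step_deg=12.0,
                                   translation_limit_vox=2)
        ref = S.render_template_reference("phf_like", 24, spec.voxel_size)
        refined, _ = A.align_iterate(stack, table, params, mode="restricted",
                                     tilts=spec.tilts, reference=ref)
        errs = []
        for i in stack.kept_indices:
            m_t = geometry.euler_to_matrix(*truth.records[i].euler)
            m_r = geometry.euler_to_matrix(*refined.records[i].euler)
            # the C2 cross-section makes psi and psi+180 physically identical
            errs.append(min(
                geometry.angular_distance_deg(m_t @ geometry.rotz(s), m_r)
                for s in (0.0, 180.0)
            ))
        frac_ok = np.mean(np.asarray(errs) <= params.psi_step_deg)
        assert frac_ok >= 0.99

    def test_full_mode_recovers_perturbed_axis(self):
        # axes perturbed by up to 6 degrees come back within the intrinsic
        # single-segment precision (90% within 10 degrees), and per-filament
        # mean directions land much closer
        spec = S.standard_test_scene(seed=17, n_filaments=4, n_opposite=0,
                                     shape=(96, 96, 96), snr=np.inf)
        sim = S.build_scene(spec)
        table = table_from_ground_truth(sim, spacing=4.0, perturb_axis=6.0, seed=2)
        truth = table_from_ground_truth(sim, spacing=4.0)
        stack = A.extract_subvolumes(sim.volume, table, 24)
        params = A.AlignmentParams(max_iterations=2, full_step_deg=3.0,
                                   full_range_deg=9.0, translation_limit_vox=2,
                                   search_flips=False)
        ref = S.render_template_reference("phf_like", 24, spec.voxel_size)
        refined, _ = A.align_iterate(stack, table, params, mode="full",
                                     tilts=spec.tilts, reference=ref)
        errs = []
        tube_dirs: dict = {}
        for i in stack.kept_indices:
            d_t = geometry.direction_from_euler(*truth.records[i].euler)
            d_r = geometry.direction_from_euler(*refined.records[i].euler)
            errs.append(np.degrees(np.arccos(np.clip(abs(d_t @ d_r), -1, 1))))
            tube_dirs.setdefault(refined.records[i].tube_id, []).append((d_r, d_t))
        assert np.mean(np.asarray(errs) <= 10.0) >= 0.9
        for tube, pairs in tube_dirs.items():
            mean_dir = np.mean([p[0] for p in pairs], axis=0)
            mean_dir /= np.linalg.norm(mean_dir)
            ang = np.degrees(np.arccos(np.clip(abs(mean_dir @ pairs[0][1]), -1, 1)))
            assert ang <= 5.0

    def test_noisy_cluster_axis_within_ten_degrees(self, small_cluster_sim):
        # snr-1 cluster aligned from picks: refined axes stay close to truth
        spec, sim = small_cluster_sim
        contours = P.contours_from_ground_truth(sim.ground_truth, spec.voxel_nm,
                                                seed=1)
        recs = []
        for tid, c in enumerate(contours, start=1):
            recs.extend(P.add_points_along_axis(P.stalk_init(c, tid), spacing=4.0))
        table = P.ParticleTable(records=recs, voxel_size_a=spec.voxel_size,
                                volume_shape=sim.volume.shape)
        stack = A.extract_subvolumes(sim.volume, table, 24)
        params = A.AlignmentParams(max_iterations=4)
        ref = S.render_template_reference("phf_like", 24, spec.voxel_size)
        refined, _ = A.align_iterate(stack, table, params, mode="restricted",
                                     tilts=spec.tilts, reference=ref)
        gt_dirs = {
            int(t): np.array([g.polarity_x.iloc[0], g.polarity_y.iloc[0],
                              g.polarity_z.iloc[0]])
            for t, g in sim.ground_truth.groupby("tube_id")
        }
        ok = 0
        for i in stack.kept_indices:
            rec = refined.records[i]
            d = geometry.direction_from_euler(*rec.euler)
            ang = np.degrees(np.arccos(np.clip(
                abs(d @ gt_dirs[rec.tube_id]), -1, 1)))
            ok += ang <= 10.0
        assert ok / len(stack) >= 0.9


class TestHelicalSymmetrize:
    def test_smooth_cylinder_is_a_fixed_point(self):
        # a rotationally and axially invariant tube is symmetric under any
        # (twist, rise); symmetrisation must reproduce it
        zz, yy, xx = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        tube = np.exp(-((xx - 15.5) ** 2 + (yy - 15.5) ** 2) / (2 * 5.0**2))
        helix = HelicalParams(twist_per_subunit=179.44, rise=2.405,
                              symmetry_order=2)
        out = A.helical_symmetrize(tube, helix, n_copies=2, voxel_size_a=9.52)
        core = (slice(8, 24),) * 3
        rms = np.sqrt(np.mean((out[core] - tube[core]) ** 2))
        assert rms < 1e-4 * tube.max()

    def test_idempotent_on_symmetrized_map(self):
        ref = S.render_template_reference("phf_like", 32, 9.52, twist_rate=2.33)
        helix = HelicalParams(twist_per_subunit=179.44, rise=2.405,
                              symmetry_order=2)
        once = A.helical_symmetrize(ref, helix, n_copies=2, voxel_size_a=9.52)
        twice = A.helical_symmetrize(once, helix, n_copies=2, voxel_size_a=9.52)
        core = (slice(10, 22),) * 3
        rms = np.sqrt(np.mean((twice[core] - once[core]) ** 2))
        assert rms < 2e-2 * once.max()

    def test_symmetrizing_noisy_filament_improves_match(self):
        truth = S.render_template_reference("phf_like", 32, 9.52, twist_rate=2.33)
        noisy = S.add_noise(truth, 0.5, seed=4)
        helix = HelicalParams(twist_per_subunit=179.44, rise=2.405,
                              symmetry_order=2)
        sym = A.helical_symmetrize(noisy, helix, n_copies=2, voxel_size_a=9.52)
        core = (slice(8, 24),) * 3

        def cc(a, b):
            a = a[core].ravel() - a[core].mean()
            b = b[core].ravel() - b[core].mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        assert cc(sym, truth) > cc(noisy, truth)

    def test_subvoxel_rise_warns(self):
        helix = HelicalParams(twist_per_subunit=179.44, rise=1.0)
        with pytest.warns(UserWarning, match="rise"):
            A.helical_symmetrize(np.zeros((8, 8, 8)), helix, 1, voxel_size_a=9.52)


@pytest.fixture(scope="module")
def refs():
    return {
        "phf_like": S.render_template_reference("phf_like", 24, 9.52),
        "sf_like": S.render_template_reference("sf_like", 24, 9.52),
    }


class TestClassification:

    def test_noiseless_mixed_scene_fully_correct(self, refs):
        spec = S.mixed_class_scene(seed=21, n_each=4, shape=(96, 96, 96),
                                   snr=np.inf)
        sim = S.build_scene(spec)
        table = table_from_ground_truth(sim, spacing=4.0)
        stack = A.extract_subvolumes(sim.volume, table, 24)
        labels, _ = A.classify_two_references(stack, table, refs,
                                              tilts=spec.tilts)
        truth = {int(t): g.template_id.iloc[0]
                 for t, g in sim.ground_truth.groupby("tube_id")}
        assert all(labels[t] == truth[t] for t in labels)

    def test_single_class_scene_all_one_label(self, refs):
        spec = S.standard_test_scene(seed=23, n_filaments=4, n_opposite=0,
                                     shape=(96, 96, 96), snr=np.inf)
        sim = S.build_scene(spec)
        table = table_from_ground_truth(sim, spacing=4.0)
        stack = A.extract_subvolumes(sim.volume, table, 24)
        labels, _ = A.classify_two_references(stack, table, refs,
                                              tilts=spec.tilts)
        assert set(labels.values()) == {"phf_like"}

    def test_identical_references_rejected(self, refs):
        table = P.ParticleTable(records=[P.SegmentRecord(
            position=(12, 12, 12), euler=(0, 0, 0))])
        stack = A.SubvolumeStack(data=np.zeros((1, 24, 24, 24)),
                                 kept_indices=np.array([0]), n_skipped=0)
        with pytest.raises(ValueError, match="identical"):
            A.classify_two_references(
                stack, table,
                {"a": refs["phf_like"], "b": refs["phf_like"]})


class TestFsc:
    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        ca = fsc(a, b, voxel_size_a=9.52)
        cb = fsc(b, a, voxel_size_a=9.52)
        np.testing.assert_array_equal(ca.values, cb.values)

    def test_identical_halves_give_unity_and_nyquist(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(32, 32, 32))
        c = fsc(a, a, voxel_size_a=9.52)
        assert np.allclose(c.values, 1.0, atol=1e-9)
        assert not c.crossed
        assert c.resolution_a == pytest.approx(2 * 9.52)

    def test_independent_noise_shells_bounded(self):
        # the two lowest-frequency shells hold < 150 coefficients and are
        # sampling-limited; all others stay below 0.2 at the 99th percentile
        worst = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(64, 64, 64))
            b = np.random.default_rng(900 + seed).normal(size=(64, 64, 64))
            worst.append(np.abs(fsc(a, b, voxel_size_a=1.0).values[2:]).max())
        assert np.quantile(worst, 0.99) < 0.2

    def test_band_limited_signal_resolution(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=(64, 64, 64))
        k = np.meshgrid(*[np.fft.fftfreq(64)] * 3, indexing="ij")
        km = np.sqrt(sum(g * g for g in k))
        voxel = 4.76
        band = voxel / 20.0  # cycles/voxel at 20 A
        lp = np.real(np.fft.ifftn(np.fft.fftn(sig) * (km <= band)))
        a = lp + 0.35 * rng.normal(size=lp.shape)
        b = lp + 0.35 * np.random.default_rng(70).normal(size=lp.shape)
        curve = fsc(a, b, voxel_size_a=voxel)
        shell_a = 1.0 / (curve.shell_freq[1] - curve.shell_freq[0]) / (20.0 / voxel)
        assert curve.crossed
        assert abs(curve.resolution_a - 20.0) < 2.0  # within one shell

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fsc(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)))
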