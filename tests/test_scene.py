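"""Synthetic-scene generator: rendering, missing wedge, noise, ground truth."""

import numpy as np
import pytest

from filtomo import io, scene as S
from filtomo.templates import TEMPLATE_IDS, get_template


def corr2(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


class TestTemplates:
    def test_nonnegative_and_bounded(self):
        for tid in TEMPLATE_IDS:
            t = get_template(tid)
            assert np.all(t.density >= 0)
            # suprathreshold support lies within the nominal max diameter
            ys, xs = np.nonzero(t.density >= 0.5 * t.density.max())
            c = (np.asarray(t.density.shape) - 1) / 2.0
            r = np.hypot(ys - c[0], xs - c[1]).max() * t.pitch_nm
            assert 2 * r <= t.nominal_max_diameter_nm + 3.0

    def test_phf_is_twofold_symmetric(self):
        t = get_template("phf_like")
        d = t.density
        rms = np.sqrt(np.mean((d - d[::-1, ::-1]) ** 2)) / np.sqrt(np.mean(d**2))
        assert rms < 0.01

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown template_id"):
            get_template("nope")


class TestRenderFilament:
    def test_no_twist_gives_identical_cross_sections(self):
        spec = S.FilamentSpec((45, 45, 5), (45, 45, 85),
                              template_id="phf_like", twist_rate=0.0)
        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        vol = S.render_filament(spec, sc)
        assert vol.max() > 0
        assert np.abs(vol[40] - vol[50]).max() < 1e-9 * vol.max()

    def test_cross_section_repeats_at_the_crossover(self, noiseless_axial_filament):
        # 2.5 deg/nm on a C2 template repeats every 180/2.5 = 72 nm
        _, sc, vol = noiseless_axial_filament
        vox_nm = sc.voxel_nm
        z0 = 50
        dz = int(round(72.0 / vox_nm))
        assert corr2(vol[z0], vol[z0 + dz]) > 0.99
        # off-repeat separations decorrelate
        assert corr2(vol[z0], vol[z0 + dz // 2]) < 0.6

    def test_out_of_bounds_raises_naming_the_spec(self):
        spec = S.FilamentSpec((2, 45, 5), (2, 45, 85), template_id="phf_like")
        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        with pytest.raises(S.OutOfBoundsError, match="phf_like"):
            S.render_filament(spec, sc)

    def test_branch_produces_one_junction(self):
        from filtomo.morphology import detect_branches

        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        parent = S.FilamentSpec((20, 45, 20), (70, 45, 70),
                                template_id="abeta_fibril", twist_rate=0)
        child = S.make_branch(parent, arc_nm=35.0, angle_deg=35.0,
                              length_nm=30.0, azimuth_deg=90.0)
        parent.branches = [(35.0, 35.0, child)]
        vol = S.render_filament(parent, sc)
        assert detect_branches(vol, threshold=0.3 * vol.max()) == [1]

    def test_branches_forbidden_on_tau_templates(self):
        parent = S.FilamentSpec((20, 45, 20), (70, 45, 70),
                                template_id="abeta_fibril", twist_rate=0)
        child = S.make_branch(parent, 20, 30, 20)
        with pytest.raises(ValueError, match="branches"):
            S.FilamentSpec((20, 45, 20), (70, 45, 70), template_id="phf_like",
                           branches=[(20, 30, child)])

    def test_rendering_is_linear_for_disjoint_supports(self):
        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        f1 = S.FilamentSpec((25, 25, 10), (25, 25, 80),
                            template_id="abeta_fibril", twist_rate=0)
        f2 = S.FilamentSpec((65, 65, 10), (65, 65, 80),
                            template_id="abeta_fibril", twist_rate=0)
        both = S.render_filament(f1, sc) + S.render_filament(f2, sc)
        sc2 = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52,
                          filaments=[f1, f2], snr=np.inf,
                          tilts=S.TiltScheme(-90, 90, 2))
        sim = S.build_scene(sc2)
        assert np.abs(sim.volume - both).max() < 1e-5 * both.max()


class TestRenderCuboid:
    def test_zero_contrast_block_has_no_interior_peak(self):
        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        p = S.CuboidParticleSpec(center=(45, 45, 45), edge_lengths=(50, 50, 50),
                                 layer_contrast=0.0)
        vol = S.render_cuboid(p, sc)
        profile = vol[24:72, 45, 45]
        power = np.abs(np.fft.rfft(profile - profile.mean())) ** 2
        assert power[2:].max() < 0.05 * (profile**2).sum()

    @pytest.mark.parametrize("spacing", [2.5, 2.8])
    def test_layer_spacing_recovered(self, spacing):
        from filtomo.morphology import striation_spacing

        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        p = S.CuboidParticleSpec(center=(45, 45, 45), edge_lengths=(50, 50, 50),
                                 layer_normal=(0, 0, 1), layer_spacing=spacing)
        vol = S.render_cuboid(p, sc)
        res = striation_spacing(vol, (slice(22, 70),) * 3, (0, 0, 1), 9.52)
        assert res.spacing_nm == pytest.approx(spacing, abs=res.frequency_bin_nm)

    def test_spacing_rotation_invariant(self):
        from filtomo.morphology import striation_spacing

        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        n = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        p = S.CuboidParticleSpec(center=(45, 45, 45), edge_lengths=(50, 50, 50),
                                 layer_normal=tuple(n), layer_spacing=2.8)
        vol = S.render_cuboid(p, sc)
        res = striation_spacing(vol, (slice(26, 66),) * 3, n, 9.52)
        assert res.spacing_nm == pytest.approx(2.8, abs=2 * res.frequency_bin_nm)

    def test_aliasing_guard(self):
        sc = S.SceneSpec(volume_shape=(96, 96, 96), voxel_size=9.52)
        p = S.CuboidParticleSpec(center=(45, 45, 45), layer_spacing=2.5)
        with pytest.raises(S.AliasingError):
            S.render_cuboid(p, S.SceneSpec(volume_shape=(96, 96, 96),
                                           voxel_size=15.0))
        S.render_cuboid(p, sc)  # fine at 9.52 A

    def test_edge_range_validated(self):
        with pytest.raises(ValueError, match="27-200"):
            S.CuboidParticleSpec(center=(45, 45, 45), edge_lengths=(20, 40, 40))


class TestMissingWedge:
    def test_full_tilt_range_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(32, 32, 32))
        out, mask = S.apply_missing_wedge(v, S.TiltScheme(-90, 90, 2))
        assert mask.all()
        assert np.abs(out - v).max() < 1e-9

    def test_retained_fraction_inside_nyquist_ball(self):
        # a +/-60 degree series keeps 120/180 = 2/3 of Fourier space
        mask = S.wedge_mask((64, 64, 64))
        k = np.meshgrid(*[np.fft.fftfreq(64)] * 3, indexing="ij")
        ball = sum(g * g for g in k) <= 0.25
        assert mask[ball].mean() == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(32, 32, 32))
        once, _ = S.apply_missing_wedge(v)
        twice, _ = S.apply_missing_wedge(once)
        assert np.abs(twice - once).max() < 1e-9

    def test_output_is_real_and_mask_shape_matches(self):
        v = np.zeros((16, 20, 24))
        v[8, 10, 12] = 1.0
        out, mask = S.apply_missing_wedge(v)
        assert out.shape == v.shape and mask.shape == v.shape
        assert np.isrealobj(out)


class TestNoise:
    def test_seed_determinism(self):
        v = np.ones((16, 16, 16))
        assert np.array_equal(S.add_noise(v, 1.0, 42), S.add_noise(v, 1.0, 42))

    def test_unit_snr_noise_variance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(64, 64, 64))
        v /= np.sqrt(np.mean(v**2))
        out = S.add_noise(v, 1.0, 3)
        assert np.var(out - v) == pytest.approx(1.0, rel=0.05)

    def test_infinite_snr_is_identity(self):
        v = np.ones((8, 8, 8))
        assert np.array_equal(S.add_noise(v, np.inf, 0), v)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            S.add_noise(np.ones((4, 4, 4)), 0.0, 0)


class TestBuildScene:
    def test_empty_scene_is_pure_noise(self):
        sc = S.SceneSpec(volume_shape=(48, 48, 48), voxel_size=9.52, snr=1.0, seed=3)
        sim = S.build_scene(sc)
        assert len(sim.ground_truth) == 0
        assert np.abs(sim.volume.mean()) < 0.1

    def test_tube_and_segment_counts(self):
        sc = S.standard_test_scene(seed=11, n_filaments=10, n_opposite=2,
                                   shape=(128, 128, 128))
        sim = S.build_scene(sc)
        assert sim.ground_truth.tube_id.nunique() == 10
        for (tube, sub), spec in zip(sim.ground_truth.groupby("tube_id"), sc.filaments):
            expected = int(np.floor(spec.length_nm / sc.voxel_nm + 1e-9)) + 1
            assert len(sub) == expected

    def test_seeded_determinism(self):
        sc = S.standard_test_scene(seed=5, n_filaments=4, n_opposite=1,
                                   shape=(96, 96, 96))
        a = S.build_scene(sc)
        b = S.build_scene(sc)
        assert np.array_equal(a.volume, b.volume)
        assert a.ground_truth.equals(b.ground_truth)

    def test_mrc_round_trip(self, tmp_path):
        sc = S.SceneSpec(volume_shape=(32, 32, 32), voxel_size=9.52, snr=2.0, seed=1)
        sim = S.build_scene(sc)
        path = tmp_path / "t.mrc"
        io.write_mrc(path, sim.volume, sc.voxel_size)
        back, voxel = io.read_mrc(path)
        assert np.array_equal(back, sim.volume.astype(np.float32))
        assert voxel == pytest.approx(9.52, abs=1e-4)

    def test_ground_truth_round_trip(self, tmp_path, small_cluster_sim):
        _, sim = small_cluster_sim
        path = tmp_path / "gt.csv"
        io.write_ground_truth(path, sim.ground_truth)
        back = io.read_ground_truth(path)
        for col in sim.ground_truth.columns:
            a, b = sim.ground_truth[col], back[col]
            if a.dtype.kind == "f":
                np.testing.assert_allclose(a, b, rtol=1e-12)
            else:
                assert (a == b).all()

    def test_scene_config_round_trip(self, tmp_path):
        sc = S.standard_test_scene(seed=2, n_filaments=3, n_opposite=1,
                                   shape=(96, 96, 96))
        for name in ("scene.yaml", "scene.json"):
            path = tmp_path / name
            io.write_scene_config(path, sc)
            back = io.read_scene_config(path)
            assert back.to_dict() == sc.to_dict()
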