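"""Seed images, smoothing, functional and structural mapping, aggregation."""

import numpy as np
import pytest

from oscillonet import (
    ConnectivityMap,
    StreamlineSet,
    VolumeImage,
    apply_gm_mask,
    functional_map,
    gen_connectome,
    gen_tractogram,
    group_aggregate,
    make_seed_image,
    mni_grid,
    noise_for_target_r,
    smooth_volume,
    structural_map,
)
from oscillonet.netmap import FunctionalConnectome


class TestMakeSeedImage:
    def test_5mm_sphere_on_2mm_grid_covers_81_voxels(self):
        # brute-force count: integer offsets with (2i)^2+(2j)^2+(2k)^2 <= 25
        seed = make_seed_image((0.0, 0.0, 0.0), 5.0, mni_grid())
        assert int(seed.values.sum()) == 81

    def test_zero_radius_single_voxel(self):
        seed = make_seed_image((1.0, 0.5, -0.5), 0.0, mni_grid())
        assert int(seed.values.sum()) == 1

    def test_translation_by_full_voxel_preserves_count(self):
        g = mni_grid()
        a = make_seed_image((3.0, -7.0, 11.0), 5.0, g)
        b = make_seed_image((3.0 - 2.0, -7.0 + 2.0, 11.0 + 2.0), 5.0, g)
        assert a.values.sum() == b.values.sum()

    def test_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_seed_image((0.0, 0.0, 500.0), 5.0, mni_grid())


class TestSmoothVolume:
    def test_delta_peak_equals_gaussian_normalisation(self):
        g = mni_grid(shape=(41, 41, 41), voxel_mm=2.0, origin_mm=(40, -40, -40))
        g.values[20, 20, 20] = 1.0
        sm = smooth_volume(g, sigma_mm=8.0)
        sigma_vox = 4.0
        expected = (2 * np.pi * sigma_vox**2) ** -1.5
        assert sm.values.max() == pytest.approx(expected, rel=0.01)

    def test_constant_image_unchanged(self, coarse_grid):
        img = VolumeImage(np.full(coarse_grid.shape, 3.7), coarse_grid.affine)
        assert np.allclose(smooth_volume(img, 8.0).values, 3.7, atol=1e-9)

    def test_total_intensity_conserved(self):
        g = mni_grid(shape=(41, 41, 41), voxel_mm=2.0, origin_mm=(40, -40, -40))
        rng = np.random.default_rng(0)
        g.values[15:26, 15:26, 15:26] = rng.uniform(size=(11, 11, 11))
        sm = smooth_volume(g, sigma_mm=4.0)
        assert sm.values.sum() == pytest.approx(g.values.sum(), rel=1e-6)


def _two_network_connectome(n_subjects=2, n_timepoints=50, noise=0.0, seed=0):
    grid = mni_grid(shape=(10, 10, 4), voxel_mm=8.0)
    vals = np.zeros(grid.shape)
    vals[:5] = 1
    vals[5:] = 2
    cmap = VolumeImage(vals, grid.affine)
    return cmap, gen_connectome(n_subjects, cmap, n_timepoints, noise, seed)


class TestFunctionalMap:
    def test_noiseless_network_structure(self):
        cmap, conn = _two_network_connectome()
        seed_xyz = conn.template.voxel_to_mm(conn.voxel_indices[0])
        seed = make_seed_image(seed_xyz, 0.0, conn.template)
        out = functional_map(seed, conn)
        labels = cmap.values
        z_cap = np.arctanh(0.999999)
        in_a = out.image.values[(labels == 1)]
        in_b = out.image.values[(labels == 2)]
        assert np.allclose(in_a, z_cap)
        assert np.nanmax(np.abs(in_b)) < 1.0  # independent latents

    def test_hand_computed_pearson_toy(self):
        # 3 voxels, 4 timepoints; two identical subjects -> mean z = z(r)
        grid = mni_grid(shape=(3, 1, 1), voxel_mm=2.0, origin_mm=(2, 0, 0))
        vox = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        ts = np.array([[1.0, 2.0, 2.0], [2.0, 1.0, 4.0], [3.0, 4.0, 8.0], [4.0, 3.0, 6.0]])
        conn = FunctionalConnectome(template=grid, voxel_indices=vox, data=[ts, ts])
        seed = VolumeImage(np.zeros(grid.shape), grid.affine)
        seed.values[0, 0, 0] = 1.0
        out = functional_map(seed, conn)
        x = ts[:, 0]
        for j in range(3):
            r = np.corrcoef(x, ts[:, j])[0, 1]
            expected = np.arctanh(np.clip(r, -0.999999, 0.999999))
            assert out.image.values[tuple(vox[j])] == pytest.approx(expected, abs=1e-9)

    def test_designed_correlation_recovered_in_z(self):
        cmap, conn = _two_network_connectome(
            n_subjects=20, n_timepoints=100, noise=noise_for_target_r(0.6), seed=1
        )
        seed_xyz = conn.template.voxel_to_mm(conn.voxel_indices[10])
        seed = make_seed_image(seed_xyz, 0.0, conn.template)
        out = functional_map(seed, conn)
        labels = cmap.values
        others = (labels == 1)
        others[tuple(conn.voxel_indices[10])] = False
        mean_z = np.nanmean(out.image.values[others])
        # seed voxel correlates with network mates at r = within-network r
        assert abs(mean_z - np.arctanh(0.6)) < 0.05

    def test_rescaling_subject_signals_invariant(self):
        _, conn = _two_network_connectome(noise=0.5, seed=3)
        conn2 = FunctionalConnectome(
            template=conn.template,
            voxel_indices=conn.voxel_indices,
            data=[conn.data[0] * 7.3, conn.data[1]],
        )
        seed_xyz = conn.template.voxel_to_mm(conn.voxel_indices[4])
        seed = make_seed_image(seed_xyz, 0.0, conn.template)
        a = functional_map(seed, conn).image.values
        b = functional_map(seed, conn2).image.values
        assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)], atol=1e-12)

    def test_seed_outside_connectome_rejected(self):
        _, conn = _two_network_connectome()
        seed = VolumeImage(np.zeros(conn.template.shape), conn.template.affine)
        with pytest.raises(ValueError, match="seed overlaps no"):
            functional_map(seed, conn)

    def test_single_subject_rejected(self):
        grid = mni_grid(shape=(3, 1, 1), voxel_mm=2.0, origin_mm=(2, 0, 0))
        conn = FunctionalConnectome(
            template=grid,
            voxel_indices=np.array([[0, 0, 0]]),
            data=[np.ones((4, 1))],
        )
        seed = VolumeImage(np.ones(grid.shape), grid.affine)
        with pytest.raises(ValueError, match="2 subjects"):
            functional_map(seed, conn)


class TestGmMask:
    def _map(self, coarse_grid):
        vals = np.random.default_rng(0).normal(size=coarse_grid.shape)
        return ConnectivityMap(
            image=VolumeImage(vals, coarse_grid.affine), modality="functional"
        )

    def test_full_mask_identity(self, coarse_grid):
        m = self._map(coarse_grid)
        mask = VolumeImage(np.ones(coarse_grid.shape), coarse_grid.affine)
        out = apply_gm_mask(m, mask)
        assert np.array_equal(out.image.values, m.image.values)

    def test_half_mask_retains_exactly_half(self, coarse_grid):
        m = self._map(coarse_grid)
        mask_vals = np.zeros(coarse_grid.shape)
        mask_vals[: coarse_grid.shape[0] // 2] = 1.0
        out = apply_gm_mask(m, VolumeImage(mask_vals, coarse_grid.affine))
        assert np.isfinite(out.image.values).sum() == int(mask_vals.sum())

    def test_empty_mask_rejected(self, coarse_grid):
        m = self._map(coarse_grid)
        with pytest.raises(ValueError, match="empty"):
            apply_gm_mask(m, VolumeImage(np.zeros(coarse_grid.shape), coarse_grid.affine))

    def test_smooth_then_mask_differs_from_mask_then_smooth(self, coarse_grid):
        m = self._map(coarse_grid)
        mask_vals = np.zeros(coarse_grid.shape)
        mask_vals[:12] = 1.0
        mask = VolumeImage(mask_vals, coarse_grid.affine)
        a = apply_gm_mask(
            ConnectivityMap(smooth_volume(m.image, 8.0), "functional"), mask
        ).image.values
        b = smooth_volume(apply_gm_mask(m, mask).image, 8.0).values
        assert not np.allclose(np.nan_to_num(a), np.nan_to_num(b))


class TestStructuralMap:
    def test_single_streamline_through_seed(self, coarse_grid):
        line = np.column_stack([np.linspace(-80, 80, 100), np.zeros(100), np.zeros(100)])
        out = structural_map((0, 0, 0), 5.0, StreamlineSet([line]), coarse_grid)
        vals = out.image.values
        assert set(np.unique(vals)) == {0.0, 1.0}
        inv = np.linalg.inv(coarse_grid.affine)
        vox = np.unique(np.round(line @ inv[:3, :3].T + inv[:3, 3]).astype(int), axis=0)
        assert int(vals.sum()) == len(vox)

    def test_bundle_selection_count(self, coarse_grid):
        through = np.column_stack([np.linspace(-80, 80, 60), np.zeros(60), np.zeros(60)])
        away = through + np.array([0.0, 60.0, 0.0])
        tr = gen_tractogram([through, away], n_per_bundle=50, jitter_mm=0.5, seed=2)
        out = structural_map((0, 0, 0), 8.0, tr, coarse_grid)
        assert out.image.values.max() == pytest.approx(50, abs=2)

    def test_segment_vs_point_convention(self, coarse_grid):
        # two points straddle the sphere; segment crosses it between them
        line = np.array([[-20.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        pt = structural_map((0, 0, 0), 5.0, StreamlineSet([line]), coarse_grid)
        seg = structural_map(
            (0, 0, 0), 5.0, StreamlineSet([line]), coarse_grid, segment_test=True
        )
        assert pt.image.values.sum() == 0
        assert seg.image.values.sum() > 0

    def test_empty_selection_zero_map(self, coarse_grid):
        line = np.array([[60.0, 60.0, 60.0], [70.0, 70.0, 70.0]])
        out = structural_map((0, 0, 0), 5.0, StreamlineSet([line]), coarse_grid)
        assert out.image.values.sum() == 0


class TestGroupAggregate:
    def test_mean_of_identical_functional_maps_is_identity(self, coarse_grid):
        vals = np.random.default_rng(1).normal(size=coarse_grid.shape)
        m = ConnectivityMap(VolumeImage(vals, coarse_grid.affine), "functional")
        out = group_aggregate([m, m], "functional")
        assert np.allclose(out.values, vals)

    def test_structural_sum(self, coarse_grid):
        a = ConnectivityMap(VolumeImage(np.full(coarse_grid.shape, 2.0), coarse_grid.affine), "structural")
        b = ConnectivityMap(VolumeImage(np.full(coarse_grid.shape, 3.0), coarse_grid.affine), "structural")
        assert np.allclose(group_aggregate([a, b], "structural").values, 5.0)

    def test_structural_conservation_and_permutation_invariance(self, coarse_grid):
        rng = np.random.default_rng(2)
        maps = [
            ConnectivityMap(
                VolumeImage(rng.poisson(2.0, coarse_grid.shape).astype(float), coarse_grid.affine),
                "structural",
            )
            for _ in range(5)
        ]
        total = group_aggregate(maps, "structural")
        assert total.values.sum() == pytest.approx(sum(m.image.values.sum() for m in maps))
        shuffled = group_aggregate(maps[::-1], "structural")
        assert np.array_equal(total.values, shuffled.values)

    def test_mixed_modalities_rejected(self, coarse_grid):
        f = ConnectivityMap(VolumeImage(np.zeros(coarse_grid.shape), coarse_grid.affine), "functional")
        s = ConnectivityMap(VolumeImage(np.zeros(coarse_grid.shape), coarse_grid.affine), "structural")
        with pytest.raises(ValueError, match="[Mm]ixed|modalit"):
            group_aggregate([f, s], "functional")

    def test_missing_aware_functional_mean(self, coarse_grid):
        va = np.full(coarse_grid.shape, np.nan)
        vb = np.full(coarse_grid.shape, 4.0)
        va[0, 0, 0] = 2.0
        a = ConnectivityMap(VolumeImage(va, coarse_grid.affine), "functional")
        b = ConnectivityMap(VolumeImage(vb, coarse_grid.affine), "functional")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = group_aggregate([a, b], "functional")
        assert out.values[0, 0, 0] == pytest.approx(3.0)
        assert out.values[1, 0, 0] == pytest.approx(4.0)
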