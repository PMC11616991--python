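"""Reslicing, PET aggregation, compound parcellation and spatial correlation."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscillonet import (
    Parcellation,
    VolumeImage,
    aggregate_pet,
    build_compound_parcellation,
    compartment_report,
    gen_pet,
    mni_grid,
    parcel_profile,
    reslice,
    spatial_spearman,
)


def _img(vals, voxel_mm=2.0):
    vals = np.asarray(vals, dtype=float)
    return VolumeImage(vals, np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0]))


class TestReslice:
    def test_identity_on_own_grid(self):
        rng = np.random.default_rng(0)
        img = _img(rng.normal(size=(8, 8, 8)))
        out = reslice(img, img)
        assert np.allclose(out.values, img.values, atol=1e-9)

    def test_constant_stays_constant(self):
        img = _img(np.full((8, 8, 8), 2.5))
        target = mni_grid(shape=(6, 6, 6), voxel_mm=2.0, origin_mm=(10, 2, 2))
        # use an overlapping axis-aligned target
        target = VolumeImage(np.zeros((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]) + 0.0)
        target.affine[:3, 3] = [2.0, 2.0, 2.0]
        out = reslice(img, target, interpolation="linear")
        assert np.allclose(out.values, 2.5, atol=1e-9)

    def test_downsampled_linear_ramp(self):
        # ramp along x: value = x-coordinate in mm
        shape = (16, 4, 4)
        vals = np.fromfunction(lambda i, j, k: 2.0 * i, shape)
        img = _img(vals)
        target = VolumeImage(np.zeros((8, 2, 2)), np.diag([4.0, 4.0, 4.0, 1.0]))
        out = reslice(img, target, interpolation="linear")
        # interior voxel centers: value equals x = 4*i exactly under linear interp
        for i in range(1, 7):
            assert out.values[i, 0, 0] == pytest.approx(4.0 * i, abs=1e-6)

    def test_nearest_preserves_labels(self):
        labels = np.zeros((8, 8, 8))
        labels[:4] = 3
        labels[4:] = 7
        img = _img(labels)
        target = VolumeImage(np.zeros((4, 4, 4)), np.diag([4.0, 4.0, 4.0, 1.0]))
        out = reslice(img, target, interpolation="nearest")
        assert set(np.unique(out.values)) <= {3.0, 7.0}

    def test_disjoint_grids_rejected(self):
        img = _img(np.zeros((4, 4, 4)))
        far = VolumeImage(np.zeros((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
        far.affine[:3, 3] = [500.0, 500.0, 500.0]
        with pytest.raises(ValueError, match="overlap"):
            reslice(img, far)


class TestAggregatePet:
    def test_single_map_is_its_zscore(self):
        rng = np.random.default_rng(1)
        img = _img(rng.normal(2.0, 3.0, size=(6, 6, 6)))
        out = aggregate_pet([img])
        z = (img.values - img.values.mean()) / img.values.std()
        assert np.allclose(out.values, z, atol=1e-12)

    def test_affine_rescaled_maps_agree(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 6, 6))
        a = _img(base)
        b = _img(4.2 * base + 7.0)
        out = aggregate_pet([a, b])
        z = (base - base.mean()) / base.std()
        assert np.allclose(out.values, z, atol=1e-10)

    def test_shared_component_recovered_better_than_any_single_map(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(size=(6, 6, 6))
        better = 0
        for _ in range(20):
            maps = [_img(shared + rng.normal(size=shared.shape)) for _ in range(4)]
            agg = aggregate_pet(maps)
            r_agg = np.corrcoef(agg.values.ravel(), shared.ravel())[0, 1]
            r_each = max(
                np.corrcoef(m.values.ravel(), shared.ravel())[0, 1] for m in maps
            )
            better += r_agg > r_each
        assert better >= 18  # aggregate beats every single map almost always

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            aggregate_pet([_img(np.ones((4, 4, 4)))])


def _atlas(shape, boxes, voxel_mm=2.0):
    """boxes: list of (slice-tuple, label)."""
    vals = np.zeros(shape)
    names = {}
    for sl, lab in boxes:
        vals[sl] = lab
        names[lab] = f"r{lab}"
    return _img(vals, voxel_mm), names


class TestCompoundParcellation:
    def test_non_overlapping_atlases_additive(self):
        shape = (10, 10, 10)
        a_img, a_names = _atlas(shape, [((slice(0, 2), slice(0, 2), slice(0, 2)), 1),
                                        ((slice(3, 5), slice(0, 2), slice(0, 2)), 2),
                                        ((slice(6, 8), slice(0, 2), slice(0, 2)), 3)])
        b_img, b_names = _atlas(shape, [((slice(0, 2), slice(5, 7), slice(0, 2)), 1),
                                        ((slice(3, 5), slice(5, 7), slice(0, 2)), 2),
                                        ((slice(6, 8), slice(5, 7), slice(0, 2)), 3),
                                        ((slice(0, 2), slice(8, 10), slice(0, 2)), 4)])
        parc = build_compound_parcellation(
            [(a_img, a_names, "basal_ganglia", "bg"), (b_img, b_names, "cortex", "ctx")]
        )
        assert parc.n_regions == 7

    def test_fully_shadowed_region_dropped(self):
        shape = (6, 6, 6)
        a_img, a_names = _atlas(shape, [((slice(0, 4), slice(0, 4), slice(0, 4)), 1)])
        b_img, b_names = _atlas(shape, [((slice(1, 3), slice(1, 3), slice(1, 3)), 1)])
        parc = build_compound_parcellation(
            [(a_img, a_names, "cortex", "A"), (b_img, b_names, "cortex", "B")]
        )
        assert parc.n_regions == 1

    def test_voxel_assignment_is_partition_matching_brute_force(self):
        rng = np.random.default_rng(4)
        shape = (8, 8, 8)
        atlases = []
        raw = []
        for aid, comp in (("x", "basal_ganglia"), ("y", "cerebellum"), ("z", "cortex")):
            vals = rng.integers(0, 4, size=shape).astype(float)
            names = {int(l): f"{aid}{int(l)}" for l in np.unique(vals) if l > 0}
            atlases.append((_img(vals), names, comp, aid))
            raw.append(vals)
        parc = build_compound_parcellation(atlases)
        # brute force: first atlas with nonzero label claims each voxel
        claimed_names = np.full(shape, "", dtype=object)
        for vals, (_, names, _, aid) in zip(raw, atlases):
            free = claimed_names == ""
            has = vals > 0
            for lab, name in names.items():
                claimed_names[free & (vals == lab)] = name
        expect_regions = {n for n in claimed_names.ravel() if n}
        got_regions = {v[0] for v in parc.lookup.values()}
        assert got_regions == expect_regions
        # partition: every claimed voxel has exactly one output label
        out_labels = np.round(parc.label_image.values).astype(int)
        assert np.all((out_labels > 0) == (claimed_names != ""))


class TestParcelProfile:
    def _parc(self):
        shape = (6, 6, 6)
        vals = np.zeros(shape)
        vals[:2] = 1
        vals[2:4] = 2
        vals[4:] = 3
        lookup = {i: (f"p{i}", "cortex", "toy") for i in (1, 2, 3)}
        return Parcellation(_img(vals), lookup)

    def test_constant_image(self):
        parc = self._parc()
        prof = parcel_profile(_img(np.full((6, 6, 6), 4.2)), parc)
        assert np.allclose(prof.values, 4.2)

    def test_label_image_returns_labels(self):
        parc = self._parc()
        prof = parcel_profile(parc.label_image, parc)
        assert np.allclose(prof.values, [1.0, 2.0, 3.0])

    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(5)
        parc = self._parc()
        img = _img(rng.normal(size=(6, 6, 6)))
        prof = parcel_profile(img, parc)
        labels = np.round(parc.label_image.values).astype(int)
        for lab, v in zip(prof.labels, prof.values):
            assert v == pytest.approx(img.values[labels == lab].mean(), abs=1e-12)

    def test_empty_parcel_flagged(self):
        parc = self._parc()
        img_vals = np.random.default_rng(6).normal(size=(6, 6, 6))
        img_vals[np.round(parc.label_image.values) == 2] = np.nan
        prof = parcel_profile(_img(img_vals), parc)
        assert np.isnan(prof.values[1])
        assert prof.n_voxels[1] == 0


class TestSpatialSpearman:
    def test_identical_profiles(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        rho, p = spatial_spearman(x, x, n_perm=999, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_minimum_p_floor_at_default_permutations(self):
        rng = np.random.default_rng(8)
        x = np.arange(100.0)
        y = x + rng.normal(0, 1e-6, 100)
        rho, p = spatial_spearman(x, y, n_perm=9999, seed=1)
        assert p == pytest.approx(1.0e-4)

    def test_exhaustive_enumeration_for_six_parcels(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        rho, p = spatial_spearman(a, b, n_perm=50, seed=2)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        obs = stats.pearsonr(ra, rb).statistic
        count = sum(
            1
            for perm in permutations(range(6))
            if abs(stats.pearsonr(ra, rb[list(perm)]).statistic) >= abs(obs) - 1e-12
        )
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(count / 720.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        rho1, _ = spatial_spearman(a, b, n_perm=99, seed=3)
        rho2, _ = spatial_spearman(np.exp(a), b**3 + 5 * b, n_perm=99, seed=3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_uniform_p_under_independence(self):
        rng = np.random.default_rng(11)
        rej = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            _, p = spatial_spearman(a, b, n_perm=199, seed=int(rng.integers(2**31)))
            rej += p <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_spearman(np.ones(10), np.arange(10.0))

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            spatial_spearman(np.arange(4.0), np.arange(4.0))


class TestCompartmentReport:
    def _parcellation(self):
        shape = (12, 12, 4)
        vals = np.zeros(shape)
        lookup = {}
        lab = 1
        for i in range(12):
            for j in range(12):
                vals[i, j, :] = lab
                comp = "cortex" if lab <= 80 else ("basal_ganglia" if lab <= 120 else "cerebellum")
                lookup[lab] = (f"p{lab}", comp, "toy")
                lab += 1
        return Parcellation(_img(vals), lookup)

    def test_planted_cortex_signal(self):
        parc = self._parcellation()
        rng = np.random.default_rng(12)
        conn_vals = np.zeros((12, 12, 4))
        labels = np.round(parc.label_image.values).astype(int)
        base = rng.normal(size=parc.n_regions)
        for lab in parc.labels:
            conn_vals[labels == lab] = base[lab - 1]
        conn = _img(conn_vals)
        # PET follows the connectivity profile in cortex, noise elsewhere
        pet_profile = base.copy()
        pet_profile[80:] = rng.normal(size=parc.n_regions - 80)
        pet_vals = np.zeros((12, 12, 4))
        for lab in parc.labels:
            pet_vals[labels == lab] = pet_profile[lab - 1]
        report = compartment_report(
            {"beta": conn}, {"dopamine": _img(pet_vals)}, parc, n_perm=999, seed=0
        )
        ctx = report[report["compartment"] == "cortex"].iloc[0]
        cb = report[report["compartment"] == "cerebellum"].iloc[0]
        assert ctx["rho"] > 0.9 and ctx["p"] <= 0.01
        assert abs(cb["rho"]) < 0.5 and cb["p"] > 0.05

    def test_deterministic(self):
        parc = self._parcellation()
        rng = np.random.default_rng(13)
        img1 = _img(rng.normal(size=(12, 12, 4)))
        img2 = _img(rng.normal(size=(12, 12, 4)))
        r1 = compartment_report({"m": img1}, {"t": img2}, parc, n_perm=199, seed=5)
        r2 = compartment_report({"m": img1}, {"t": img2}, parc, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_bh_column_present_and_valid(self):
        parc = self._parcellation()
        rng = np.random.default_rng(14)
        report = compartment_report(
            {"m": _img(rng.normal(size=(12, 12, 4)))},
            {"t": _img(rng.normal(size=(12, 12, 4)))},
            parc,
            n_perm=99,
            seed=6,
        )
        assert len(report) == 3
        assert ((report["p_bh"] >= report["p"] - 1e-12)).all()
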