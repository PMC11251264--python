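"""Tests for the organoid instance-segmentation pipeline."""

import numpy as np
import pytest

from orgscreen import synthgen
from orgscreen.segment import (
    SegmentationConfig,
    clipping_mask,
    detect_seeds,
    distance_transform,
    downsample_inplane,
    downsampled_spacing,
    extract_records,
    fullres_mask,
    lowres_mask,
    mean_image,
    percentile_otsu,
    postprocess,
    segment_stack,
    watershed_segment,
)
from orgscreen.stacks import LabelVolume, MultiChannelStack
from orgscreen.synthgen import GroundTruthOrganoid, SceneSpec

CFG = SegmentationConfig()


class TestMeanImage:
    def test_constant_channels_average(self):
        vals = np.stack([np.full((2, 3, 3), 100.0), np.full((2, 3, 3), 300.0)])
        assert np.all(mean_image(MultiChannelStack(vals)) == 200.0)

    def test_single_channel_identity(self, rng):
        vals = rng.uniform(0, 1000, size=(1, 2, 4, 4))
        np.testing.assert_array_equal(mean_image(MultiChannelStack(vals)), vals[0])

    def test_matches_elementwise_oracle(self, rng):
        vals = rng.uniform(0, 65535, size=(7, 3, 5, 5))
        got = mean_image(MultiChannelStack(vals))
        oracle = np.zeros((3, 5, 5))
        for c in range(7):
            oracle += vals[c]
        np.testing.assert_allclose(got, oracle / 7.0)


class TestClippingMask:
    def test_strict_inequality_at_65000(self):
        vol = np.array([[[0.0, 65000.0, 65001.0]]])
        np.testing.assert_array_equal(clipping_mask(vol), [[[False, False, True]]])

    def test_saturation_fraction_recovered(self):
        spec = SceneSpec(shape_voxels=(32, 64, 64), saturation_fraction=0.01, seed=11)
        stack, _ = synthgen.generate_stack(spec)
        frac = clipping_mask(mean_image(stack)).mean()
        # binomial CI around 0.01 for 131072 voxels
        assert abs(frac - 0.01) < 0.003


class TestPercentileOtsu:
    def test_bimodal_threshold_between_modes(self, rng):
        vals = np.concatenate([rng.normal(100, 5, 5000), rng.normal(1000, 5, 5000)])
        assert 105 < percentile_otsu(vals) < 995

    def test_outliers_do_not_move_threshold(self, rng):
        vals = np.concatenate([rng.normal(100, 5, 5000), rng.normal(1000, 5, 5000)])
        t0 = percentile_otsu(vals)
        with_outliers = np.concatenate([vals, np.full(50, 65535.0)])
        t1 = percentile_otsu(with_outliers)
        bin_width = (vals.max() - vals.min()) / 256
        assert abs(t1 - t0) <= bin_width

    def test_matches_bruteforce_on_six_values(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])

        def between_class_variance(t):
            lo, hi = vals[vals <= t], vals[vals > t]
            if len(lo) == 0 or len(hi) == 0:
                return -np.inf
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        candidates = (vals[:-1] + vals[1:]) / 2
        best = candidates[np.argmax([between_class_variance(t) for t in candidates])]
        got = percentile_otsu(vals, hi=100.0)
        # same induced partition as the exhaustive search, up to the
        # half-bin convention of histogram-based Otsu
        bin_width = (vals.max() - vals.min()) / 256
        np.testing.assert_array_equal(vals <= got + bin_width, vals <= best)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            percentile_otsu(np.full(100, 7.0))


class TestMasks:
    def test_fullres_mask_covers_bright_sphere(self):
        spec = SceneSpec(
            shape_voxels=(48, 128, 128),
            organoids=[GroundTruthOrganoid(1, (20.0, 26.0, 26.0), 12.0, [10000.0])],
            gaussian_sd=200.0,
            seed=1,
        )
        stack, gt = synthgen.generate_stack(spec)
        mask = fullres_mask(mean_image(stack), CFG)
        sphere = gt.labels == 1
        assert (mask & sphere).sum() / sphere.sum() > 0.95

    def test_sigma_zero_override_equals_raw_threshold(self, rng):
        vol = rng.uniform(0, 1000, size=(4, 30, 30))
        cfg0 = CFG.replace(full_smooth_sigma_vox=0.0)
        raw = vol > percentile_otsu(vol, CFG.otsu_percentile_hi)
        np.testing.assert_array_equal(fullres_mask(vol, cfg0), raw)

    def test_lowres_small_patch_filter_is_strict(self):
        # 99-voxel spurious patch removed; >=100-voxel core kept
        vol = np.full((20, 40, 40), 10.0)
        bright = np.zeros_like(vol, dtype=bool)
        bright[2:4, 2:12, 2:7].flat[:99] = True  # 99 bright voxels
        bright[8:13, 20:30, 20:30] = True  # 500-voxel core
        vol[bright] = 10000.0
        cfg = CFG.replace(low_smooth_sigma_vox=0.0, mask_dilation_vox=0)
        mask = lowres_mask(vol, cfg)
        assert not mask[2:4, 2:12, 2:7].any()
        assert mask[8:13, 20:30, 20:30].all()

    def test_hollow_shell_interior_filled(self):
        org = GroundTruthOrganoid(
            1, (20.0, 30.0, 30.0), 12.0, [12000.0], shell_thickness_um=3.0
        )
        spec = SceneSpec(shape_voxels=(48, 160, 160), organoids=[org])
        stack, _ = synthgen.generate_stack(spec)
        mean_lo = downsample_inplane(mean_image(stack), CFG.downsample_factor_inplane)
        mask = lowres_mask(mean_lo, CFG)
        center = (int(20.0 / 0.9), int(30.0 / 2.075), int(30.0 / 2.075))
        assert mask[center]

    def test_dilation_grows_flat_face_by_radius(self):
        vol = np.full((20, 40, 40), 0.0)
        vol[5:15, 10:30, 10:30] = 1000.0
        cfg = CFG.replace(low_smooth_sigma_vox=0.0)
        mask = lowres_mask(vol, cfg)
        # flat face at y=10 grows by exactly mask_dilation_vox
        assert mask[10, 10 - CFG.mask_dilation_vox, 20]
        assert not mask[10, 10 - CFG.mask_dilation_vox - 1, 20]


class TestDownsample:
    def test_constant_volume(self):
        out = downsample_inplane(np.full((3, 10, 15), 7.0), 5)
        assert out.shape == (3, 2, 3)
        assert np.all(out == 7.0)

    def test_block_mean_matches_hand_computation(self, rng):
        vol = rng.uniform(0, 100, size=(1, 5, 5))
        out = downsample_inplane(vol, 5)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(vol.mean())

    def test_partial_edge_blocks_use_partial_windows(self):
        vol = np.arange(7, dtype=float).reshape(1, 1, 7)
        vol = np.repeat(vol, 5, axis=1)
        out = downsample_inplane(vol, 5)
        assert out[0, 0, 0] == pytest.approx(np.mean([0, 1, 2, 3, 4]))
        assert out[0, 0, 1] == pytest.approx(np.mean([5, 6]))

    def test_spacing_arithmetic(self):
        assert downsampled_spacing((0.9, 0.415, 0.415), 5) == pytest.approx((0.9, 2.075, 2.075))


class TestDistanceTransform:
    def test_sphere_max_edt_approximates_radius(self):
        spec = SceneSpec(
            shape_voxels=(48, 128, 128),
            organoids=[GroundTruthOrganoid(1, (20.0, 26.0, 26.0), 10.0, [1000.0])],
        )
        _, gt = synthgen.generate_stack(spec)
        edt = distance_transform(gt.labels > 0, gt.voxel_size_um)
        assert abs(edt.max() - 10.0) < 1.0

    def test_single_voxel_matches_bruteforce(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        spacing = (0.9, 0.415, 0.415)
        edt = distance_transform(mask, spacing)
        # nearest background voxel centre is one x-step away
        assert edt[1, 1, 1] == pytest.approx(0.415)

    def test_anisotropy_scales_with_spacing(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        iso = distance_transform(mask, (1.0, 1.0, 1.0))
        aniso = distance_transform(mask, (2.0, 1.0, 1.0))
        assert aniso[4, 4, 4] == pytest.approx(2 * iso[4, 4, 4]) or aniso.max() >= iso.max()
        # a voxel adjacent to background along z doubles its distance
        assert aniso[2, 4, 4] == pytest.approx(2.0)
        assert iso[2, 4, 4] == pytest.approx(1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="all-false"):
            distance_transform(np.zeros((2, 2, 2), dtype=bool), (1, 1, 1))


def _lowres_scene(organoids, shape=(48, 160, 160)):
    spec = SceneSpec(shape_voxels=shape, organoids=organoids)
    stack, gt = synthgen.generate_stack(spec)
    mean_lo = downsample_inplane(mean_image(stack), CFG.downsample_factor_inplane)
    sp = downsampled_spacing(stack.voxel_size_um, CFG.downsample_factor_inplane)
    mask = lowres_mask(mean_lo, CFG)
    edt = distance_transform(mask, sp)
    return stack, gt, mask, edt, sp


class TestSeedsAndWatershed:
    def test_single_sphere_single_seed_near_center(self):
        org = GroundTruthOrganoid(1, (24.0, 33.0, 33.0), 11.0, [10000.0])
        _, _, mask, edt, sp = _lowres_scene([org])
        seeds = detect_seeds(edt, CFG, sp)
        assert len(seeds) == 1
        center_vox = np.array([24.0, 33.0, 33.0]) / np.array(sp)
        assert np.all(np.abs(np.array(seeds[0][0]) - center_vox) <= 2.0)

    def test_two_separated_spheres_two_seeds(self):
        orgs = [
            GroundTruthOrganoid(1, (24.0, 18.0, 18.0), 10.0, [10000.0]),
            GroundTruthOrganoid(2, (24.0, 48.0, 48.0), 12.0, [10000.0]),
        ]
        _, _, mask, edt, sp = _lowres_scene(orgs)
        assert len(detect_seeds(edt, CFG, sp)) == 2

    def test_tiny_sphere_is_documented_miss(self):
        # far below min_sigma: no seed (known miss mode of the size group)
        org = GroundTruthOrganoid(1, (24.0, 33.0, 33.0), 3.0, [10000.0])
        spec = SceneSpec(shape_voxels=(48, 160, 160), organoids=[org])
        stack, _ = synthgen.generate_stack(spec)
        mean_lo = downsample_inplane(mean_image(stack), CFG.downsample_factor_inplane)
        sp = downsampled_spacing(stack.voxel_size_um, CFG.downsample_factor_inplane)
        sm_mask = mean_lo > 5000.0  # tiny blob: bypass patch filter to isolate the detector
        edt = distance_transform(sm_mask, sp)
        assert detect_seeds(edt, CFG, sp) == []

    def test_widening_sigma_range_never_drops_seeds(self):
        orgs = [
            GroundTruthOrganoid(1, (24.0, 18.0, 18.0), 10.0, [10000.0]),
            GroundTruthOrganoid(2, (24.0, 48.0, 48.0), 12.0, [10000.0]),
        ]
        _, _, _, edt, sp = _lowres_scene(orgs)
        narrow = detect_seeds(edt, CFG, sp)
        wide = detect_seeds(edt, CFG.replace(sigma_range_um=(5.0, 17.0)), sp)
        assert len(wide) >= len(narrow)

    def test_single_seed_fills_component(self):
        org = GroundTruthOrganoid(1, (24.0, 33.0, 33.0), 11.0, [10000.0])
        _, _, mask, edt, sp = _lowres_scene([org])
        seeds = detect_seeds(edt, CFG, sp)
        labels = watershed_segment(edt, seeds, mask, CFG)
        assert set(np.unique(labels)) == {0, 1}
        np.testing.assert_array_equal(labels > 0, mask)

    def test_touching_spheres_split_near_midplane(self):
        orgs = [
            GroundTruthOrganoid(1, (24.0, 30.0, 22.0), 10.0, [10000.0]),
            GroundTruthOrganoid(2, (24.0, 30.0, 43.0), 10.0, [10000.0]),
        ]
        _, _, mask, edt, sp = _lowres_scene(orgs)
        seeds = detect_seeds(edt, CFG, sp)
        assert len(seeds) == 2
        labels = watershed_segment(edt, seeds, mask, CFG)
        assert set(np.unique(labels)) == {0, 1, 2}
        # geometric midplane between centres, in low-res x voxels
        mid_x = (22.0 + 43.0) / 2.0 / sp[2]
        zc, yc = int(24.0 / sp[0]), int(30.0 / sp[1])
        row = labels[zc, yc, :]
        boundary = np.flatnonzero(np.diff(row[row > 0]))  # transition 1 -> 2
        xs = np.flatnonzero(row > 0)
        transition = xs[boundary[0] + 1] if boundary.size else -99
        assert abs(transition - mid_x) <= 2.0

    def test_labels_disjoint_and_within_mask(self):
        orgs = [
            GroundTruthOrganoid(1, (24.0, 18.0, 18.0), 10.0, [10000.0]),
            GroundTruthOrganoid(2, (24.0, 48.0, 48.0), 12.0, [10000.0]),
        ]
        _, _, mask, edt, sp = _lowres_scene(orgs)
        labels = watershed_segment(edt, detect_seeds(edt, CFG, sp), mask, CFG)
        assert not labels[~mask].any()

    def test_seed_outside_mask_dropped_with_warning(self):
        org = GroundTruthOrganoid(1, (24.0, 33.0, 33.0), 11.0, [10000.0])
        _, _, mask, edt, sp = _lowres_scene([org])
        seeds = detect_seeds(edt, CFG, sp) + [((0, 0, 0), (1.0, 1.0, 1.0))]
        with pytest.warns(UserWarning, match="outside"):
            labels = watershed_segment(edt, seeds, mask, CFG)
        assert labels.max() == 1


class TestPostprocess:
    def test_volume_filter_is_strict_at_5000(self):
        sp_lo = (0.9, 2.075, 2.075)
        voxvol = float(np.prod(sp_lo))  # 3.875 um^3
        n_small = int(np.floor(5000.0 / voxvol))  # 1290 vox = 4998.8 um^3
        n_big = n_small + 1  # 1291 vox = 5002.6 um^3
        labels = np.zeros((40, 60, 60), dtype=np.int32)
        flat = labels[5:15].reshape(-1)
        flat[:n_small] = 1
        labels[5:15] = flat.reshape(labels[5:15].shape)
        flat = labels[25:35].reshape(-1)
        flat[:n_big] = 2
        labels[25:35] = flat.reshape(labels[25:35].shape)
        full_mask = np.ones((40, 300, 300), dtype=bool)
        clip = np.zeros_like(full_mask)
        cfg = CFG.replace(upsample_expand_um=0.0)
        out = postprocess(labels, full_mask, clip, cfg, sp_lo, (0.9, 0.415, 0.415))
        kept = np.unique(out[out > 0])
        assert list(kept) == [1]  # relabelled survivor of original id 2
        # survivor is the big instance: support matches upsampled region
        assert out[25:35].any() and not out[5:15].any()

    def test_saturated_instance_removed(self):
        labels = np.zeros((10, 20, 20), dtype=np.int32)
        labels[2:8, 2:10, 2:10] = 1
        labels[2:8, 12:19, 12:19] = 2
        full_mask = np.ones((10, 100, 100), dtype=bool)
        clip = np.zeros_like(full_mask)
        clip[5, 30, 30] = True  # falls inside upsampled instance 1
        cfg = CFG.replace(upsample_expand_um=0.0, min_volume_um3=0.0)
        out = postprocess(labels, full_mask, clip, cfg, (0.9, 2.075, 2.075), (0.9, 0.415, 0.415))
        assert 0 < out.max() == len(np.unique(out)) - 1 == 1
        assert not out[clip].any()

    def test_no_label_outside_fullres_mask(self):
        labels = np.zeros((6, 10, 10), dtype=np.int32)
        labels[1:5, 2:8, 2:8] = 1
        full_mask = np.zeros((6, 50, 50), dtype=bool)
        full_mask[2:4, 15:35, 15:35] = True
        clip = np.zeros_like(full_mask)
        cfg = CFG.replace(min_volume_um3=0.0)
        out = postprocess(labels, full_mask, clip, cfg, (0.9, 2.075, 2.075), (0.9, 0.415, 0.415))
        assert not out[~full_mask].any()

    def test_raising_min_volume_never_increases_count(self, small_scene):
        _, stack, _ = small_scene
        counts = []
        for mv in (0.0, 5000.0, 20000.0):
            cfg = CFG.replace(min_volume_um3=mv)
            counts.append(segment_stack(stack, cfg).ids.size)
        assert counts[0] >= counts[1] >= counts[2]


class TestExtractRecords:
    def test_noiseless_means_exact_on_interior(self):
        org = GroundTruthOrganoid(1, (20.0, 26.0, 26.0), 9.0, [1200.0, 300.0], line_id="L")
        spec = SceneSpec(shape_voxels=(48, 128, 128), organoids=[org])
        stack, gt = synthgen.generate_stack(spec)
        rec = extract_records(gt, stack, line_id="L", day_id="d1")
        assert len(rec) == 1
        assert rec.loc[0, "ch0"] == 1200.0
        assert rec.loc[0, "ch1"] == 300.0
        assert not rec.loc[0, "saturated"]
        analytic = 4 / 3 * np.pi * 9.0**3
        assert abs(rec.loc[0, "volume_um3"] - analytic) / analytic < 0.05

    def test_noisy_mean_within_clt_bound(self):
        org = GroundTruthOrganoid(1, (20.0, 26.0, 26.0), 10.0, [10000.0])
        spec = SceneSpec(
            shape_voxels=(48, 128, 128), organoids=[org], gaussian_sd=500.0, seed=3
        )
        stack, gt = synthgen.generate_stack(spec)
        rec = extract_records(gt, stack)
        n = int((gt.labels == 1).sum())
        assert abs(rec.loc[0, "ch0"] - 10000.0) < 4 * 500.0 / np.sqrt(n)

    def test_geometry_mismatch_raises(self, small_scene):
        _, stack, gt = small_scene
        bad = LabelVolume(np.zeros((2, 2, 2), dtype=np.int32))
        with pytest.raises(ValueError, match="geometry"):
            extract_records(bad, stack)


class TestPipeline:
    def test_full_pipeline_deterministic(self, small_scene):
        _, stack, _ = small_scene
        l1 = segment_stack(stack)
        l2 = segment_stack(stack)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_recovers_instances_with_matching_ids(self, small_scene):
        spec, stack, gt = small_scene
        labels = segment_stack(stack)
        assert labels.ids.size == len(spec.organoids)
        for org in spec.organoids:
            gmask = gt.labels == org.id
            hit = labels.labels[gmask]
            ids, cnt = np.unique(hit[hit > 0], return_counts=True)
            assert ids.size >= 1
            best = ids[np.argmax(cnt)]
            pmask = labels.labels == best
            iou = (gmask & pmask).sum() / (gmask | pmask).sum()
            assert iou >= 0.6

    def test_flat_stack_yields_no_instances(self):
        spec = SceneSpec(shape_voxels=(32, 64, 64), background_level=100.0)
        stack, _ = synthgen.generate_stack(spec)
        labels = segment_stack(stack)
        assert labels.ids.size == 0

    def test_fullres_mask_false_positive_fraction_below_1pct(self, small_scene):
        # with real signal present, background stays out of the organoid mask
        _, stack, gt = small_scene
        mask = fullres_mask(mean_image(stack), CFG)
        background = gt.labels == 0
        from scipy import ndimage as ndi

        halo = ndi.binary_dilation(gt.labels > 0, iterations=8)
        strict_background = background & ~halo
        assert mask[strict_background].mean() < 0.01


class TestConfig:
    def test_defaults_match_validated_settings(self):
        cfg = SegmentationConfig()
        assert cfg.clip_threshold == 65000
        assert cfg.full_smooth_sigma_vox == 5
        assert cfg.low_smooth_sigma_vox == 1
        assert cfg.otsu_percentile_hi == 99
        assert cfg.downsample_factor_inplane == 5
        assert cfg.min_patch_vox == 100
        assert cfg.mask_dilation_vox == 3
        assert cfg.seed_dilation_vox == 7
        assert cfg.num_sigma == 10
        assert cfg.log_threshold == 1.0
        assert cfg.log_overlap == 0.5
        assert cfg.min_volume_um3 == 5000
        assert cfg.upsample_expand_um == 4
        assert cfg.sigma_range() == (7.0, 11.0)

    def test_yaml_roundtrip_and_unknown_key(self, tmp_path):
        p = tmp_path / "seg.yaml"
        p.write_text("size_group: large\nmin_volume_um3: 4000\n")
        cfg = SegmentationConfig.from_yaml(p)
        assert cfg.sigma_range() == (9.0, 17.0)
        assert cfg.min_volume_um3 == 4000
        p.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            SegmentationConfig.from_yaml(p)

    def test_invalid_size_group_rejected(self):
        with pytest.raises(ValueError, match="size_group"):
            SegmentationConfig(size_group="gigantic")
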