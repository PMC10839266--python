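"""Stack preprocessing and anisotropic blob detection."""

import numpy as np
import pandas as pd
import pytest

from perisynapse import synthetic
from perisynapse.spot_detection import (
    ImageStack,
    PunctumSet,
    calibrate_threshold,
    detect_spots,
    normalize_layers,
    read_puncta,
    read_stack,
    subtract_background,
    trim_stack,
    write_puncta,
    write_stack,
)


def _noise_stack(shape=(60, 64, 64), sigma=1.0, seed=0, voxel=(0.185, 0.043, 0.043)):
    rng = np.random.default_rng(seed)
    return ImageStack(voxels=rng.normal(10, sigma, shape), voxel_size=voxel, channel="t")


class TestTrim:
    @pytest.mark.parametrize(
        "depth_um,expected_parts",
        [(25.0, 1), (50.0, 2), (90.0, 4)],  # smallest split with every part < 30 um
    )
    def test_split_counts_and_round_trip(self, depth_um, expected_parts):
        nz = int(np.ceil(depth_um / 0.185))  # depth >= the nominal value
        rng = np.random.default_rng(1)
        stack = ImageStack(voxels=rng.uniform(size=(nz, 8, 8)), channel="c")
        parts = trim_stack(stack)
        assert len(parts) == expected_parts
        assert all(p.depth_um < 30.0 for p in parts)
        reassembled = np.concatenate([p.voxels for p in parts], axis=0)
        np.testing.assert_array_equal(reassembled, stack.voxels)
        # z offsets keep coordinates global
        offsets = [p.z_offset for p in parts]
        sizes = np.cumsum([0] + [p.voxels.shape[0] for p in parts[:-1]])
        np.testing.assert_allclose(offsets, sizes * 0.185)


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        stack = ImageStack(voxels=np.full((20, 16, 16), 7.0))
        out = subtract_background(stack)
        np.testing.assert_allclose(out.voxels, 0.0, atol=1e-9)

    def test_output_nonnegative(self):
        out = subtract_background(_noise_stack(sigma=3.0))
        assert out.voxels.min() >= 0.0

    def test_narrow_blob_survives_on_offset(self):
        # blob sigma << background radius: offset removed, peak kept within 10%
        shape = (40, 64, 64)
        voxel = (0.185, 0.043, 0.043)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
        c = (20, 32, 32)
        sig = (0.15 / 0.185, 0.08 / 0.043, 0.08 / 0.043)
        blob = 50.0 * np.exp(
            -0.5 * (((zz - c[0]) / sig[0]) ** 2 + ((yy - c[1]) / sig[1]) ** 2 + ((xx - c[2]) / sig[2]) ** 2)
        )
        stack = ImageStack(voxels=blob + 30.0, voxel_size=voxel)
        out = subtract_background(stack)
        assert out.voxels[c] == pytest.approx(50.0, rel=0.10)
        # far from the blob the offset is gone
        assert out.voxels[5, 5, 5] < 2.0

    def test_subvoxel_radius_rejected(self):
        with pytest.raises(ValueError, match="below one voxel"):
            subtract_background(_noise_stack(), radius=0.1)


class TestNormalizeLayers:
    def test_linear_attenuation_equalized(self):
        rng = np.random.default_rng(2)
        plane = rng.uniform(0.0, 100.0, size=(32, 32))
        gains = np.linspace(1.0, 0.5, 24)
        stack = ImageStack(voxels=plane[None] * gains[:, None, None])
        out = normalize_layers(stack)
        for i in range(1, 24):
            np.testing.assert_allclose(out.voxels[i], out.voxels[0], rtol=1e-6)

    def test_uniform_stack_unchanged(self):
        stack = _noise_stack(seed=3)
        uniform = ImageStack(voxels=np.tile(stack.voxels[:1], (20, 1, 1)))
        out = normalize_layers(uniform)
        np.testing.assert_allclose(out.voxels, uniform.voxels, rtol=1e-6)

    def test_attenuated_spots_equalized_across_depth(self):
        # identical spots at several depths, attenuated; peaks equalize to CV < 5%
        recs = [
            dict(punctum_id=i + 1, x_um=1.5, y_um=1.5, z_um=1.0 + 2.0 * i, r_xy_um=0.15, r_z_um=0.3, intensity=100.0)
            for i in range(5)
        ]
        puncta = PunctumSet.from_records("t", recs)
        stack = synthetic.render_stack(puncta, synthetic.RenderConfig(snr=50.0), seed=0)
        gains = np.linspace(1.0, 0.5, stack.voxels.shape[0])
        attenuated = ImageStack(voxels=stack.voxels * gains[:, None, None], voxel_size=stack.voxel_size)
        out = normalize_layers(attenuated)
        zs = [int(round((1.0 + 2.0 * i - stack.origin_um[2]) / 0.185)) for i in range(5)]
        peaks = [out.voxels[z].max() for z in zs]
        assert np.std(peaks) / np.mean(peaks) < 0.05


class TestCalibration:
    def test_same_statistics_same_detections(self):
        stack = _noise_stack(shape=(120, 48, 48), seed=4)
        thr_top = calibrate_threshold(stack, top_depth=10.0)
        thr_full = calibrate_threshold(stack, top_depth=stack.depth_um)
        np.testing.assert_allclose(thr_top.scale_sigmas, thr_full.scale_sigmas, rtol=0.15)

    def test_bottom_half_does_not_affect_calibration(self):
        stack = _noise_stack(shape=(120, 48, 48), seed=5)
        dimmed = stack.voxels.copy()
        dimmed[60:] *= 0.5
        thr_a = calibrate_threshold(stack)
        thr_b = calibrate_threshold(ImageStack(voxels=dimmed, voxel_size=stack.voxel_size))
        assert thr_a.scale_sigmas == thr_b.scale_sigmas
        assert thr_a.scale_medians == thr_b.scale_medians

    def test_shallow_stack_warns_and_uses_full(self):
        stack = _noise_stack(shape=(20, 32, 32), seed=6)  # 3.7 um deep
        with pytest.warns(UserWarning, match="full stack"):
            calibrate_threshold(stack, top_depth=10.0)


class TestDetection:
    def test_zero_stack_yields_no_puncta(self):
        stack = ImageStack(voxels=np.zeros((30, 32, 32)))
        thr = calibrate_threshold(_noise_stack(shape=(60, 32, 32)))
        assert len(detect_spots(stack, thr)) == 0

    def test_separated_spots_all_found_with_subvoxel_centroids(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(25):
            x, y, z = (i % 5) * 1.2 + 0.6, (i // 5) * 1.2 + 0.6, 1.0 + (i % 3) * 0.8
            recs.append(
                dict(punctum_id=i + 1, x_um=x + rng.uniform(-0.1, 0.1), y_um=y + rng.uniform(-0.1, 0.1),
                     z_um=z, r_xy_um=0.15, r_z_um=0.3, intensity=100.0)
            )
        puncta = PunctumSet.from_records("t", recs)
        stack = synthetic.render_stack(puncta, synthetic.RenderConfig(snr=10.0), seed=8)
        thr = calibrate_threshold(stack)
        det = detect_spots(stack, thr)
        assert len(det) == 25
        origin = np.asarray(stack.origin_um)
        found = det.centers() + origin
        truth = puncta.centers()
        for t in truth:
            err = np.abs(found - t).min(axis=0)
            assert err[0] < 0.043 and err[1] < 0.043  # < 1 voxel in x and y

    def test_close_pair_suppressed_to_one(self):
        recs = [
            dict(punctum_id=1, x_um=1.0, y_um=1.0, z_um=1.0, r_xy_um=0.15, r_z_um=0.3, intensity=100.0),
            dict(punctum_id=2, x_um=1.2, y_um=1.0, z_um=1.0, r_xy_um=0.15, r_z_um=0.3, intensity=100.0),
        ]
        puncta = PunctumSet.from_records("t", recs)
        stack = synthetic.render_stack(puncta, synthetic.RenderConfig(snr=20.0), seed=9)
        det = detect_spots(stack, calibrate_threshold(stack))
        assert len(det) == 1

    def test_count_invariant_to_global_intensity_scaling(self):
        recs = [
            dict(punctum_id=i + 1, x_um=0.8 + 1.4 * i, y_um=1.0, z_um=1.0, r_xy_um=0.15, r_z_um=0.3, intensity=100.0)
            for i in range(4)
        ]
        puncta = PunctumSet.from_records("t", recs)
        stack = synthetic.render_stack(puncta, synthetic.RenderConfig(snr=10.0), seed=10)
        det1 = detect_spots(stack, calibrate_threshold(stack))
        scaled = ImageStack(voxels=stack.voxels * 37.0, voxel_size=stack.voxel_size)
        det2 = detect_spots(scaled, calibrate_threshold(scaled))
        assert len(det1) == len(det2)


class TestIO:
    def test_stack_round_trip_with_voxel_metadata(self, tmp_path):
        stack = _noise_stack(shape=(8, 16, 16), seed=11)
        p = tmp_path / "s.ome.tif"
        write_stack(stack, p)
        back = read_stack(p, voxel_size=stack.voxel_size)
        np.testing.assert_allclose(back.voxels, stack.voxels.astype(np.float32))

    def test_puncta_tsv_round_trip(self, tmp_path):
        recs = [dict(punctum_id=1, x_um=1.25, y_um=2.5, z_um=0.5, r_xy_um=0.15, r_z_um=0.3, intensity=42.0)]
        puncta = PunctumSet.from_records("ch0", recs)
        p = tmp_path / "p.tsv"
        write_puncta(puncta, p)
        back = read_puncta(p)
        assert back.channel == "ch0"
        pd.testing.assert_frame_equal(back.table, puncta.table, check_dtype=False)

    def test_duplicate_punctum_ids_rejected(self):
        recs = [
            dict(punctum_id=1, x_um=0.0, y_um=0.0, z_um=0.0, r_xy_um=0.1, r_z_um=0.2, intensity=1.0),
            dict(punctum_id=1, x_um=1.0, y_um=0.0, z_um=0.0, r_xy_um=0.1, r_z_um=0.2, intensity=1.0),
        ]
        with pytest.raises(ValueError, match="unique"):
            PunctumSet.from_records("c", recs)
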