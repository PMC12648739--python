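import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from germtrack.series_io import (LabelMap, SeedROI, align_series, crop_roi,
                                 load_series, read_label_map, split_masks,
                                 write_label_map)


def _write_frames(tmp_path, frames, names=None):
    import imageio.v3 as iio
    for i, f in enumerate(frames):
        name = names[i] if names else f"frame_{i:03d}.png"
        iio.imwrite(tmp_path / name, f)


class TestLoadSeries:
    def test_filename_order_and_hours(self, tmp_path, rng):
        frames = [rng.integers(0, 255, (20, 30, 3), dtype=np.uint8)
                  for _ in range(6)]
        _write_frames(tmp_path, frames)
        s = load_series(tmp_path, interval_h=1.0)
        assert len(s) == 6
        assert s.frames[-1].hour == 5.0
        assert np.array_equal(s.frames[2].pixels, frames[2])

    def test_fractional_interval(self, tmp_path, rng):
        _write_frames(tmp_path, [rng.integers(0, 255, (8, 8, 3),
                                              dtype=np.uint8)
                                 for _ in range(10)])
        s = load_series(tmp_path, interval_h=0.5)
        assert np.allclose(s.hours, np.arange(10) * 0.5)
        assert s.hours[-1] == 4.5

    def test_single_file_is_an_error(self, tmp_path, rng):
        _write_frames(tmp_path, [rng.integers(0, 255, (8, 8, 3),
                                              dtype=np.uint8)])
        with pytest.raises(ValueError, match="no frames"):
            load_series(tmp_path)

    def test_shape_mismatch_is_an_error(self, tmp_path, rng):
        import imageio.v3 as iio
        iio.imwrite(tmp_path / "a.png",
                    rng.integers(0, 255, (8, 8, 3), dtype=np.uint8))
        iio.imwrite(tmp_path / "b.png",
                    rng.integers(0, 255, (9, 8, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape mismatch"):
            load_series(tmp_path)

    def test_manifest_overrides_order(self, tmp_path, rng):
        frames = [np.full((5, 5, 3), v, np.uint8) for v in (10, 20, 30)]
        _write_frames(tmp_path, frames, names=["c.png", "b.png", "a.png"])
        (tmp_path / "manifest.csv").write_text(
            "filename,hour\nc.png,0\nb.png,2\na.png,4\n")
        s = load_series(tmp_path)
        assert s.frames[0].pixels[0, 0, 0] == 10
        assert s.frames[2].hour == 4.0


class TestLabelMapIO:
    @given(arrays(np.uint8, (17, 23), elements=st.integers(0, 3)))
    def test_png_round_trip_preserves_every_pixel(self, tmp_path, labels):
        path = tmp_path / "m_labels.png"
        write_label_map(path, LabelMap(labels))
        back = read_label_map(path)
        assert np.array_equal(back.labels, labels)

    def test_invalid_label_value_rejected(self):
        with pytest.raises(ValueError, match="4"):
            LabelMap(np.array([[0, 4]], np.uint8))


class TestLoadPhases:
    def test_phase_calls_attached_to_rois(self, tmp_path):
        from germtrack.series_io import load_phases
        path = tmp_path / "phases.csv"
        path.write_text("seed_id,frame,phase,confidence\n"
                        "0,10,IMB,0.9\n0,50,RE,0.85\n")
        rois = [SeedROI(0, (0, 0, 10, 10))]
        load_phases(path, rois)
        assert rois[0].phase_by_frame == {10: "IMB", 50: "RE"}
        assert rois[0].confidence_by_frame[50] == 0.85

    def test_unknown_phase_rejected(self, tmp_path):
        from germtrack.series_io import load_phases
        path = tmp_path / "phases.csv"
        path.write_text("seed_id,frame,phase\n0,10,XYZ\n")
        with pytest.raises(ValueError, match="XYZ"):
            load_phases(path, [SeedROI(0, (0, 0, 10, 10))])


class TestCropRoi:
    def test_simple_box(self):
        arr = np.arange(100 * 100).reshape(100, 100)
        out = crop_roi(arr, SeedROI(0, (0, 0, 10, 10)))
        assert out.shape == (10, 10)

    def test_full_box_is_identity(self, rng):
        arr = rng.integers(0, 9, (40, 60))
        assert np.array_equal(crop_roi(arr, SeedROI(0, (0, 0, 40, 60))), arr)

    def test_out_of_bounds_rejected(self):
        arr = np.zeros((100, 100))
        with pytest.raises(ValueError):
            crop_roi(arr, SeedROI(0, (90, 90, 101, 101)))


class TestSplitMasks:
    def test_all_background(self):
        t = split_masks(LabelMap(np.zeros((10, 10), np.uint8)),
                        SeedROI(0, (0, 0, 10, 10)))
        assert not t.seed_body.any() and not t.full_plant.any() \
            and not t.seedling.any()

    def test_seed_only(self):
        lm = np.zeros((10, 10), np.uint8)
        lm[2:5, 2:5] = 1
        t = split_masks(LabelMap(lm), SeedROI(0, (0, 0, 10, 10)))
        assert np.array_equal(t.seed_body, t.full_plant)
        assert not t.seedling.any()

    def test_full_plant_is_union(self):
        lm = np.zeros((10, 10), np.uint8)
        lm[0, 0] = 1
        lm[5, 5] = 2
        lm[9, 9] = 3
        t = split_masks(LabelMap(lm), SeedROI(0, (0, 0, 10, 10)))
        assert t.full_plant.sum() == 3
        assert t.root.sum() == 1 and t.root[5, 5]


class TestAlignSeries:
    def _series(self, base, shifted_list):
        from germtrack.series_io import Frame, ImageSeries
        frames = [Frame(0, 0.0, base)]
        for i, px in enumerate(shifted_list, 1):
            frames.append(Frame(i, float(i), px))
        return ImageSeries(frames, 1.0, 0.05)

    def test_known_shift_recovered(self, rng):
        base = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        moved = np.roll(base, (3, -2), axis=(0, 1))
        s = align_series(self._series(base, [moved]))
        dr, dc = s.shifts[1]
        assert round(dr) == 3 and round(dc) == -2
        # residual shift after alignment is zero
        s2 = align_series(s)
        assert np.allclose(s2.shifts[1], (0, 0), atol=1)

    def test_identical_frames_zero_shift(self, rng):
        base = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        s = align_series(self._series(base, [base.copy()]))
        assert np.allclose(s.shifts[1], (0, 0), atol=0.5)

    def test_mode_none_is_identity(self, rng):
        base = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        orig = self._series(base, [np.roll(base, 2, axis=0)])
        out = align_series(orig, mode="none")
        assert out is orig

    def test_huge_shift_flagged_not_applied(self, rng):
        base = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        moved = np.roll(base, 15, axis=0)  # 37% of frame height
        with pytest.warns(UserWarning, match="unaligned"):
            s = align_series(self._series(base, [moved]))
        assert 1 in s.unaligned
        assert np.array_equal(s.frames[1].pixels, moved)

    def test_labels_follow_frames(self, rng):
        base = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        lab = np.zeros((64, 64), np.uint8)
        lab[10:14, 10:14] = 1
        moved = np.roll(base, (4, 0), axis=(0, 1))
        lab_moved = np.roll(lab, (4, 0), axis=(0, 1))
        s, maps = align_series(self._series(base, [moved]),
                               label_maps=[LabelMap(lab),
                                           LabelMap(lab_moved)])
        assert np.array_equal(maps[1].labels[10:14, 10:14],
                              lab[10:14, 10:14])
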