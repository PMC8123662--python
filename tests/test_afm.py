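"""AFM morphometry: segmentation, wire classification, tip correction, films."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwire import (
    FilmSpec,
    HeightMap,
    IslandSpec,
    ValidationError,
    WireSpec,
    classify_wires,
    correct_wire_length,
    height_statistics,
    morphometry_summary,
    segment_objects,
    synth_film,
)


def _disk_map(radius_px=5, height=2.4, size=64, pixel_size=2.0):
    rr, cc = np.ogrid[:size, :size]
    mask = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= radius_px**2
    heights = np.where(mask, height, 0.0)
    return HeightMap(heights=heights, pixel_size=pixel_size)


class TestSegmentation:
    def test_flat_map_yields_nothing(self):
        hmap = HeightMap(heights=np.zeros((32, 32)), pixel_size=2.0)
        assert segment_objects(hmap) == []

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            HeightMap(heights=np.zeros((0, 0)), pixel_size=2.0)

    def test_single_disk_round_trip(self):
        records = segment_objects(_disk_map())
        assert len(records) == 1
        r = records[0]
        assert r.max_height == pytest.approx(2.4)
        assert r.elongation == pytest.approx(1.0, abs=0.15)

    def test_two_disjoint_rods_counted(self):
        heights = np.zeros((64, 64))
        heights[10:13, 5:45] = 2.3
        heights[40:43, 5:45] = 2.3
        hmap = HeightMap(heights=heights, pixel_size=2.0)
        records = segment_objects(hmap)
        assert len(records) == 2

    def test_rod_extents_follow_principal_axes(self):
        heights = np.zeros((64, 128))
        heights[30:33, 10:90] = 2.3  # 3 x 80 pixels
        hmap = HeightMap(heights=heights, pixel_size=2.0)
        (r,) = segment_objects(hmap)
        assert r.length == pytest.approx(80 * 2.0, rel=0.02)
        assert r.width == pytest.approx(3 * 2.0, rel=0.2)

    def test_sub_threshold_object_ignored(self):
        hmap = _disk_map(height=0.6)
        assert segment_objects(hmap, height_threshold=1.0) == []

    def test_threshold_monotonicity(self):
        film = synth_film(
            FilmSpec(islands=IslandSpec(count=12, height_mean=2.3, height_sd=0.6)),
            shape=(256, 256), seed=5,
        )
        counts = [len(segment_objects(film, thr)) for thr in (1.0, 1.5, 2.0, 2.5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWireClassification:
    def test_threshold_behaviour(self):
        records = segment_objects(_disk_map())
        classified = classify_wires(records, min_elongation=2.0)
        assert not classified[0].is_wire

    def test_long_rod_is_wire(self):
        heights = np.zeros((128, 128))
        heights[60:70, 10:110] = 2.3  # 100 x 10 pixels
        hmap = HeightMap(heights=heights, pixel_size=2.0)
        (r,) = classify_wires(segment_objects(hmap))
        assert r.is_wire

    def test_ordering_preserved(self):
        heights = np.zeros((64, 64))
        heights[5:8, 5:40] = 2.3
        heights[30:40, 30:40] = 2.3
        records = segment_objects(HeightMap(heights=heights, pixel_size=1.0))
        classified = classify_wires(records)
        assert [r.id for r in classified] == [r.id for r in records]


class TestTipCorrection:
    @pytest.mark.parametrize(
        "measured, correction, expected",
        [(100.0, 15.0, 85.0), (10.0, 15.0, 0.0), (42.0, 0.0, 42.0)],
    )
    def test_constant_offset_with_clamp(self, measured, correction, expected):
        assert correct_wire_length(measured, correction) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(1.0, 500.0),
        b=st.floats(1.0, 500.0),
        correction=st.floats(0.0, 50.0),
    )
    def test_order_preserving(self, a, b, correction):
        ca, cb = correct_wire_length(a, correction), correct_wire_length(b, correction)
        assert (a <= b) == (ca <= cb) or ca == cb


class TestHeightStatistics:
    def test_mean_of_max_heights(self):
        maps = [_disk_map(height=h) for h in (2.0, 2.4, 2.8)]
        records = [segment_objects(m)[0] for m in maps]
        mean, sd = height_statistics(records)
        assert mean == pytest.approx(2.4)

    def test_single_record_sd_zero(self):
        records = segment_objects(_disk_map())
        assert height_statistics(records)[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            height_statistics([])

    def test_synthetic_film_height_recovered(self):
        film = synth_film(
            FilmSpec(islands=IslandSpec(count=50, height_mean=2.3, height_sd=0.2)),
            shape=(1024, 1024), pixel_size=2.0, seed=3,
        )
        records = segment_objects(film)
        mean, _ = height_statistics(records)
        assert len(records) == 50
        assert mean == pytest.approx(2.3, abs=0.1)


class TestSynthFilm:
    def test_island_count_round_trip(self):
        film = synth_film(
            FilmSpec(islands=IslandSpec(count=10)), shape=(512, 512), seed=1
        )
        assert len(segment_objects(film)) == 10

    def test_tip_broadening_lengthens_then_correction_recovers(self):
        pixel = 2.5  # nm; tip radius 7.5 nm = 3 px exactly
        true_length = 80.0
        film = synth_film(
            FilmSpec(wires=WireSpec(count=1, length_range=(true_length, true_length))),
            shape=(128, 128), pixel_size=pixel, tip_broadening=15.0, seed=4,
            axis_aligned_wires=True,
        )
        (r,) = classify_wires(segment_objects(film))
        assert r.is_wire
        assert r.length == pytest.approx(true_length + 15.0, abs=pixel)
        corrected = correct_wire_length(r.length, 15.0)
        assert corrected == pytest.approx(true_length, abs=pixel)

    def test_seed_repeat_identical(self):
        spec = FilmSpec(islands=IslandSpec(count=5), wires=WireSpec(count=2))
        a = synth_film(spec, shape=(256, 256), seed=8)
        b = synth_film(spec, shape=(256, 256), seed=8)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_overdense_spec_rejected(self):
        spec = FilmSpec(islands=IslandSpec(count=500, radius_range=(20.0, 30.0)))
        with pytest.raises(ValidationError, match="dense"):
            synth_film(spec, shape=(64, 64), seed=0, max_tries=5)

    def test_mixed_film_summary(self):
        spec = FilmSpec(
            islands=IslandSpec(count=8),
            wires=WireSpec(count=4, length_range=(60.0, 100.0)),
        )
        film = synth_film(spec, shape=(512, 512), seed=2)
        records = classify_wires(segment_objects(film))
        summary = morphometry_summary(records, tip_correction=15.0)
        assert summary.n_particles == 12
        assert summary.n_wires >= 4  # every true wire must classify as one
        assert summary.histogram_counts.sum() == summary.n_wires
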