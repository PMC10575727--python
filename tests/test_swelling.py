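"""Enteroid segmentation, tracking, diameter ratios, and inhibition."""

import numpy as np
import pytest

from enteroquant.analysis import swelling_ratios
from enteroquant.swelling import (
    EnteroidTrack,
    diameter_ratio,
    segment_enteroids,
    summarize_swelling,
    swelling_inhibition,
    track_objects,
)
from enteroquant.simulate import (
    SyntheticSwellingConfig,
    gen_swelling_series,
    swelling_config,
)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestSegmentEnteroids:
    def test_single_disk_equivalent_diameter(self):
        mask = disk_mask((200, 200), (100, 100), 50)
        labels = segment_enteroids(mask.astype(np.int32))
        from skimage.measure import regionprops

        props = regionprops(labels)
        assert len(props) == 1
        d = 2 * np.sqrt(props[0].area / np.pi)
        assert d == pytest.approx(100.0, rel=0.01)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="no enteroid"):
            labels = segment_enteroids(np.zeros((50, 50), dtype=np.int32))
        assert labels.max() == 0

    def test_two_disks_correct_areas(self):
        m = disk_mask((200, 200), (50, 50), 20) | disk_mask((200, 200), (150, 150), 30)
        labels = segment_enteroids(m.astype(np.int32))
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert len(areas) == 2
        assert areas[0] == pytest.approx(np.pi * 20 ** 2, rel=0.02)
        assert areas[1] == pytest.approx(np.pi * 30 ** 2, rel=0.02)

    def test_small_and_irregular_objects_dropped(self):
        m = disk_mask((100, 100), (30, 30), 15).astype(np.int32)
        m[70:72, 10:40] = 1  # thin streak: low circularity
        m[90, 90] = 1        # below min area
        labels = segment_enteroids(m)
        assert labels.max() == 1


class TestTrackObjects:
    def test_static_objects_full_tracks(self):
        frame = disk_mask((100, 100), (30, 30), 10).astype(np.int32)
        tracks = track_objects([frame, frame, frame])
        assert len(tracks) == 1
        assert len(tracks[0].times) == 3
        assert np.allclose(tracks[0].areas, tracks[0].areas[0])

    def test_displacement_beyond_gate_splits_track(self):
        f0 = disk_mask((120, 120), (30, 30), 10).astype(np.int32)
        f1 = disk_mask((120, 120), (30, 90), 10).astype(np.int32)  # 60 px jump
        tracks = track_objects([f0, f1], max_displacement=20.0)
        assert len(tracks) == 2
        assert all(len(tr.times) == 1 for tr in tracks)

    def test_generator_tracks_match_truth_order(self):
        cfg = SyntheticSwellingConfig(n_objects=5, seed=9,
                                      diameter_growth=(1.3,))
        frames, truth = gen_swelling_series(cfg)
        tracks = track_objects(frames, times=truth.data["times"],
                               max_displacement=5.0)
        assert len(tracks) == 5
        for tr, center in zip(tracks, truth.data["centers"]):
            assert np.allclose(tr.centroids[0], center, atol=1.0)


class TestDiameterRatio:
    def test_area_growth_maps_to_sqrt(self):
        tr = EnteroidTrack(0, [0.0, 1.0], [(0, 0), (0, 0)], [100.0, 144.0])
        assert diameter_ratio(tr, 1.0) == pytest.approx(1.2)

    def test_unchanged_is_unity(self):
        tr = EnteroidTrack(0, [0.0, 1.0], [(0, 0), (0, 0)], [80.0, 80.0])
        assert diameter_ratio(tr, 1.0) == pytest.approx(1.0)
        assert diameter_ratio(tr, 0.0) == 1.0  # t0 ratio exactly 1

    def test_missing_timepoint_rejected(self):
        tr = EnteroidTrack(0, [0.0, 1.0], [(0, 0), (0, 0)], [80.0, 90.0])
        with pytest.raises(ValueError):
            diameter_ratio(tr, 2.0)

    def test_generator_truth_recovered_with_discretization_tolerance(self):
        cfg = SyntheticSwellingConfig(n_objects=8, diameter_growth=(1.35,), seed=2)
        frames, truth = gen_swelling_series(cfg)
        ratios = swelling_ratios(frames, truth.data["times"], 1.0)
        assert ratios == pytest.approx(np.full(8, 1.35), abs=0.02)

    def test_invariant_to_translation_and_rotation(self):
        cfg = SyntheticSwellingConfig(n_objects=4, diameter_growth=(1.3,), seed=4)
        frames, truth = gen_swelling_series(cfg)
        base = np.sort(swelling_ratios(frames, truth.data["times"], 1.0))
        rotated = [np.rot90(f) for f in frames]
        rolled = [np.roll(f, (7, -5), axis=(0, 1)) for f in frames]
        assert np.allclose(np.sort(swelling_ratios(rotated, truth.data["times"], 1.0)), base)
        assert np.allclose(np.sort(swelling_ratios(rolled, truth.data["times"], 1.0)), base)


class TestSwellingInhibition:
    @pytest.mark.parametrize("ag,inh,expected", [
        (1.5, 1.25, 50.0),
        (1.4, 1.4, 0.0),
        (1.4, 1.0, 100.0),
    ])
    def test_formula(self, ag, inh, expected):
        assert swelling_inhibition(np.full(5, ag), np.full(5, inh)) == pytest.approx(expected)

    def test_no_swelling_in_agonist_arm_is_error(self):
        with pytest.raises(ValueError, match="no swelling"):
            swelling_inhibition(np.full(5, 0.99), np.full(5, 0.9))

    @pytest.mark.parametrize("condition,planted", [("healthy", 40.0), ("mvid", 50.0)])
    def test_recovers_planted_inhibition(self, condition, planted):
        """Noise-free default arms recover the planted percent within 5 points."""
        fa, ta = gen_swelling_series(swelling_config(condition, "agonist", seed=1))
        fi, _ = gen_swelling_series(
            swelling_config(condition, "agonist+crofelemer", seed=2))
        ra = swelling_ratios(fa, ta.data["times"], 1.0)
        ri = swelling_ratios(fi, ta.data["times"], 1.0)
        assert swelling_inhibition(ra, ri) == pytest.approx(planted, abs=5.0)

    def test_summary_statistics(self):
        cfg = SyntheticSwellingConfig(n_objects=6, diameter_growth=(1.2,), seed=3)
        frames, truth = gen_swelling_series(cfg)
        labeled = [segment_enteroids(f) for f in frames]
        tracks = track_objects(labeled, times=truth.data["times"])
        s = summarize_swelling(tracks, 1.0)
        assert s.median == pytest.approx(1.2, abs=0.02)
        assert s.iqr[0] <= s.median <= s.iqr[1]
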