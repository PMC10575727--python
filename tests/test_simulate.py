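"""Synthetic generators: planted truth, determinism, and config validation."""

import numpy as np
import pytest

from enteroquant.simulate import (
    ChannelSpec,
    SimEvent,
    SyntheticAssayConfig,
    SyntheticImageConfig,
    SyntheticPhConfig,
    SyntheticSwellingConfig,
    SyntheticTruth,
    gen_isc_trace,
    gen_mxif_image,
    gen_ph_trace,
    gen_swelling_series,
)


class TestImageGenerator:
    def test_noise_free_truth_lists_exact_spot_count(self):
        cfg = SyntheticImageConfig(
            channels={"DAPI": ChannelSpec("nuclei", n_spots=10)},
            noise_sd=0.0, seed=0)
        _, truth = gen_mxif_image(cfg)
        assert len(truth.data["channels"]["DAPI"]["centers"]) == 10

    def test_same_seed_identical_pixels(self):
        cfg = SyntheticImageConfig(
            channels={"DAPI": ChannelSpec("nuclei", n_spots=20),
                      "CD10": ChannelSpec("ribbon", n_fragments=4)},
            seed=42)
        a, ta = gen_mxif_image(cfg)
        b, tb = gen_mxif_image(cfg)
        for name in a.channel_names:
            assert np.array_equal(a[name], b[name])
        assert ta.to_yaml() == tb.to_yaml()

    def test_impossible_fragment_placement_errors(self):
        cfg = SyntheticImageConfig(
            shape=(64, 64),
            channels={"CD10": ChannelSpec("ribbon", n_fragments=40,
                                          fragment_length=50.0)},
            seed=0)
        with pytest.raises(RuntimeError, match="fragment"):
            gen_mxif_image(cfg)

    def test_invalid_correlation_target_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec("correlated", source="x", pearson=1.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticImageConfig(channels={}, noise_sd=-1.0)


class TestIscGenerator:
    def test_no_events_no_noise_is_constant_baseline(self):
        cfg = SyntheticAssayConfig(duration=100.0, baseline=7.0, noise_sd=0.0)
        trace, _ = gen_isc_trace(cfg)
        assert np.allclose(trace.value, 7.0)

    def test_sustained_event_plateau_equals_amplitude(self):
        cfg = SyntheticAssayConfig(
            duration=600.0, baseline=5.0, noise_sd=0.0,
            events=[SimEvent(50.0, "forskolin", 20.0, "sustained", tau=10.0)])
        trace, _ = gen_isc_trace(cfg)
        assert trace.value[-1] - 5.0 == pytest.approx(20.0, abs=1e-6)

    def test_dose_run_matches_four_pl_closed_form(self):
        cfg = SyntheticAssayConfig(
            doses=[1.0, 10.0, 30.0, 100.0],
            four_pl=(0.0, 80.0, 30.0, 1.0),
            noise_sd=0.0, seed=0)
        _, truth = gen_isc_trace(cfg)
        for entry in truth.data["doses"]:
            d = entry["dose"]
            expected = 80.0 / (1.0 + 30.0 / d)  # slope-1 4PL closed form
            assert entry["inhibition_pct"] == pytest.approx(expected)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            SyntheticAssayConfig(doses=[10.0, 1.0], four_pl=(0, 80, 30, 1))

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            SyntheticAssayConfig(duration=100.0,
                                 events=[SimEvent(150.0, "x", 1.0)])


class TestPhGenerator:
    def test_zero_recovery_flat_post_readdition(self):
        cfg = SyntheticPhConfig(delta_ph=0.0, noise_sd=0.0, seed=0)
        trace, _ = gen_ph_trace(cfg)
        t_re, t_cal = 120.0, 420.0
        seg = trace.value[(trace.time >= t_re) & (trace.time < t_cal)]
        assert np.ptp(seg) == pytest.approx(0.0)

    def test_clamp_signal_spacing_follows_affine_slope(self):
        cfg = SyntheticPhConfig(noise_sd=0.0, signal_slope=0.3,
                                signal_intercept=-1.5, seed=0)
        trace, truth = gen_ph_trace(cfg)
        t0 = truth.data["calibration_start"]
        dur = truth.data["clamp_duration"]
        means = [trace.window(t0 + i * dur + 10, t0 + (i + 1) * dur).mean()
                 for i in range(3)]
        assert means[1] - means[0] == pytest.approx(0.3, abs=1e-9)
        assert means[2] - means[1] == pytest.approx(0.3, abs=1e-9)

    def test_duplicate_clamp_ph_rejected(self):
        with pytest.raises(ValueError):
            SyntheticPhConfig(clamp_ph=(6.0, 6.0, 8.0))


class TestSwellingGenerator:
    def test_area_growth_and_truth_order(self):
        cfg = SyntheticSwellingConfig(n_objects=3, diameter_growth=(1.2,), seed=0)
        frames, truth = gen_swelling_series(cfg)
        assert len(frames) == 2
        for i in range(3):
            a0 = (frames[0] == i + 1).sum()
            a1 = (frames[1] == i + 1).sum()
            assert np.sqrt(a1 / a0) == pytest.approx(1.2, abs=0.02)
            assert truth.data["diameter_growth"][i][0] == pytest.approx(1.2)

    def test_unit_growth_keeps_masks_identical(self):
        cfg = SyntheticSwellingConfig(n_objects=4, diameter_growth=(1.0,), seed=1)
        frames, _ = gen_swelling_series(cfg)
        assert np.array_equal(frames[0], frames[1])

    def test_overflowing_placement_errors(self):
        cfg = SyntheticSwellingConfig(
            shape=(64, 64), n_objects=10, radius_range=(20.0, 25.0),
            diameter_growth=(1.5,), seed=0)
        with pytest.raises(RuntimeError):
            gen_swelling_series(cfg)


class TestTruthSerialization:
    def test_yaml_round_trip(self):
        truth = SyntheticTruth("demo", {
            "a": [1, 2.5, "x"], "nested": {"b": np.float64(3.0)}})
        again = SyntheticTruth.from_yaml(truth.to_yaml())
        assert again.kind == "demo"
        assert again.data == {"a": [1, 2.5, "x"], "nested": {"b": 3.0}}

    def test_serialization_is_deterministic(self):
        t = SyntheticTruth("demo", {"z": 1, "a": 2})
        assert t.to_yaml() == SyntheticTruth("demo", {"a": 2, "z": 1}).to_yaml()
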