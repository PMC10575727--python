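"""Isc response extraction, inhibitor fractions, and 4PL dose-response fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from enteroquant.core import AssayTrace, TraceEvent
from enteroquant.electrophys import (
    delta_isc,
    fit_dose_response,
    four_param_logistic,
    percent_change,
    sensitive_fraction,
)
from enteroquant.analysis import measure_dose_inhibition, sglt1_sensitive_delta
from enteroquant.simulate import (
    SimEvent,
    SyntheticAssayConfig,
    crofelemer_dose_config,
    gen_isc_trace,
    sglt1_config,
)


def step_trace(amplitude=20.0, baseline=5.0, t_event=100.0, duration=400.0):
    t = np.arange(0.0, duration, 1.0)
    y = np.full_like(t, baseline)
    y[t >= t_event] += amplitude
    return AssayTrace(t, y, [TraceEvent(t_event, "forskolin", 10.0)], units="uA/cm2")


class TestDeltaIsc:
    def test_constant_trace_gives_zero(self):
        tr = step_trace(amplitude=0.0)
        assert delta_isc(tr, "forskolin", "plateau") == pytest.approx(0.0)

    def test_clean_step_plateau(self):
        tr = step_trace(amplitude=20.0)
        assert delta_isc(tr, "forskolin", "plateau") == pytest.approx(20.0)

    def test_peak_mode_recovers_transient_amplitude(self):
        cfg = SyntheticAssayConfig(
            duration=400.0, baseline=5.0, noise_sd=0.0,
            events=[SimEvent(100.0, "carbachol", 15.0, "peak", tau=30.0)],
        )
        trace, truth = gen_isc_trace(cfg)
        d = delta_isc(trace, "carbachol", "peak")
        assert d == pytest.approx(truth.data["events"][0]["amplitude"], rel=1e-6)

    def test_missing_event_raises(self):
        with pytest.raises(KeyError):
            delta_isc(step_trace(), "glucose")

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            delta_isc(step_trace(), "forskolin", mode="average")

    @given(st.floats(-50, 50))
    def test_invariant_to_constant_offset(self, offset):
        tr = step_trace(amplitude=12.0)
        shifted = AssayTrace(tr.time, tr.value + offset, tr.events)
        assert delta_isc(shifted, "forskolin", "plateau") == pytest.approx(
            delta_isc(tr, "forskolin", "plateau")
        )


class TestSensitiveFraction:
    @pytest.mark.parametrize("control,inhibited,expected", [
        (100.0, 20.0, 80.0),
        (50.0, 50.0, 0.0),
    ])
    def test_formula(self, control, inhibited, expected):
        assert sensitive_fraction(control, inhibited) == pytest.approx(expected)

    def test_overshoot_flagged(self):
        with pytest.warns(UserWarning, match="overshoot"):
            assert sensitive_fraction(40.0, -2.0) == pytest.approx(105.0)

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError):
            sensitive_fraction(0.0, 10.0)

    @given(st.floats(0.1, 1e3))
    def test_complete_block_is_100_percent(self, x):
        assert sensitive_fraction(x, 0.0) == pytest.approx(100.0)


class TestPercentChange:
    @pytest.mark.parametrize("ref,test,expected", [
        (10.0, 4.0, 60.0),
        (10.0, 10.0, 0.0),
        (10.0, 13.0, -30.0),
    ])
    def test_formula(self, ref, test, expected):
        assert percent_change(ref, test) == pytest.approx(expected)

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestFitDoseResponse:
    def test_noiseless_round_trip(self):
        doses = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
        y = four_param_logistic(doses, 0.0, 80.0, 30.0, 1.0)
        fit = fit_dose_response(doses, y)
        assert fit.converged
        assert fit.ceiling == pytest.approx(80.0, rel=0.01)
        assert fit.ic50 == pytest.approx(30.0, rel=0.01)
        assert fit.slope == pytest.approx(1.0, rel=0.01)

    def test_flat_response_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            fit_dose_response(np.array([1.0, 3.0, 10.0, 30.0]), np.zeros(4))

    def test_three_doses_insufficient(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_dose_response(np.array([1.0, 10.0, 100.0]),
                              np.array([5.0, 40.0, 70.0]))

    def test_recovers_truth_under_noise_across_seeds(self):
        """Median IC50 error stays below 15% at 5%-of-ceiling noise."""
        errors = []
        for seed in range(20):
            trace, truth = gen_isc_trace(crofelemer_dose_config(seed=seed))
            doses, inhib = measure_dose_inhibition(trace)
            fit = fit_dose_response(doses, inhib)
            assert fit.converged
            errors.append(abs(fit.ic50 - 30.0) / 30.0)
        assert np.median(errors) < 0.15


class TestSglt1Protocol:
    def test_phlorizin_sensitive_component_recovered(self):
        cfg = sglt1_config("control", seed=0)
        cfg.noise_sd = 0.0
        trace, truth = gen_isc_trace(cfg)
        sens = sglt1_sensitive_delta(trace)
        planted = next(e["amplitude"] for e in truth.data["events"]
                       if e["agent"] == "glucose") - 2.0  # insensitive part
        assert sens == pytest.approx(planted, abs=0.2)

    def test_disease_deficit_is_sixty_percent_by_construction(self):
        tc, _ = gen_isc_trace(sglt1_config("control", seed=1))
        tm, _ = gen_isc_trace(sglt1_config("mvid", seed=2))
        deficit = percent_change(sglt1_sensitive_delta(tc), sglt1_sensitive_delta(tm))
        assert deficit == pytest.approx(60.0, abs=5.0)
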