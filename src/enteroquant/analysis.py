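"""Protocol-level analysis helpers built on the per-module primitives.

These functions encode whole assay protocols — cumulative-dose
inhibition runs, the glucose/phlorizin SGLT1 protocol, calibrated NHE
recovery, and swelling-arm ratio extraction — so the pipeline, the CLI
and scripts can go from a raw trace or mask series to the headline
quantity in one call.
"""

from __future__ import annotations

import numpy as np

from .core import AssayTrace
from .electrophys import sensitive_fraction
from .ph import NheActivityResult, fit_calibration, nhe_activity, signal_to_ph
from .swelling import diameter_ratio, segment_enteroids, track_objects

__all__ = [
    "measure_dose_inhibition",
    "sglt1_sensitive_delta",
    "analyze_ph_trace",
    "swelling_ratios",
]


def _segment_plateau(trace: AssayTrace, start: float, stop: float) -> float:
    """Mean value over the final third of [start, stop)."""
    vals = trace.window(start + 2.0 * (stop - start) / 3.0, stop)
    if vals.size == 0:
        raise ValueError(f"no samples in segment [{start}, {stop})")
    return float(vals.mean())


def measure_dose_inhibition(
    trace: AssayTrace,
    agonist: str = "forskolin+carbachol",
    inhibitor: str = "crofelemer",
    baseline_window: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent inhibition of the stimulated current at each dose.

    Expects a cumulative-dose protocol: one agonist event establishing a
    stimulated plateau, then successive inhibitor additions. For each
    dose the residual stimulated current (plateau before the next
    addition minus the pre-agonist baseline) is compared with the
    uninhibited stimulated current. Returns (doses, percent inhibition).
    """
    t_ag = trace.event(agonist).time
    dose_events = trace.events_for(inhibitor)
    if not dose_events:
        raise ValueError(f"no {inhibitor!r} dose events in trace")
    if any(ev.concentration is None for ev in dose_events):
        raise ValueError("dose events must carry concentrations")
    dose_events = sorted(dose_events, key=lambda e: e.time)

    base = trace.window(t_ag - baseline_window, t_ag)
    if base.size == 0:
        raise ValueError("no samples before the agonist event")
    baseline = float(base.mean())

    bounds = [t_ag] + [ev.time for ev in dose_events] + [float(trace.time[-1])]
    delta0 = _segment_plateau(trace, bounds[0], bounds[1]) - baseline
    if delta0 == 0:
        raise ValueError("no stimulated current; inhibition undefined")
    doses, inhib = [], []
    for i, ev in enumerate(dose_events):
        delta_d = _segment_plateau(trace, bounds[i + 1], bounds[i + 2]) - baseline
        doses.append(ev.concentration)
        inhib.append(sensitive_fraction(delta0, delta_d))
    return np.asarray(doses), np.asarray(inhib)


def sglt1_sensitive_delta(
    trace: AssayTrace,
    glucose: str = "glucose",
    blocker: str = "phlorizin",
    baseline_window: float = 60.0,
) -> float:
    """Phlorizin-sensitive, glucose-stimulated ΔIsc (µA/cm²).

    The SGLT1 readout: the glucose-stimulated plateau minus the residual
    plateau after phlorizin, both relative to the pre-glucose baseline,
    i.e. exactly the component of current the blocker removes.
    """
    t_glu = trace.event(glucose).time
    t_blk = trace.event(blocker).time
    if t_blk <= t_glu:
        raise ValueError("blocker must follow glucose in this protocol")
    base = trace.window(t_glu - baseline_window, t_glu)
    if base.size == 0:
        raise ValueError("no samples before the glucose event")
    baseline = float(base.mean())
    d_glu = _segment_plateau(trace, t_glu, t_blk) - baseline
    d_res = _segment_plateau(trace, t_blk, float(trace.time[-1])) - baseline
    return d_glu - d_res


def analyze_ph_trace(
    trace: AssayTrace,
    baseline_window: float = 30.0,
    rate_window: float = 60.0,
    window: float | None = None,
    clamp_skip_fraction: float = 0.2,
) -> NheActivityResult:
    """Calibrate a pH-probe trace from its clamp events and quantify recovery.

    Clamp segments are located from events labelled ``clamp_<pH>``; the
    first ``clamp_skip_fraction`` of each segment is discarded as
    equilibration. The affine calibration converts the whole trace to
    pH, and recovery after the ``na_readdition`` event is quantified
    over ``window`` seconds (default: up to the first clamp).
    """
    clamp_events = sorted(
        (ev for ev in trace.events if ev.agent.startswith("clamp_")),
        key=lambda e: e.time,
    )
    if len(clamp_events) < 3:
        raise ValueError("need at least three clamp_<pH> events to calibrate")
    t_end = float(trace.time[-1])
    segments: dict[float, np.ndarray] = {}
    for i, ev in enumerate(clamp_events):
        stop = clamp_events[i + 1].time if i + 1 < len(clamp_events) else t_end + 1e-9
        start = ev.time + clamp_skip_fraction * (stop - ev.time)
        segments[float(ev.agent.split("_", 1)[1])] = trace.window(start, stop)
    calibration = fit_calibration(segments)
    ph_trace = signal_to_ph(trace, calibration)
    t_re = trace.event("na_readdition").time
    if window is None:
        window = clamp_events[0].time - t_re
    return nhe_activity(
        ph_trace, t_re, window=window,
        baseline_window=baseline_window, rate_window=rate_window,
    )


def swelling_ratios(
    frames: list[np.ndarray],
    times: list[float],
    t: float,
    min_area: float = 50.0,
    min_circularity: float = 0.6,
    max_displacement: float = 20.0,
) -> np.ndarray:
    """Per-enteroid diameter ratios at time ``t`` from a mask/image series."""
    labeled = [
        segment_enteroids(f, min_area=min_area, min_circularity=min_circularity)
        for f in frames
    ]
    tracks = track_objects(labeled, times=list(times),
                           max_displacement=max_displacement)
    ratios = [
        diameter_ratio(tr, t)
        for tr in tracks
        if tr.times[0] == times[0] and tr.has_time(t)
    ]
    if not ratios:
        raise ValueError("no tracks span t0 and the requested time")
    return np.asarray(ratios)
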