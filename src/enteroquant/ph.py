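"""Intracellular pH calibration and Na⁺/H⁺-exchanger (NHE) kinetics.

A pH-sensitive fluorophore (e.g. SNARF-5F) reports intracellular pH as a
scalar signal — either a precomputed emission ratio or a single
intensity series; both are handled identically. At the end of each
experiment the signal is calibrated against nigericin/K⁺ clamps that set
intracellular pH to known values (6, 7, 8 by default). NHE activity is
read out from the alkalinization after Na⁺ re-addition following a
Na⁺-free acid load: the pH recovery magnitude ΔpH and its initial rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AssayTrace

__all__ = [
    "CalibrationCurve",
    "NheActivityResult",
    "fit_calibration",
    "signal_to_ph",
    "nhe_activity",
    "inhibitor_corrected",
]


@dataclass
class CalibrationCurve:
    """Affine signal→pH map fitted to nigericin clamp segments."""

    clamp_ph: np.ndarray
    clamp_signal: np.ndarray  # mean signal per clamp
    slope: float              # pH per signal unit
    intercept: float
    residuals: np.ndarray
    signal_range: tuple[float, float]

    def __call__(self, signal: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(signal, dtype=float) + self.intercept


@dataclass
class NheActivityResult:
    """Na⁺-dependent pH recovery quantification."""

    delta_ph: float          # pH units over the recovery window
    initial_rate: float      # pH units / s over the first part of recovery
    n_rate_samples: int
    corrected_delta_ph: float | None = None
    negative_corrected: bool = False


def fit_calibration(clamp_segments: dict[float, np.ndarray]) -> CalibrationCurve:
    """Fit the affine signal→pH map from clamp segments.

    ``clamp_segments`` maps each clamped pH to the signal samples
    recorded while that clamp was applied. At least three distinct pH
    values are required (three points cannot constrain more than an
    affine model) and the mean signal must be strictly monotone in pH.
    """
    if len(clamp_segments) < 3:
        raise ValueError("need at least 3 distinct clamp pH values")
    ph = np.array(sorted(clamp_segments), dtype=float)
    sig = np.array([np.mean(clamp_segments[p]) for p in ph])
    d = np.diff(sig)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(
            "clamp mean signals are not monotone in pH; calibration invalid"
        )
    slope, intercept = np.polyfit(sig, ph, 1)
    resid = ph - (slope * sig + intercept)
    all_samples = np.concatenate([np.ravel(v) for v in clamp_segments.values()])
    return CalibrationCurve(
        clamp_ph=ph,
        clamp_signal=sig,
        slope=float(slope),
        intercept=float(intercept),
        residuals=resid,
        # range actually observed during calibration, noise included
        signal_range=(float(all_samples.min()), float(all_samples.max())),
    )


def signal_to_ph(trace: AssayTrace, calibration: CalibrationCurve) -> AssayTrace:
    """Convert a fluorescence trace to a pH trace via the calibration.

    Signals outside the calibrated range are still converted (linear
    extrapolation) but a warning is raised so drifting or saturating
    probes are noticed.
    """
    lo, hi = calibration.signal_range
    out_of_range = (trace.value < lo) | (trace.value > hi)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} samples outside the calibrated signal "
            "range; pH values there are extrapolated"
        )
    return AssayTrace(
        time=trace.time.copy(),
        value=calibration(trace.value),
        events=list(trace.events),
        units="pH",
    )


def nhe_activity(
    ph_trace: AssayTrace,
    readdition_time: float,
    window: float = 300.0,
    baseline_window: float = 30.0,
    rate_window: float = 60.0,
    min_rate_samples: int = 5,
) -> NheActivityResult:
    """Quantify pH recovery after Na⁺ re-addition.

    ΔpH is the mean pH over the final 10% of the recovery ``window``
    minus the mean over the ``baseline_window`` seconds preceding
    re-addition. The initial rate is the least-squares slope of pH
    against time over the first ``rate_window`` seconds of recovery.
    """
    t = ph_trace.time
    if not (t[0] <= readdition_time <= t[-1]):
        raise ValueError("re-addition time outside the trace")
    if readdition_time + window > t[-1] + 1e-9:
        raise ValueError("recovery window extends beyond the trace")
    base = ph_trace.window(readdition_time - baseline_window, readdition_time)
    if base.size == 0:
        raise ValueError("no samples in the pre-re-addition baseline window")
    tail_start = readdition_time + 0.9 * window
    tail = ph_trace.window(tail_start, readdition_time + window)
    if tail.size == 0:
        raise ValueError("recovery window too short: empty plateau segment")
    delta = float(tail.mean() - base.mean())

    sel = (t >= readdition_time) & (t <= readdition_time + rate_window)
    if sel.sum() < min_rate_samples:
        raise ValueError(
            f"fewer than {min_rate_samples} samples in the rate window"
        )
    slope = float(np.polyfit(t[sel] - readdition_time, ph_trace.value[sel], 1)[0])
    return NheActivityResult(
        delta_ph=delta, initial_rate=slope, n_rate_samples=int(sel.sum())
    )


def inhibitor_corrected(
    test: NheActivityResult, inhibitor: NheActivityResult
) -> NheActivityResult:
    """NHE-specific ΔpH: test recovery minus the inhibitor-condition recovery.

    The paired inhibitor condition (e.g. S3226 pretreatment) measures
    the NHE-independent component; subtracting it isolates the
    transporter-dependent recovery. A negative difference is floored at
    0 and flagged.
    """
    diff = test.delta_ph - inhibitor.delta_ph
    negative = diff < 0
    return NheActivityResult(
        delta_ph=test.delta_ph,
        initial_rate=test.initial_rate,
        n_rate_samples=test.n_rate_samples,
        corrected_delta_ph=max(diff, 0.0),
        negative_corrected=negative,
    )
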