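"""Short-circuit current (Isc) trace analysis.

Transepithelial short-circuit current under voltage clamp is the net
electrogenic ion transport across an epithelial monolayer. Secretagogue
responses are quantified as the current change ΔIsc over a baseline
(plateau mode for sustained cAMP responses such as forskolin, peak mode
for transient Ca²⁺ responses such as carbachol), inhibitor efficacy as
the percent of a stimulated current abolished, and dose-dependent block
by a four-parameter logistic (4PL) fit in log dose yielding the IC50 and
the maximal inhibition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AssayTrace, TraceEvent

__all__ = [
    "DoseResponseFit",
    "delta_isc",
    "sensitive_fraction",
    "fit_dose_response",
    "percent_change",
    "four_param_logistic",
]


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit of percent inhibition against dose.

    ``floor`` and ``ceiling`` are the bottom and top asymptotes in
    percent inhibition, ``ic50`` the half-maximal dose (µM), ``slope``
    the Hill coefficient. ``converged`` is False when the optimizer
    failed; parameters are then None.
    """

    floor: float | None
    ceiling: float | None
    ic50: float | None
    slope: float | None
    residuals: np.ndarray | None
    converged: bool
    doses: np.ndarray | None = None

    @property
    def max_inhibition(self) -> float | None:
        return self.ceiling


def four_param_logistic(dose: np.ndarray, floor: float, ceiling: float,
                        ic50: float, slope: float) -> np.ndarray:
    """Percent inhibition at ``dose`` for a 4PL in log10 dose."""
    dose = np.asarray(dose, dtype=float)
    return floor + (ceiling - floor) / (
        1.0 + 10.0 ** (slope * (np.log10(ic50) - np.log10(dose)))
    )


def delta_isc(
    trace: AssayTrace,
    event: TraceEvent | str,
    mode: str = "plateau",
    baseline_window: float = 60.0,
    response_window: float = 180.0,
) -> float:
    """Agonist-evoked current change ΔIsc (µA/cm²).

    The baseline is the mean current over ``baseline_window`` seconds
    immediately before the event. In ``peak`` mode the response is the
    maximum current inside the ``response_window`` after the event; in
    ``plateau`` mode it is the mean over the final third of that window,
    once the sustained phase has settled.
    """
    if isinstance(event, str):
        event = trace.event(event)  # raises KeyError when absent
    if mode not in ("peak", "plateau"):
        raise ValueError(f"mode must be 'peak' or 'plateau', got {mode!r}")
    t0 = event.time
    base = trace.window(t0 - baseline_window, t0)
    if base.size == 0:
        raise ValueError("baseline window contains no samples")
    resp_start = t0 if mode == "peak" else t0 + 2 * response_window / 3
    resp = trace.window(resp_start, t0 + response_window)
    if resp.size == 0:
        raise ValueError("response window contains no samples")
    baseline = float(base.mean())
    if mode == "peak":
        return float(resp.max() - baseline)
    return float(resp.mean() - baseline)


def sensitive_fraction(delta_control: float, delta_inhibited: float) -> float:
    """Percent of a stimulated current blocked by an inhibitor.

    100 × (ΔIsc_control − ΔIsc_inhibited) / ΔIsc_control. Values above
    100% (inhibited response crossing below baseline) are reported as
    computed but flagged with a warning.
    """
    if delta_control == 0:
        raise ValueError("control ΔIsc is zero; fraction undefined")
    pct = 100.0 * (delta_control - delta_inhibited) / delta_control
    if pct > 100.0:
        warnings.warn(f"inhibited response overshoots baseline: {pct:.1f}% > 100%")
    return pct


def percent_change(reference: float, test: float) -> float:
    """Percent reduction of ``test`` relative to ``reference``.

    Positive for a deficit (test below reference), negative for an
    increase — e.g. the SGLT1 current deficit of disease monolayers
    versus controls.
    """
    if reference == 0:
        raise ValueError("reference value is zero; percent change undefined")
    return 100.0 * (reference - test) / reference


def fit_dose_response(
    doses: np.ndarray,
    inhibition_pct: np.ndarray,
    floor_bounds: tuple[float, float] = (0.0, 100.0),
    ceiling_bounds: tuple[float, float] = (0.0, 100.0),
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent inhibition against dose.

    The model is fitted in log10 dose with the floor and ceiling bounded
    to the physical percent-inhibition scale by default (overrideable).
    Requires at least four distinct positive doses; a flat response is
    degenerate and refused.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(inhibition_pct, dtype=float)
    if doses.shape != y.shape:
        raise ValueError("doses and responses must align")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses for a 4PL fit")
    if np.ptp(y) == 0:
        raise ValueError("constant response: dose-response fit is degenerate")

    lo = np.array([floor_bounds[0], ceiling_bounds[0], doses.min() / 100.0, 0.1])
    hi = np.array([floor_bounds[1], ceiling_bounds[1], doses.max() * 100.0, 10.0])
    p0 = np.array([
        max(lo[0], min(hi[0], y.min())),
        max(lo[1], min(hi[1], y.max())),
        float(np.sqrt(doses.min() * doses.max())),
        1.0,
    ])
    try:
        popt, _ = curve_fit(
            four_param_logistic, doses, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError:
        return DoseResponseFit(None, None, None, None, None, converged=False)
    floor, ceiling, ic50, slope = (float(v) for v in popt)
    resid = y - four_param_logistic(doses, *popt)
    return DoseResponseFit(
        floor=floor, ceiling=ceiling, ic50=ic50, slope=slope,
        residuals=resid, converged=True, doses=doses,
    )
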