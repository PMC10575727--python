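"""Synthetic data generators with planted ground truth.

Every input modality the pipeline consumes can be generated here with a
known, serializable ground truth and seeded reproducibility:
multichannel fluorescence images (nuclei/marker spots, ribbon-like
brush-border fragments, correlated channel pairs), short-circuit
current traces with agonist steps and dose-dependent inhibition,
pH-probe traces with nigericin calibration clamps and Na⁺ re-addition
recovery, enteroid swelling mask series, and three-contrast
differential-expression tables with planted rescue genes.

Default disease and drug effect sizes encode the effects reported for
MVID patient-derived enteroids, so pipeline-level recovery checks are
self-contained:

* crofelemer dose–response: IC50 30 µM, maximal inhibition 80%
* crofelemer inhibition of forskolin-induced swelling: 40% in healthy
  enteroids, 50% in MVID enteroids
* SGLT1 (phlorizin-sensitive, glucose-stimulated) current reduced by
  60% in MVID monolayers versus controls

Quantities with no reported value (noise levels, kinetic time
constants, baseline magnitudes) are fixed here at physiologically
reasonable defaults and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .core import AssayTrace, MultichannelImage, TraceEvent

__all__ = [
    "SyntheticTruth",
    "ChannelSpec",
    "SyntheticImageConfig",
    "SimEvent",
    "SyntheticAssayConfig",
    "SyntheticPhConfig",
    "SyntheticSwellingConfig",
    "SyntheticDeConfig",
    "gen_mxif_image",
    "gen_isc_trace",
    "gen_ph_trace",
    "gen_swelling_series",
    "gen_de_tables",
    "crofelemer_dose_config",
    "sglt1_config",
    "nhe_config",
    "swelling_config",
]


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    kind: str
    data: dict

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"kind": self.kind, "data": _plain(self.data)}, sort_keys=True
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticTruth":
        obj = yaml.safe_load(text)
        return cls(kind=obj["kind"], data=obj["data"])


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML round trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------
# multichannel image generator


@dataclass
class ChannelSpec:
    """Content model for one synthetic channel.

    kind: ``nuclei`` | ``marker`` (isotropic Gaussian spots),
    ``ribbon`` (dilated line fragments), or ``correlated`` (noisy affine
    copy of another channel hitting a requested Pearson correlation).
    """

    kind: str
    n_spots: int = 0
    amplitude: float = 150.0
    spot_sigma: float = 2.5
    n_fragments: int = 0
    fragment_length: float = 60.0
    fragment_length_sd: float = 0.0
    ribbon_width: int = 2
    source: str | None = None
    pearson: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("nuclei", "marker", "ribbon", "correlated"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "correlated":
            if self.source is None:
                raise ValueError("correlated channel needs a source channel")
            if not -1.0 <= self.pearson <= 1.0:
                raise ValueError("requested correlation must lie in [-1, 1]")


@dataclass
class SyntheticImageConfig:
    shape: tuple[int, int] = (256, 256)
    channels: dict[str, ChannelSpec] = field(default_factory=dict)
    background: float = 5.0
    noise_sd: float = 2.0
    min_spot_separation: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("image shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    if shape[0] - 1 - 2 * margin <= 0 or shape[1] - 1 - 2 * margin <= 0:
        raise RuntimeError(
            f"objects of margin {margin:.1f} cannot fit inside a {shape} image"
        )
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} points with separation {min_sep} "
                f"in {shape} after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep ** 2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts)


def gen_mxif_image(
    config: SyntheticImageConfig,
) -> tuple[MultichannelImage, SyntheticTruth]:
    """Generate a multichannel image with planted spots and fragments.

    Spots are isotropic Gaussians at recorded centres; ribbons are line
    segments of recorded endpoints dilated to a small width; correlated
    channels mix a standardized copy of the source with independent
    noise to hit the requested Pearson coefficient in expectation.
    Additive Gaussian noise is clipped at zero (background-corrected
    intensities are non-negative).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    rr_grid, cc_grid = np.mgrid[0: shape[0], 0: shape[1]]
    channels: dict[str, np.ndarray] = {}
    truth_data: dict = {"channels": {}}

    for name, spec in config.channels.items():
        if spec.kind in ("nuclei", "marker"):
            pts = _place_points(
                rng, spec.n_spots, shape, config.min_spot_separation,
                margin=3 * spec.spot_sigma,
            )
            img = np.zeros(shape)
            for r, c in pts:
                img += spec.amplitude * np.exp(
                    -((rr_grid - r) ** 2 + (cc_grid - c) ** 2)
                    / (2 * spec.spot_sigma ** 2)
                )
            channels[name] = img
            truth_data["channels"][name] = {
                "kind": spec.kind,
                "centers": pts.tolist(),
                "amplitude": spec.amplitude,
            }
        elif spec.kind == "ribbon":
            img = np.zeros(shape)
            occupied = np.zeros(shape, dtype=bool)
            selem = disk(spec.ribbon_width)
            frags = []
            for _ in range(spec.n_fragments):
                placed = False
                for _try in range(2000):
                    length = spec.fragment_length
                    if spec.fragment_length_sd > 0:
                        length = max(
                            4.0, rng.normal(length, spec.fragment_length_sd)
                        )
                    theta = rng.uniform(0, np.pi)
                    margin = spec.ribbon_width + 2
                    r0 = rng.uniform(margin, shape[0] - 1 - margin)
                    c0 = rng.uniform(margin, shape[1] - 1 - margin)
                    r1 = r0 + length * np.sin(theta)
                    c1 = c0 + length * np.cos(theta)
                    if not (margin <= r1 < shape[0] - margin
                            and margin <= c1 < shape[1] - margin):
                        continue
                    lr, lc = draw_line(int(round(r0)), int(round(c0)),
                                       int(round(r1)), int(round(c1)))
                    frag_mask = np.zeros(shape, dtype=bool)
                    frag_mask[lr, lc] = True
                    frag_mask = binary_dilation(frag_mask, selem)
                    grown = binary_dilation(frag_mask, disk(3))
                    if (grown & occupied).any():
                        continue
                    occupied |= grown
                    img[frag_mask] = np.maximum(img[frag_mask], spec.amplitude)
                    end_a = (int(round(r0)), int(round(c0)))
                    end_b = (int(round(r1)), int(round(c1)))
                    frags.append({
                        "endpoints": [list(end_a), list(end_b)],
                        "length": float(np.hypot(end_b[0] - end_a[0],
                                                 end_b[1] - end_a[1])),
                    })
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place fragment {len(frags) + 1} of "
                        f"{spec.n_fragments} without overlap"
                    )
            channels[name] = img
            truth_data["channels"][name] = {
                "kind": "ribbon",
                "fragments": frags,
                "lengths": [f["length"] for f in frags],
            }
        elif spec.kind == "correlated":
            if spec.source not in channels:
                raise ValueError(
                    f"correlated channel {name!r}: source {spec.source!r} "
                    "must be generated first"
                )
            src = channels[spec.source]
            sd = src.std()
            z = (src - src.mean()) / sd if sd > 0 else np.zeros(shape)
            g = rng.standard_normal(shape)
            rho = spec.pearson
            mix = rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * g
            channels[name] = mix * 20.0 + 100.0
            truth_data["channels"][name] = {
                "kind": "correlated",
                "source": spec.source,
                "pearson": rho,
            }

    for name in channels:
        noisy = channels[name] + config.background
        if config.noise_sd > 0:
            noisy = noisy + rng.normal(0, config.noise_sd, shape)
        channels[name] = np.clip(noisy, 0, None)

    truth = SyntheticTruth("mxif_image", truth_data)
    return MultichannelImage(channels=channels), truth


# ---------------------------------------------------------------------------
# short-circuit current generator


@dataclass
class SimEvent:
    """Planted intervention in a simulated Isc trace."""

    time: float
    agent: str
    amplitude: float
    shape: str = "sustained"  # or "peak"
    tau: float = 20.0
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sustained", "peak"):
            raise ValueError(f"unknown event shape {self.shape!r}")


@dataclass
class SyntheticAssayConfig:
    dt: float = 1.0
    duration: float = 600.0
    baseline: float = 5.0
    events: list[SimEvent] = field(default_factory=list)
    doses: list[float] | None = None  # µM, strictly increasing
    four_pl: tuple[float, float, float, float] | None = None  # floor, ceiling, IC50, slope
    agonist_amplitude: float = 40.0
    agonist_time: float = 120.0
    dose_interval: float = 180.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doses is not None:
            d = np.asarray(self.doses, dtype=float)
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise ValueError("doses must be strictly positive and increasing")
            if self.four_pl is None:
                raise ValueError("dose runs need true 4PL parameters")
            floor, ceiling, ic50, slope = self.four_pl
            if ic50 <= 0:
                raise ValueError("IC50 must be positive")
            if floor > ceiling:
                raise ValueError("4PL floor must not exceed ceiling")
        for ev in self.events:
            if not 0 <= ev.time <= self.duration:
                raise ValueError(f"event {ev.agent!r} outside trace duration")


def _four_pl(dose, floor, ceiling, ic50, slope):
    return floor + (ceiling - floor) / (
        1.0 + 10.0 ** (slope * (np.log10(ic50) - np.log10(dose)))
    )


def gen_isc_trace(
    config: SyntheticAssayConfig,
) -> tuple[AssayTrace, SyntheticTruth]:
    """Simulate an Isc trace with shaped agonist/inhibitor responses.

    Sustained events rise exponentially to a plateau equal to their
    amplitude; peak events follow an alpha function that attains the
    amplitude at ``tau`` seconds after the event. For dose-inhibition
    runs (``doses`` set) a sustained combined-agonist response is laid
    down and each cumulative dose rescales the stimulated component to
    the residual fraction prescribed by the true 4PL curve.
    """
    rng = np.random.default_rng(config.seed)
    if config.doses is not None:
        n_doses = len(config.doses)
        duration = config.agonist_time + config.dose_interval * (n_doses + 1)
    else:
        duration = config.duration
    t = np.arange(0.0, duration + config.dt / 2, config.dt)
    y = np.full_like(t, config.baseline)
    events: list[TraceEvent] = []
    truth_events = []

    for ev in config.events:
        rel = t - ev.time
        on = rel >= 0
        if ev.shape == "sustained":
            y[on] += ev.amplitude * (1.0 - np.exp(-rel[on] / ev.tau))
        else:
            x = rel[on] / ev.tau
            y[on] += ev.amplitude * x * np.exp(1.0 - x)
        events.append(TraceEvent(ev.time, ev.agent, ev.concentration))
        truth_events.append({
            "agent": ev.agent, "time": ev.time,
            "amplitude": ev.amplitude, "shape": ev.shape,
        })

    truth_data: dict = {"baseline": config.baseline, "events": truth_events}

    if config.doses is not None:
        floor, ceiling, ic50, slope = config.four_pl
        amp = config.agonist_amplitude
        t_ag = config.agonist_time
        rise = (t >= t_ag) * (1.0 - np.exp(-np.maximum(t - t_ag, 0) / 10.0))
        frac = np.ones_like(t)  # residual stimulated fraction after doses
        events.append(TraceEvent(t_ag, "forskolin+carbachol", None))
        dose_truth = []
        for i, dose in enumerate(config.doses):
            t_dose = t_ag + config.dose_interval * (i + 1)
            inhib = float(_four_pl(dose, floor, ceiling, ic50, slope))
            resid = 1.0 - inhib / 100.0
            after = t >= t_dose
            # exponential relaxation from the previous residual level
            prev = frac[after][0] if after.any() else 1.0
            frac[after] = resid + (prev - resid) * np.exp(
                -(t[after] - t_dose) / 15.0
            )
            events.append(TraceEvent(t_dose, "crofelemer", dose))
            dose_truth.append({"dose": dose, "inhibition_pct": inhib})
        y = y + amp * rise * frac
        truth_data.update({
            "four_pl": {"floor": floor, "ceiling": ceiling,
                        "ic50": ic50, "slope": slope},
            "agonist_amplitude": amp,
            "doses": dose_truth,
        })

    if config.noise_sd > 0:
        y = y + rng.normal(0, config.noise_sd, y.shape)
    trace = AssayTrace(time=t, value=y, events=sorted(events, key=lambda e: e.time),
                       units="uA/cm2")
    return trace, SyntheticTruth("isc_trace", truth_data)


def crofelemer_dose_config(seed: int = 0) -> SyntheticAssayConfig:
    """Default crofelemer dose-inhibition run.

    True 4PL: floor 0%, ceiling (maximal inhibition) 80%, IC50 30 µM,
    Hill slope 1 — the dose–response reported for combined
    forskolin/carbachol-stimulated current in MVID enteroid monolayers.
    Six half-log doses bracket the IC50; trace noise is 5% of the
    stimulated amplitude.
    """
    amp = 40.0
    return SyntheticAssayConfig(
        doses=[1.0, 3.0, 10.0, 30.0, 100.0, 300.0],
        four_pl=(0.0, 80.0, 30.0, 1.0),
        agonist_amplitude=amp,
        noise_sd=0.05 * amp,
        seed=seed,
    )


def sglt1_config(condition: str = "control", seed: int = 0) -> SyntheticAssayConfig:
    """Glucose/phlorizin protocol for SGLT1 current measurement.

    Glucose (20 mM) evokes a sustained current whose phlorizin-sensitive
    component is the SGLT1 readout; phlorizin then removes exactly that
    component. The MVID default plants a 60% reduction of the sensitive
    component versus control (10 → 4 µA/cm²), the deficit reported in
    MVID monolayers; a small phlorizin-insensitive component is common
    to both.
    """
    if condition not in ("control", "mvid"):
        raise ValueError("condition must be 'control' or 'mvid'")
    sensitive = 10.0 if condition == "control" else 4.0
    insensitive = 2.0
    events = [
        SimEvent(120.0, "glucose", sensitive + insensitive, "sustained", tau=15.0,
                 concentration=20000.0),
        SimEvent(420.0, "phlorizin", -sensitive, "sustained", tau=15.0,
                 concentration=200.0),
    ]
    cfg = SyntheticAssayConfig(
        duration=720.0, baseline=2.0, events=events, noise_sd=0.3, seed=seed
    )
    return cfg


# ---------------------------------------------------------------------------
# pH trace generator


@dataclass
class SyntheticPhConfig:
    dt: float = 2.0
    clamp_ph: tuple[float, ...] = (6.0, 7.0, 8.0)
    clamp_duration: float = 120.0
    signal_slope: float = 0.25   # signal units per pH unit
    signal_intercept: float = -1.2
    start_ph: float = 6.6        # acidified, Na⁺-free starting point
    na_free_duration: float = 120.0
    recovery_window: float = 300.0
    delta_ph: float = 0.5        # true recovery magnitude, pH units
    rate_k: float = 0.02         # 1/s, exponential recovery rate
    inhibitor: bool = False
    inhibitor_scale: float = 0.1
    noise_sd: float = 0.005      # on the signal
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.clamp_ph)) != len(self.clamp_ph):
            raise ValueError("clamp pH values must be distinct")
        if self.delta_ph < 0:
            raise ValueError("recovery magnitude must be non-negative")


def gen_ph_trace(config: SyntheticPhConfig) -> tuple[AssayTrace, SyntheticTruth]:
    """Simulate a SNARF-like trace: Na⁺-free plateau, recovery, clamps.

    The pH course is an acidified plateau, an exponential alkalinization
    of magnitude ``delta_ph`` (scaled down under the inhibitor flag)
    after Na⁺ re-addition, then one clamp segment per calibration pH.
    The recorded signal is an affine map of pH plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    dph = config.delta_ph * (config.inhibitor_scale if config.inhibitor else 1.0)
    t_re = config.na_free_duration
    t_cal = t_re + config.recovery_window
    total = t_cal + config.clamp_duration * len(config.clamp_ph)
    t = np.arange(0.0, total + config.dt / 2, config.dt)
    ph = np.full_like(t, config.start_ph)
    rec = (t >= t_re) & (t < t_cal)
    ph[rec] = config.start_ph + dph * (1.0 - np.exp(-config.rate_k * (t[rec] - t_re)))
    events = [
        TraceEvent(0.0, "na_free"),
        TraceEvent(t_re, "na_readdition"),
    ]
    for i, cph in enumerate(config.clamp_ph):
        seg = (t >= t_cal + i * config.clamp_duration) & (
            t < t_cal + (i + 1) * config.clamp_duration
        )
        ph[seg] = cph
        events.append(TraceEvent(t_cal + i * config.clamp_duration, f"clamp_{cph:g}"))
    # last sample may fall exactly on the final boundary
    ph[t >= t_cal + len(config.clamp_ph) * config.clamp_duration] = config.clamp_ph[-1]

    signal = config.signal_slope * ph + config.signal_intercept
    if config.noise_sd > 0:
        signal = signal + rng.normal(0, config.noise_sd, signal.shape)
    trace = AssayTrace(time=t, value=signal, events=events, units="ratio")
    truth = SyntheticTruth("ph_trace", {
        "delta_ph": float(dph),
        "nominal_delta_ph": config.delta_ph,
        "initial_rate": float(dph * config.rate_k),
        "readdition_time": t_re,
        "recovery_window": config.recovery_window,
        "calibration_start": t_cal,
        "clamp_duration": config.clamp_duration,
        "clamp_ph": list(config.clamp_ph),
        "signal_slope": config.signal_slope,
        "signal_intercept": config.signal_intercept,
        "inhibitor": config.inhibitor,
    })
    return trace, truth


def nhe_config(condition: str = "healthy", inhibitor: bool = False,
               seed: int = 0) -> SyntheticPhConfig:
    """NHE-activity defaults: robust recovery (ΔpH 0.5) in healthy cells,
    near-complete loss (ΔpH 0.05) in MVID cells; the inhibitor flag
    scales recovery to 10% (NHE-independent residual)."""
    if condition not in ("healthy", "mvid"):
        raise ValueError("condition must be 'healthy' or 'mvid'")
    return SyntheticPhConfig(
        delta_ph=0.5 if condition == "healthy" else 0.05,
        inhibitor=inhibitor,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# swelling series generator


@dataclass
class SyntheticSwellingConfig:
    shape: tuple[int, int] = (512, 512)
    n_objects: int = 20
    radius_range: tuple[float, float] = (10.0, 16.0)
    times: tuple[float, ...] = (0.0, 1.0)  # hours
    diameter_growth: tuple[float, ...] = (1.4,)  # per timepoint after t0
    growth_jitter_sd: float = 0.0   # sd of per-object multiplicative jitter
    margin: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.diameter_growth) != len(self.times) - 1:
            raise ValueError("need one growth factor per post-t0 timepoint")
        if any(g <= 0 for g in self.diameter_growth):
            raise ValueError("growth factors must be positive")


def gen_swelling_series(
    config: SyntheticSwellingConfig,
) -> tuple[list[np.ndarray], SyntheticTruth]:
    """Simulate per-timepoint label masks of swelling disks.

    Disks are placed without overlap (accounting for their final size);
    at each later timepoint every disk's radius is its initial radius
    times the cumulative diameter growth factor (optionally jittered
    per object). Objects are labeled in placement order in every frame.
    Placement failure after bounded retries, or a disk crossing the
    image bounds, raises an error.
    """
    rng = np.random.default_rng(config.seed)
    max_growth = max(float(np.prod(config.diameter_growth[: k + 1]))
                     for k in range(len(config.diameter_growth)))
    max_growth = max(max_growth, 1.0)
    jitter = (
        rng.normal(0.0, config.growth_jitter_sd, config.n_objects)
        if config.growth_jitter_sd > 0 else np.zeros(config.n_objects)
    )
    radii = rng.uniform(*config.radius_range, config.n_objects)
    max_radius = radii.max() * max_growth * (1 + max(0.0, jitter.max()))
    min_sep = 2 * radii.max() * max_growth * (1 + abs(jitter).max()) + config.margin
    centers = _place_points(
        rng, config.n_objects, config.shape, min_sep,
        margin=max_radius + config.margin,
    )
    if (centers[:, 0] - max_radius < 0).any() or (
        centers[:, 0] + max_radius >= config.shape[0]
    ).any() or (centers[:, 1] - max_radius < 0).any() or (
        centers[:, 1] + max_radius >= config.shape[1]
    ).any():
        raise RuntimeError("disk placement overflows image bounds")

    rr_grid, cc_grid = np.mgrid[0: config.shape[0], 0: config.shape[1]]
    frames: list[np.ndarray] = []
    growth_per_object = []
    for k, _t in enumerate(config.times):
        cum = 1.0 if k == 0 else float(np.prod(config.diameter_growth[:k]))
        labels = np.zeros(config.shape, dtype=np.int32)
        for i, ((r, c), rad0) in enumerate(zip(centers, radii)):
            g = cum * (1.0 + jitter[i]) if k > 0 else 1.0
            rad = rad0 * g
            labels[(rr_grid - r) ** 2 + (cc_grid - c) ** 2 <= rad ** 2] = i + 1
        frames.append(labels)
    for i in range(config.n_objects):
        growth_per_object.append([
            float(np.prod(config.diameter_growth[:k]) * (1.0 + jitter[i]))
            for k in range(1, len(config.times))
        ])
    truth = SyntheticTruth("swelling_series", {
        "times": list(config.times),
        "centers": centers.tolist(),
        "initial_radii": radii.tolist(),
        "diameter_growth": [list(g) for g in growth_per_object],
        "nominal_diameter_growth": list(config.diameter_growth),
    })
    return frames, truth


# crofelemer inhibition of forskolin-induced swelling at 1 h, by condition:
# the reported percentages (healthy 40%, MVID 50%) applied to the swelling
# increment of the chosen agonist-only growth.
_SWELL_DEFAULTS = {
    ("healthy", "agonist"): 1.4,
    ("healthy", "agonist+crofelemer"): 1.0 + 0.4 * (1.0 - 0.40),
    ("mvid", "agonist"): 1.3,
    ("mvid", "agonist+crofelemer"): 1.0 + 0.3 * (1.0 - 0.50),
}


def swelling_config(condition: str = "healthy", arm: str = "agonist",
                    seed: int = 0) -> SyntheticSwellingConfig:
    """Default forskolin ± crofelemer swelling arms per condition."""
    key = (condition, arm)
    if key not in _SWELL_DEFAULTS:
        raise ValueError(
            f"unknown condition/arm {key}; conditions: healthy|mvid, "
            "arms: agonist|agonist+crofelemer"
        )
    return SyntheticSwellingConfig(
        diameter_growth=(_SWELL_DEFAULTS[key],), seed=seed
    )


# ---------------------------------------------------------------------------
# DE table generator


@dataclass
class SyntheticDeConfig:
    n_genes: int = 2000
    n_rescue: int = 50
    rescue_lfc_mean: float = 2.0
    rescue_lfc_sd: float = 0.4
    rescue_lfc_min: float = 1.2   # keeps planted genes past |lfc| >= 1
    null_lfc_sd: float = 0.3
    rescue_basemean_min: float = 50.0
    basemean_mu: float = 4.0      # lognormal parameters for base mean
    basemean_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rescue > self.n_genes:
            raise ValueError("cannot plant more rescue genes than genes")


def gen_de_tables(
    config: SyntheticDeConfig,
) -> tuple[dict[str, "object"], SyntheticTruth]:
    """Generate three DE contrast tables with planted rescue genes.

    Planted genes get a significant baseline effect (random sign) and a
    significant treatment effect of the opposite sign, with adjusted p
    drawn log-uniformly well below 0.05 and base mean above the default
    prioritization floor. Null genes draw adjusted p uniformly on [0, 1]
    independently per contrast, so they satisfy the rescue predicate
    only at the nominal false rate. Returns contrasts keyed
    ``baseline`` (disease vs healthy), ``treatment`` (disease+drug vs
    disease), and ``healthy_drug`` (healthy+drug vs healthy).
    """
    from .rescue import DeContrastTable

    rng = np.random.default_rng(config.seed)
    n, k = config.n_genes, config.n_rescue
    genes = np.array([f"G{i:05d}" for i in range(n)])
    planted_idx = rng.choice(n, size=k, replace=False) if k else np.array([], int)
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted_idx] = True

    basemean = rng.lognormal(config.basemean_mu, config.basemean_sigma, n)
    basemean[is_planted] = np.maximum(basemean[is_planted],
                                      config.rescue_basemean_min)

    def null_lfc(size):
        return rng.normal(0.0, config.null_lfc_sd, size)

    def planted_mag(size):
        mag = rng.normal(config.rescue_lfc_mean, config.rescue_lfc_sd, size)
        return np.maximum(mag, config.rescue_lfc_min)

    sign = rng.choice([-1.0, 1.0], size=k)

    tables = {}
    truth_signs = {}
    for contrast in ("baseline", "treatment", "healthy_drug"):
        lfc = null_lfc(n)
        padj = rng.uniform(0.0, 1.0, n)
        if contrast == "baseline" and k:
            lfc[planted_idx] = sign * planted_mag(k)
            padj[planted_idx] = 10.0 ** rng.uniform(-6.0, -2.0, k)
        elif contrast == "treatment" and k:
            lfc[planted_idx] = -sign * planted_mag(k)
            padj[planted_idx] = 10.0 ** rng.uniform(-6.0, -2.0, k)
        tables[contrast] = DeContrastTable(
            name=contrast,
            table=pd.DataFrame({
                "gene": genes,
                "log2fc": lfc,
                "padj": padj,
                # contrasts see slightly different normalized means
                "basemean": basemean * rng.lognormal(0.0, 0.05, n),
            }),
        )
        if contrast in ("baseline", "treatment"):
            truth_signs[contrast] = lfc[planted_idx].tolist()

    truth = SyntheticTruth("de_tables", {
        "rescue_genes": sorted(genes[planted_idx].tolist()),
        "n_genes": n,
        "baseline_lfc": truth_signs.get("baseline", []),
        "treatment_lfc": truth_signs.get("treatment", []),
    })
    return tables, truth
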