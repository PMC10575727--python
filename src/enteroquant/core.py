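"""Core data containers shared across the pipeline.

Two kinds of raw measurement flow through ``enteroquant``: multichannel
2D fluorescence images (one intensity grid per antigen, assumed
background-corrected upstream) and timestamped scalar assay traces
(short-circuit current in µA/cm², or pH-probe fluorescence in arbitrary
units) annotated with intervention events such as agonist or inhibitor
additions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultichannelImage", "TraceEvent", "AssayTrace"]


@dataclass
class MultichannelImage:
    """Named-channel 2D intensity image with an optional tissue mask.

    Parameters
    ----------
    channels
        Mapping from channel name (antigen) to a 2D non-negative float
        array. All channels must share one shape.
    mask
        Optional boolean array of the same shape restricting analysis to
        tissue pixels.
    pixel_size
        Physical pixel edge length in µm/px, if known.
    """

    channels: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultichannelImage needs at least one channel")
        shapes = {name: np.asarray(grid).shape for name, grid in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError("channels must be 2D arrays")
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree in shape: {shapes}")
        self.channels = {
            name: np.asarray(grid, dtype=float) for name, grid in self.channels.items()
        }
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != first:
                raise ValueError("mask shape must match channel shape")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass(frozen=True)
class TraceEvent:
    """An intervention applied during an assay (agonist, inhibitor, buffer switch)."""

    time: float
    agent: str
    concentration: float | None = None  # µM where applicable


@dataclass
class AssayTrace:
    """Timestamped scalar series with annotated intervention events.

    ``value`` carries µA/cm² for short-circuit current traces and
    arbitrary fluorescence units (or pH after calibration) for probe
    traces.
    """

    time: np.ndarray
    value: np.ndarray
    events: list[TraceEvent] = field(default_factory=list)
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.value.shape:
            raise ValueError("time and value must be 1D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for ev in self.events:
            if not (self.time[0] <= ev.time <= self.time[-1]):
                raise ValueError(f"event {ev.agent!r} at t={ev.time} outside trace range")

    def event(self, agent: str) -> TraceEvent:
        """Return the first event whose agent label matches ``agent``."""
        for ev in self.events:
            if ev.agent == agent:
                return ev
        raise KeyError(f"no event with agent {agent!r}")

    def events_for(self, agent: str) -> list[TraceEvent]:
        return [ev for ev in self.events if ev.agent == agent]

    def window(self, start: float, stop: float) -> np.ndarray:
        """Values sampled in the half-open time interval [start, stop)."""
        sel = (self.time >= start) & (self.time < stop)
        return self.value[sel]
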