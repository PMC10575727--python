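"""Forskolin-induced enteroid swelling quantification.

Enteroids secrete fluid into their closed lumen when stimulated (e.g.
by forskolin raising cAMP), so cross-sectional area grows over time.
Objects are segmented per frame, matched across frames by nearest
centroid, and swelling is expressed as the ratio of the equivalent
circular diameter at time t to that at t₀. Inhibitor efficacy (e.g.
crofelemer) is the percent reduction of the swelling increment
(ratio − 1) relative to the agonist-only arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "EnteroidTrack",
    "SwellingSummary",
    "segment_enteroids",
    "track_objects",
    "diameter_ratio",
    "swelling_inhibition",
    "summarize_swelling",
]


@dataclass
class EnteroidTrack:
    """One enteroid followed over timepoints."""

    track_id: int
    times: list[float]
    centroids: list[tuple[float, float]]
    areas: list[float]  # px²
    condition: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.areas):
            raise ValueError("areas must be positive")
        if len(self.times) >= 2 and any(np.diff(self.times) <= 0):
            raise ValueError("timepoints must be increasing")

    @property
    def diameters(self) -> np.ndarray:
        """Equivalent circular diameter 2·√(area/π) per timepoint."""
        return 2.0 * np.sqrt(np.asarray(self.areas) / np.pi)

    def has_time(self, t: float) -> bool:
        return any(np.isclose(t, ti) for ti in self.times)


@dataclass
class SwellingSummary:
    """Distribution of diameter ratios at one timepoint."""

    time: float
    ratios: np.ndarray
    median: float
    iqr: tuple[float, float]
    mean: float


def segment_enteroids(
    frame: np.ndarray,
    threshold: float | None = None,
    min_area: float = 50.0,
    min_circularity: float = 0.6,
) -> np.ndarray:
    """Label enteroid objects in one frame.

    Accepts either an integer label mask (used as-is after filtering) or
    an intensity image, which is thresholded (Otsu unless ``threshold``
    is given), hole-filled and connected-component labeled. Objects
    smaller than ``min_area`` px² or with circularity 4πA/P² below
    ``min_circularity`` (lumen-collapsed, irregular debris) are dropped.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    # integer/bool input is taken as a (label) mask; float input is an image
    if frame.dtype == bool or np.issubdtype(frame.dtype, np.integer):
        binary = frame > 0
    else:
        if threshold is None:
            from skimage.filters import threshold_otsu

            if np.ptp(frame) == 0:
                warnings.warn("constant frame: no objects")
                return np.zeros(frame.shape, dtype=np.int32)
            threshold = float(threshold_otsu(frame.astype(float)))
        binary = frame.astype(float) > threshold
    binary = binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        circ = 4.0 * np.pi * prop.area / prop.perimeter ** 2 if prop.perimeter > 0 else 1.0
        if circ < min_circularity:
            continue
        out[labels == prop.label] = next_id
        next_id += 1
    if next_id == 1:
        warnings.warn("no enteroid objects found in frame")
    return out


def track_objects(
    labeled_frames: list[np.ndarray],
    times: list[float] | None = None,
    max_displacement: float = 20.0,
    condition: dict[str, object] | None = None,
) -> list[EnteroidTrack]:
    """Match objects across frames by nearest centroid.

    Greedy nearest-centroid assignment with a displacement gate:
    an object moving farther than ``max_displacement`` px between
    consecutive frames ends its track and a new track is opened.
    Only tracks present in the first frame carry a t₀ reference and are
    eligible for diameter ratios.
    """
    if len(labeled_frames) < 2:
        raise ValueError("need at least two frames to track")
    if times is None:
        times = list(range(len(labeled_frames)))
    if len(times) != len(labeled_frames):
        raise ValueError("times must align with frames")

    def frame_objects(labels: np.ndarray) -> list[tuple[tuple[float, float], float]]:
        return [
            (tuple(p.centroid), float(p.area)) for p in regionprops(labels)
        ]

    tracks: list[EnteroidTrack] = []
    next_id = 0
    prev_assign: dict[int, int] = {}  # index in prev frame objects -> track index
    prev_objs = frame_objects(labeled_frames[0])
    for j, (cen, area) in enumerate(prev_objs):
        tracks.append(EnteroidTrack(next_id, [times[0]], [cen], [area],
                                    dict(condition or {})))
        prev_assign[j] = next_id
        next_id += 1

    for fi in range(1, len(labeled_frames)):
        objs = frame_objects(labeled_frames[fi])
        new_assign: dict[int, int] = {}
        used_prev: set[int] = set()
        # greedy: closest pairs first
        pairs = sorted(
            (
                (np.hypot(c[0] - pc[0], c[1] - pc[1]), j, pj)
                for j, (c, _) in enumerate(objs)
                for pj, (pc, _) in enumerate(prev_objs)
            ),
        )
        for dist, j, pj in pairs:
            if dist > max_displacement:
                break
            if j in new_assign or pj in used_prev:
                continue
            tid = prev_assign[pj]
            tracks[tid].times.append(times[fi])
            tracks[tid].centroids.append(objs[j][0])
            tracks[tid].areas.append(objs[j][1])
            new_assign[j] = tid
            used_prev.add(pj)
        for j, (cen, area) in enumerate(objs):
            if j not in new_assign:
                tracks.append(EnteroidTrack(next_id, [times[fi]], [cen], [area],
                                            dict(condition or {})))
                new_assign[j] = next_id
                next_id += 1
        prev_objs = objs
        prev_assign = new_assign
    return tracks


def diameter_ratio(track: EnteroidTrack, t: float) -> float:
    """Equivalent diameter at ``t`` over the diameter at the track's t₀."""
    times = np.asarray(track.times)
    it = np.flatnonzero(np.isclose(times, t))
    if it.size == 0:
        raise ValueError(f"track {track.track_id} has no timepoint {t}")
    d = track.diameters
    return float(d[it[0]] / d[0])


def summarize_swelling(tracks: list[EnteroidTrack], t: float) -> SwellingSummary:
    """Diameter-ratio distribution over all tracks spanning t₀ and ``t``."""
    ratios = np.array([
        diameter_ratio(tr, t) for tr in tracks if tr.has_time(t) and len(tr.times) > 1
    ])
    if ratios.size == 0:
        raise ValueError(f"no tracks span t0 and t={t}")
    q1, q3 = np.percentile(ratios, [25, 75])
    return SwellingSummary(
        time=t, ratios=ratios, median=float(np.median(ratios)),
        iqr=(float(q1), float(q3)), mean=float(ratios.mean()),
    )


def swelling_inhibition(
    ratios_agonist: np.ndarray, ratios_inhibited: np.ndarray
) -> float:
    """Percent inhibition of swelling by an inhibitor-treated arm.

    Defined on the swelling increment: 100 × (R̄_ag − R̄_ag+inh) /
    (R̄_ag − 1) with group means R̄. Undefined (error) when the agonist
    arm does not swell (R̄_ag ≤ 1).
    """
    ra = np.asarray(ratios_agonist, dtype=float)
    ri = np.asarray(ratios_inhibited, dtype=float)
    if ra.size == 0 or ri.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_ag = ra.mean()
    if mean_ag <= 1.0:
        raise ValueError(
            f"agonist arm shows no swelling (mean ratio {mean_ag:.3f} <= 1); "
            "percent inhibition undefined"
        )
    return float(100.0 * (mean_ag - ri.mean()) / (mean_ag - 1.0))
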