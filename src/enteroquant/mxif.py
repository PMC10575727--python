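"""Multiplex-immunofluorescence quantification.

Three analyses operate on background-corrected multichannel images of
intestinal tissue:

* **Prominence-based counting** — nuclei and marker-positive cells are
  counted as regional intensity maxima whose topographic prominence
  exceeds a channel-specific threshold (h-maxima semantics). Secretory
  cell abundance is reported as marker maxima per nucleus.
* **Brush-border continuity** — the brush-border channel (CD10) is
  thresholded, skeletonized, and spur-pruned; the maximum Feret caliper
  of each skeleton fragment measures how long an uninterrupted stretch
  of apical membrane staining is.
* **Channel cross-correlation** — pairwise Pearson correlation of pixel
  intensities between antigens, optionally hierarchically clustered,
  summarises co-localization across the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .core import MultichannelImage

__all__ = [
    "MaximaResult",
    "SkeletonSet",
    "FeretSummary",
    "ChannelCorrelationMatrix",
    "normalize_histogram",
    "find_maxima",
    "cell_type_fractions",
    "skeletonize_marker",
    "feret_distances",
    "channel_cross_correlation",
    "cluster_correlation",
]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MaximaResult:
    """Prominent regional maxima found in one channel."""

    channel: str
    prominence: float
    coordinates: np.ndarray  # (n, 2) int array of (row, col)
    prominences: np.ndarray  # per-maximum topographic prominence
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)
        self.prominences = np.asarray(self.prominences, dtype=float)
        self.count = len(self.coordinates)


@dataclass
class SkeletonSet:
    """Connected one-pixel-wide curve components from a binarized channel."""

    components: list[np.ndarray]  # each (n, 2) int array of (row, col)
    channel: str = ""
    threshold: float | None = None
    min_branch_length: int = 10

    def __len__(self) -> int:
        return len(self.components)

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for comp in self.components:
            out[comp[:, 0], comp[:, 1]] = True
        return out


@dataclass
class FeretSummary:
    """Per-fragment maximum caliper (Feret) distances with summaries."""

    calipers_px: np.ndarray
    mean_px: float
    median_px: float
    count: int
    calipers_um: np.ndarray | None = None
    mean_um: float | None = None


@dataclass
class ChannelCorrelationMatrix:
    """Symmetric Pearson correlation matrix over channels.

    ``matrix`` is a square :class:`pandas.DataFrame` indexed by channel
    name. ``order`` and ``linkage`` are populated by
    :func:`cluster_correlation`.
    """

    matrix: pd.DataFrame
    order: list[str] | None = None
    linkage: np.ndarray | None = None

    @property
    def channel_names(self) -> list[str]:
        return list(self.matrix.index)


# ---------------------------------------------------------------------------
# histogram normalization


def normalize_histogram(
    grid: np.ndarray,
    low_percentile: float = 0.1,
    high_percentile: float = 99.9,
) -> np.ndarray:
    """Percentile contrast-stretch a channel to the [0, 255] range.

    Intensities at or below the low percentile map to 0, at or above the
    high percentile to 255; values in between are mapped linearly, which
    preserves their rank order. A constant image cannot be stretched and
    is returned unchanged with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty image")
    lo = np.percentile(grid, low_percentile)
    hi = np.percentile(grid, high_percentile)
    if hi <= lo:
        warnings.warn("constant (or near-constant) image: histogram normalization skipped")
        return grid.copy()
    return np.clip((grid - lo) / (hi - lo), 0.0, 1.0) * 255.0


# ---------------------------------------------------------------------------
# prominence-based maxima counting


def _merge_components(
    values: np.ndarray, mask: np.ndarray
) -> tuple[list[float], list[np.ndarray]]:
    """Flood the image from high to low, recording component prominences.

    Pixels are activated in descending intensity order. Each freshly
    isolated summit starts a component; when two components meet, the
    one with the lower peak dies and its prominence is its peak height
    above the merge level. Survivors (one per connected mask region) get
    peak minus the regional minimum. Returns the prominence of every
    component together with its peak plateau pixels.
    """
    nrow, ncol = values.shape
    flat_vals = values.ravel()
    idx = np.flatnonzero(mask.ravel())
    # stable sort: descending value, then raster order for determinism
    order = idx[np.argsort(-flat_vals[idx], kind="stable")]

    parent = {}
    peak: dict[int, float] = {}
    plateau: dict[int, list[int]] = {}
    comp_min: dict[int, float] = {}

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    proms: list[float] = []
    plateaus: list[np.ndarray] = []
    mask_flat = mask.ravel()
    active = np.zeros(nrow * ncol, dtype=bool)

    for p in order:
        v = flat_vals[p]
        r, c = divmod(int(p), ncol)
        roots = []
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol:
                q = rr * ncol + cc
                if active[q] and mask_flat[q]:
                    rt = find(q)
                    if rt not in roots:
                        roots.append(rt)
        active[p] = True
        if not roots:
            parent[p] = p
            peak[p] = v
            plateau[p] = [int(p)]
            comp_min[p] = v
            continue
        # survivor: highest peak, deterministic tie-break on root id
        surv = max(roots, key=lambda rt: (peak[rt], -rt))
        for rt in roots:
            if rt is surv or rt == surv:
                continue
            if peak[rt] == peak[surv] == v:
                # both components are pieces of one summit plateau joined here
                plateau[surv].extend(plateau[rt])
            else:
                proms.append(peak[rt] - v)
                plateaus.append(np.array(
                    [divmod(i, ncol) for i in plateau[rt]], dtype=int))
            parent[rt] = surv
            comp_min[surv] = min(comp_min[surv], comp_min[rt])
            del peak[rt], plateau[rt], comp_min[rt]
        parent[p] = surv
        if v == peak[surv]:
            plateau[surv].append(int(p))
        comp_min[surv] = min(comp_min[surv], v)

    for rt, pk in peak.items():
        proms.append(pk - comp_min[rt])
        plateaus.append(np.array([divmod(i, ncol) for i in plateau[rt]], dtype=int))
    return proms, plateaus


def _plateau_representative(pix: np.ndarray) -> tuple[int, int]:
    """Plateau pixel nearest the plateau centroid, raster-order tie-break."""
    centroid = pix.mean(axis=0)
    d2 = ((pix - centroid) ** 2).sum(axis=1)
    order = np.lexsort((pix[:, 1], pix[:, 0], d2))
    return int(pix[order[0], 0]), int(pix[order[0], 1])


def find_maxima(
    grid: np.ndarray,
    prominence: float,
    mask: np.ndarray | None = None,
    channel: str = "",
) -> MaximaResult:
    """Count regional maxima that stand out by more than ``prominence``.

    A regional maximum is reported when its intensity exceeds the level
    at which it merges with higher terrain by strictly more than
    ``prominence`` (the classic h-maxima criterion, matching the "Find
    Maxima" prominence parameter used for cell counting). Equal-height
    summits whose connecting saddle is within ``prominence`` of the top
    collapse into a single reported point. Each summit plateau yields
    one representative pixel.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2D")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape must match grid")

    proms, plateaus = _merge_components(grid, mask)
    coords = []
    kept_proms = []
    for prom, pix in zip(proms, plateaus):
        if prom > prominence:
            coords.append(_plateau_representative(pix))
            kept_proms.append(prom)
    if coords:
        order = np.lexsort(([c for _, c in coords], [r for r, _ in coords]))
        coords = [coords[i] for i in order]
        kept_proms = [kept_proms[i] for i in order]
    return MaximaResult(
        channel=channel,
        prominence=float(prominence),
        coordinates=np.array(coords, dtype=int).reshape(-1, 2),
        prominences=np.array(kept_proms, dtype=float),
    )


def cell_type_fractions(
    image: MultichannelImage,
    nuclei_channel: str,
    marker_prominences: dict[str, float],
    nuclei_prominence: float = 15.0,
    normalize_nuclei: bool = True,
) -> dict[str, float]:
    """Marker-positive cells as a fraction of nuclei.

    The nuclei channel is histogram-normalized before counting (so the
    default prominence of 15 applies on the 0–255 scale); each marker
    channel is counted with its own prominence on its native scale. A
    fraction above 1 is physiologically implausible and triggers a
    warning rather than an error.
    """
    nuc = image[nuclei_channel]
    if normalize_nuclei:
        nuc = normalize_histogram(nuc)
    n_nuclei = find_maxima(nuc, nuclei_prominence, image.mask, nuclei_channel).count
    if n_nuclei == 0:
        raise ValueError("no nuclei detected; cannot form cell-type fractions")
    fractions: dict[str, float] = {}
    for marker, prom in marker_prominences.items():
        n = find_maxima(image[marker], prom, image.mask, marker).count
        frac = n / n_nuclei
        if frac > 1:
            warnings.warn(
                f"{marker}: marker count {n} exceeds nuclei count {n_nuclei} "
                f"(fraction {frac:.2f} > 1)"
            )
        fractions[marker] = frac
    return fractions


# ---------------------------------------------------------------------------
# skeletonization and Feret continuity


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    counts = np.zeros(skel.shape, dtype=int)
    for dr, dc in _NEIGHBORS8:
        shifted = np.zeros_like(counts)
        src = skel[
            max(0, -dr): skel.shape[0] - max(0, dr),
            max(0, -dc): skel.shape[1] - max(0, dc),
        ]
        shifted[
            max(0, dr): skel.shape[0] - max(0, -dr),
            max(0, dc): skel.shape[1] - max(0, -dc),
        ] = src
        counts += shifted
    return counts


def _skel_neighbors(skel: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    out = []
    for dr, dc in _NEIGHBORS8:
        rr, cc = r + dr, c + dc
        if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
            out.append((rr, cc))
    return out


def _prune_spurs(skel: np.ndarray, min_length: int, max_passes: int = 100) -> np.ndarray:
    """Remove side branches shorter than ``min_length`` pixels.

    From every endpoint, the branch is traced to the first junction
    pixel (a pixel with three or more skeleton neighbours); if the
    traced path is shorter than the minimum it is deleted. Passes repeat
    until stable because removing a spur can expose a new endpoint.
    """
    skel = skel.copy()
    for _ in range(max_passes):
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        removed_any = False
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            visited = {path[0]}
            cur = path[0]
            spur = None
            while True:
                nbrs = _skel_neighbors(skel, *cur)
                if cur != path[0] and len(nbrs) >= 3:
                    spur = path[:-1]  # exclude the junction pixel
                    break
                nxt = [q for q in nbrs if q not in visited]
                if not nxt:
                    break  # ran the whole component: not a side branch
                cur = nxt[0]
                path.append(cur)
                visited.add(cur)
            if spur is not None and len(spur) < min_length:
                for r, c in spur:
                    skel[r, c] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def skeletonize_marker(
    grid: np.ndarray,
    threshold: float | str = "otsu",
    min_branch_length: int = 10,
    mask: np.ndarray | None = None,
    channel: str = "",
) -> SkeletonSet:
    """Threshold, binarize and skeletonize a marker channel.

    Side branches shorter than ``min_branch_length`` pixels are pruned
    and whole components with fewer pixels than the minimum are
    discarded, suppressing speckle that would otherwise masquerade as
    short brush-border fragments.
    """
    grid = np.asarray(grid, dtype=float)
    sel = grid if mask is None else grid[mask]
    if threshold == "otsu":
        if np.ptp(sel) == 0:
            raise ValueError("constant image: automatic (Otsu) threshold undefined")
        thr = float(threshold_otsu(sel))
    else:
        thr = float(threshold)
    binary = grid > thr
    if mask is not None:
        binary &= mask
    if not binary.any():
        warnings.warn("empty foreground after thresholding: empty skeleton set")
        return SkeletonSet([], channel, thr, min_branch_length)
    skel = skeletonize(binary)
    skel = _prune_spurs(skel, min_branch_length)
    labels = sk_label(skel, connectivity=2)
    components = []
    for lab in range(1, labels.max() + 1):
        comp = np.argwhere(labels == lab)
        if len(comp) >= max(2, min_branch_length):
            components.append(comp)
    if not components:
        warnings.warn("all skeleton components shorter than the minimum branch length")
    return SkeletonSet(components, channel, thr, min_branch_length)


def _max_caliper(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance between pixel centres."""
    pts = np.asarray(points, dtype=float)
    if len(pts) > 40:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: all-pairs on the raw points is still cheap
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def feret_distances(skeletons: SkeletonSet, pixel_size: float | None = None) -> FeretSummary:
    """Maximum Feret caliper of every skeleton fragment.

    The caliper of a fragment is the largest Euclidean distance between
    any two of its pixel centres; its distribution over fragments is the
    brush-border continuity readout (longer fragments = more continuous
    staining).
    """
    if len(skeletons) == 0:
        raise ValueError(
            "empty skeleton set (see the upstream thresholding warning); "
            "no Feret distances to compute"
        )
    calipers = np.array([_max_caliper(c) for c in skeletons.components])
    um = calipers * pixel_size if pixel_size else None
    return FeretSummary(
        calipers_px=calipers,
        mean_px=float(calipers.mean()),
        median_px=float(np.median(calipers)),
        count=len(calipers),
        calipers_um=um,
        mean_um=float(um.mean()) if um is not None else None,
    )


# ---------------------------------------------------------------------------
# channel cross-correlation


def channel_cross_correlation(
    image: MultichannelImage, mask: np.ndarray | None = None
) -> ChannelCorrelationMatrix:
    """Pairwise Pearson correlation of channel intensities over pixels.

    Uses the tissue mask attached to the image (or the ``mask``
    argument) when present, otherwise all pixels. Channels with zero
    variance have no defined correlation: their off-diagonal entries are
    NaN and a warning is raised.
    """
    names = image.channel_names
    if len(names) < 2:
        raise ValueError("need at least two channels for cross-correlation")
    use_mask = mask if mask is not None else image.mask
    if use_mask is not None:
        if use_mask.sum() < 2:
            raise ValueError("mask selects fewer than two pixels")
        data = np.stack([image[n][use_mask] for n in names])
    else:
        data = np.stack([image[n].ravel() for n in names])
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        bad = [n for n, flag in zip(names, constant) if flag]
        warnings.warn(f"constant channel(s) {bad}: correlation undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return ChannelCorrelationMatrix(pd.DataFrame(corr, index=names, columns=names))


def cluster_correlation(
    matrix: ChannelCorrelationMatrix,
    method: str = "average",
    drop_undefined: bool = False,
) -> ChannelCorrelationMatrix:
    """Hierarchically cluster channels on the distance 1 − r.

    Returns a copy whose rows/columns follow the dendrogram leaf order,
    with the scipy linkage matrix attached. Channels with undefined
    correlations must be dropped explicitly (``drop_undefined=True``).
    """
    df = matrix.matrix
    if df.isna().any().any():
        if not drop_undefined:
            raise ValueError(
                "correlation matrix contains undefined entries; "
                "pass drop_undefined=True to exclude those channels"
            )
        bad = [n for n in df.index if df.loc[n].drop(n).isna().all()]
        df = df.drop(index=bad, columns=bad)
        if len(df) < 2 or df.isna().any().any():
            raise ValueError("too few channels with defined correlations")
    dist = 1.0 - df.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard against float asymmetry
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaves = hierarchy.leaves_list(link)
    order = [df.index[i] for i in leaves]
    return ChannelCorrelationMatrix(
        matrix=df.loc[order, order], order=order, linkage=link
    )
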