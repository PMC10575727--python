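"""Independent brute-force oracles used by the test suite.

Each oracle implements the mathematical definition of a quantity by a
route deliberately different from the package implementation: maxima
prominences by explicit superlevel-set merge simulation, Feret calipers
by pure-Python all-pairs distances, and the rescue filter by a
row-by-row predicate.
"""

from itertools import combinations

import numpy as np
from scipy.ndimage import binary_dilation, label as ndlabel

_S8 = np.ones((3, 3), dtype=int)


def maxima_prominences(img: np.ndarray) -> list[float]:
    """Prominence of every regional-max plateau by level-descent merging.

    Walk the unique intensity levels from high to low; at each level,
    group the regional-max plateaus by the connected component of the
    superlevel set {img >= level} that contains them. Within a
    component, every alive plateau below the component's top value dies
    at this level, as do all but one of the plateaus tied at the top;
    a dying plateau's prominence is its height above the current level.
    Survivors get height above the minimum of their final component.
    """
    img = np.asarray(img, dtype=float)
    plateaus = []  # (value, boolean mask)
    for v in np.unique(img):
        lab, n = ndlabel(img == v, structure=_S8)
        for k in range(1, n + 1):
            m = lab == k
            ring = binary_dilation(m, structure=_S8) & ~m
            if not (img[ring] > v).any():
                plateaus.append((float(v), m))
    alive = [True] * len(plateaus)
    proms: dict[int, float] = {}
    levels = np.unique(img)[::-1]
    for t in levels:
        sup, _ = ndlabel(img >= t, structure=_S8)
        groups: dict[int, list[int]] = {}
        for i, (v, m) in enumerate(plateaus):
            if alive[i] and v >= t:
                comp = int(sup[m][0])
                groups.setdefault(comp, []).append(i)
        for members in groups.values():
            vmax = max(plateaus[i][0] for i in members)
            top = [i for i in members if plateaus[i][0] == vmax]
            for i in members:
                if plateaus[i][0] < vmax or i in top[1:]:
                    proms[i] = plateaus[i][0] - float(t)
                    alive[i] = False
    bottom = levels[-1]
    sup, _ = ndlabel(img >= bottom, structure=_S8)
    for i, (v, m) in enumerate(plateaus):
        if alive[i]:
            comp = int(sup[m][0])
            proms[i] = v - float(img[sup == comp].min())
    return sorted(proms.values())


def count_maxima(img: np.ndarray, prominence: float) -> int:
    return sum(1 for p in maxima_prominences(img) if p > prominence)


def feret_caliper(pixels) -> float:
    """All-pairs maximum distance between pixel centres (pure Python)."""
    pts = [tuple(map(float, p)) for p in pixels]
    if len(pts) == 1:
        return 0.0
    return max(
        ((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) ** 0.5
        for a, b in combinations(pts, 2)
    )


def rescue_predicate_filter(baseline_df, treatment_df, fdr: float) -> set[str]:
    """Row-by-row rescue-gene predicate over the shared gene namespace."""
    base = {r.gene: r for r in baseline_df.itertuples()}
    hits = set()
    for row in treatment_df.itertuples():
        b = base.get(row.gene)
        if b is None:
            continue
        if not (b.padj < fdr and row.padj < fdr):
            continue
        if b.log2fc == 0 or row.log2fc == 0:
            continue
        if (b.log2fc > 0) != (row.log2fc > 0):
            hits.add(row.gene)
    return hits
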