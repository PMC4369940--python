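"""Connected-region analysis: labeling, boundary tracing, and lung removal.

Lungs dominate the air mask on the first slices of an abdominal stack.
They are rejected by a region-count gate plus an area rule: when a slice
has at most ``max_l`` (default 18) 8-connected air regions, the largest
region is removed and the regions recounted, repeatedly, for as long as
the largest region exceeds ``lung_area_min``.  Slices with more regions
are left untouched — many small regions mean the colon has originated and
the lungs are gone.

Boundary extraction follows Moore-Neighbor contour tracing with Jacob's
stopping criterion (terminate when the start pixel is re-entered from the
direction it was first entered).  Parents are outer contours of
8-connected components; children are the contours of the 4-connected
holes inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import as_bool

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = ndimage.generate_binary_structure(2, 1)

# Moore neighborhood in clockwise order starting at west (image rows grow down)
_CLOCKWISE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass
class LabelMap:
    """8-connected components labeled 1..L in raster first-encounter order."""

    labels: np.ndarray
    n_labels: int


@dataclass
class BoundaryTrace:
    """A closed contour: ordered boundary pixels of a region or of a hole."""

    pixels: list[tuple[int, int]]
    is_hole: bool = False
    parent_label: int | None = None


@dataclass
class RegionProps:
    label: int
    area: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    perimeter: float
    euler_number: int
    extent: float
    orientation: float


@dataclass
class LungParams:
    max_l: int = 18
    lung_area_min: int = 2000


def label_components(mask) -> LabelMap:
    """Label 8-connected regions in raster-scan first-encounter order."""
    m = as_bool(mask)
    raw, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return LabelMap(raw, 0)
    # scipy's labels are already raster-ordered for its algorithm, but the
    # ordering is an implementation detail; relabel by first occurrence.
    flat = raw.ravel()
    nz = flat[flat > 0]
    first = {}
    order = []
    for lb in nz:
        if lb not in first:
            first[lb] = len(order) + 1
            order.append(lb)
        if len(order) == n:
            break
    lut = np.zeros(n + 1, dtype=raw.dtype)
    for lb, new in first.items():
        lut[lb] = new
    return LabelMap(lut[raw], n)


def _moore_trace(fg: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Trace the outer contour of the region containing ``start``.

    ``start`` must be the first foreground pixel of the region in raster
    order, so its west and north neighbors are background and the initial
    backtrack direction is west.
    """
    # The walk is a deterministic map on (pixel, backtrack) states, so it
    # terminates exactly when a state repeats — Jacob's criterion (a pixel
    # re-entered from the direction it was first entered).  The artificial
    # initial backtrack (west of the start) may lie on a tail before the
    # contour cycle; the returned trace is the cycle, which is closed.
    seen: dict[tuple, int] = {}
    trace: list[tuple[int, int]] = []
    p, cur_b = start, (start[0], start[1] - 1)
    while (p, cur_b) not in seen:
        seen[(p, cur_b)] = len(trace)
        trace.append(p)
        # scan the Moore neighborhood clockwise starting from the backtrack
        start_dir = _CLOCKWISE.index((cur_b[0] - p[0], cur_b[1] - p[1]))
        nxt = None
        prev = cur_b
        for j in range(1, 9):
            d = _CLOCKWISE[(start_dir + j) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if 0 <= q[0] < fg.shape[0] and 0 <= q[1] < fg.shape[1] and fg[q]:
                nxt = q
                break
            prev = q
        if nxt is None:
            return trace  # isolated pixel
        p, cur_b = nxt, prev
    return trace[seen[(p, cur_b)]:]


def _first_pixel(region: np.ndarray) -> tuple[int, int]:
    idx = int(np.flatnonzero(region.ravel())[0])
    return divmod(idx, region.shape[1])


def trace_boundaries(mask) -> list[BoundaryTrace]:
    """Parent contour per 8-connected component, child contour per hole."""
    m = as_bool(mask)
    lm = label_components(m)
    traces: list[BoundaryTrace] = []
    slices = ndimage.find_objects(lm.labels)
    for lb, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = np.pad(lm.labels[sl] == lb, 1)
        r0, c0 = sl[0].start - 1, sl[1].start - 1
        pix = [(r + r0, c + c0) for r, c in _moore_trace(comp, _first_pixel(comp))]
        traces.append(BoundaryTrace(pix, is_hole=False, parent_label=lb))
        holes = ndimage.binary_fill_holes(comp) & ~comp
        if holes.any():
            hlabels, hn = ndimage.label(holes, structure=_FOUR)
            for hb in range(1, hn + 1):
                hole = hlabels == hb
                hpix = [(r + r0, c + c0) for r, c in _moore_trace(hole, _first_pixel(hole))]
                traces.append(BoundaryTrace(hpix, is_hole=True, parent_label=lb))
    return traces


def region_props(labelmap: LabelMap) -> list[RegionProps]:
    """Shape descriptors of each labeled region (area drives lung removal)."""
    from skimage.measure import regionprops

    out = []
    for rp in regionprops(labelmap.labels):
        out.append(
            RegionProps(
                label=int(rp.label),
                area=int(rp.area),
                bbox=tuple(rp.bbox),
                centroid=tuple(rp.centroid),
                perimeter=float(rp.perimeter),
                euler_number=int(rp.euler_number),
                extent=float(rp.extent),
                orientation=float(rp.orientation),
            )
        )
    return out


def remove_lungs(mask, labelmap: LabelMap | None = None, params: LungParams | None = None) -> np.ndarray:
    """Remove lung-sized components from the air mask of one slice.

    If the slice has more than ``params.max_l`` connected regions it is
    returned unchanged.  Otherwise the largest component is removed and the
    components recounted, iterating while the largest area exceeds
    ``params.lung_area_min``.  Anti-extensive.
    """
    m = as_bool(mask)
    params = params or LungParams()
    if labelmap is None:
        labelmap = label_components(m)
    if labelmap.n_labels == 0 or labelmap.n_labels > params.max_l:
        return m.copy()
    out = m.copy()
    while True:
        labels, n = ndimage.label(out, structure=_EIGHT)
        if n == 0:
            return out
        areas = np.bincount(labels.ravel())[1:]
        biggest = int(np.argmax(areas)) + 1
        if areas[biggest - 1] <= params.lung_area_min:
            return out
        out[labels == biggest] = False
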