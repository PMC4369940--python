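"""Colon assembly: morphology, mask combination, cleanup, and the pipeline.

Per-slice flow:

1.  Otsu air extraction -> IS; external air cleared.
2.  Connected-region lung removal -> OI (the original segmented output).
3.  Morphological opening with a disk of radius 2 -> I_mo.
4.  Branch A: Otsu binarization of the slice restricted to I_mo -> D1.
    Branch B: trained cascade network over windows of the slice -> D0.
5-7. OutF = D0 AND D1 (background removal).
8.  Block-wise tiny-hole removal (8x8 blocks, area threshold 10) on slices
    that contained lungs; otherwise
9.  border rows 1-40 and 400-512 (1-based) are cleared; AND with OI -> OutF1.
10. SLDR: segments of the current slice whose XOR fraction against the
    previous final exceeds a threshold are bowels and are removed; a second
    block pass with threshold 35 strips non-colon boundary remnants; the
    extracted fluid/partial-volume region is concatenated and holes filled.

The SLDR reference is the previous slice's *final* mask, so continuity
propagates causally forward; the first slice has no predecessor and passes
through unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume_io import CTVolume, as_bool
from .presegment import otsu_threshold, extract_air, remove_external_air
from .region_analysis import LabelMap, LungParams, label_components, remove_lungs
from .pve_classifier import CascadeNet, detect_pve, extract_fluid

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class PipelineConfig:
    """All tunable parameters of the per-slice pipeline."""

    window: int = 8
    disk_radius: int = 2
    hole_threshold_1: int = 10
    hole_threshold_2: int = 35
    block: int = 8
    sldr_threshold: float = 0.5
    otsu_bins: int = 65536
    lung_params: LungParams = field(default_factory=LungParams)
    strip_top: tuple[int, int] = (1, 40)      # 1-based inclusive row spans
    strip_bottom: tuple[int, int] = (400, 512)
    strict_hole_threshold: bool = True


@dataclass
class SldrDecision:
    """Per-segment outcome of the slice-difference removal step."""

    segment_label: int
    xor_fraction: float
    removed: bool


@dataclass
class SliceState:
    """Every intermediate mask of one slice, for audit."""

    index: int
    IS: np.ndarray
    OI: np.ndarray
    I_mo: np.ndarray
    D0: np.ndarray
    D1: np.ndarray
    OutF: np.ndarray
    OutF1: np.ndarray
    fluid: np.ndarray
    final: np.ndarray
    otsu_threshold: float
    had_lungs: bool
    sldr_decisions: list[SldrDecision]


def morphological_open(mask, radius: int = 2) -> np.ndarray:
    """Binary opening (erosion then dilation) with a flat disk element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndimage.binary_opening(as_bool(mask), structure=disk(radius))


def binarize_opened(i_mo, slice_: np.ndarray, radius: int = 2, n_bins: int = 65536) -> np.ndarray:
    """D1: Otsu binarization of the morphologically opened slice.

    The opening is applied to the grayscale slice (erosion then dilation of
    intensities with the flat disk), the opened image is re-thresholded by
    Otsu, and D1 is its dark (air) class.  ``i_mo`` gates the degenerate
    case: when no interior air survived the binary opening the slice has
    nothing to binarize and D1 is empty.
    """
    m = as_bool(i_mo)
    if not m.any():
        return np.zeros_like(m)
    g = ndimage.grey_opening(np.asarray(slice_), footprint=disk(radius))
    res = otsu_threshold(g, n_bins=n_bins)
    return g < res.threshold


def combine(d0, d1) -> np.ndarray:
    """OutF: pixelwise conjunction of the two branches."""
    a, b = as_bool(d0), as_bool(d1)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a & b


def remove_tiny_holes(mask, block: int = 8, area_threshold: int = 10, strict: bool = True) -> np.ndarray:
    """Block-wise small-dot removal.

    The mask is divided into ``block x block`` blocks scanned left-to-right,
    top-to-bottom; the foreground of any block whose foreground area falls
    below ``area_threshold`` (strictly, by default) is cleared.  Blocks clip
    at image edges when the dimensions are not divisible.  Anti-extensive.
    """
    m = as_bool(mask)
    if area_threshold < 0:
        raise ValueError("area_threshold must be >= 0")
    rows, cols = m.shape
    if block > rows or block > cols:
        raise ValueError(f"block {block} larger than mask {m.shape}")
    out = m.copy()
    r_edges = np.arange(0, rows, block)
    c_edges = np.arange(0, cols, block)
    sums = np.add.reduceat(np.add.reduceat(m.astype(np.int64), r_edges, axis=0), c_edges, axis=1)
    small = sums < area_threshold if strict else sums <= area_threshold
    for i in np.flatnonzero(small.any(axis=1)):
        r0 = r_edges[i]
        for j in np.flatnonzero(small[i]):
            c0 = c_edges[j]
            out[r0:r0 + block, c0:c0 + block] = False
    return out


def remove_small_segments(mask, min_area: int = 35, strict: bool = True) -> np.ndarray:
    """Remove 8-connected segments with area below ``min_area``.

    The post-SLDR cleanup: bowel and noise remnants are small free-standing
    fragments, while true colon segments are large, so the area test is
    applied to whole segments rather than to block-local foreground (which
    would nibble the boundary blocks of genuine segments).  Anti-extensive.
    """
    m = as_bool(mask)
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return m.copy()
    areas = np.bincount(labels.ravel())
    small = areas < min_area if strict else areas <= min_area
    small[0] = False
    out = m.copy()
    out[small[labels]] = False
    return out


def block_grid(shape: tuple[int, int], block: int = 8) -> tuple[int, int, int]:
    """(grid rows, grid cols, pixels per full block) of the block partition."""
    rows, cols = shape
    return (-(-rows // block), -(-cols // block), block * block)


def strip_border_rows(mask, top: tuple[int, int] = (1, 40), bottom: tuple[int, int] = (400, 512)) -> np.ndarray:
    """Clear the 1-based inclusive row spans ``top`` and ``bottom``."""
    m = as_bool(mask)
    out = m.copy()
    rows = m.shape[0]
    t0, t1 = top
    b0, b1 = bottom
    out[max(t0 - 1, 0):min(t1, rows)] = False
    out[max(b0 - 1, 0):min(b1, rows)] = False
    return out


def and_with_initial(mask, is_mask) -> np.ndarray:
    """OutF1: conjunction with the lung-removed initial segmentation (OI)."""
    return combine(mask, is_mask)


def sldr(
    prev_final: np.ndarray | None,
    current,
    overlap_threshold: float = 0.5,
) -> tuple[np.ndarray, list[SldrDecision]]:
    """Slice-difference removal of bowels.

    XOR of the previous final mask and the current mask is zero over colon
    (the areas persist) and high over bowels (they do not).  Each 8-connected
    segment X_i of the current mask is removed iff the fraction of its area
    lying in the XOR image exceeds ``overlap_threshold``.  The first slice of
    a stack (no predecessor) passes through unmodified.
    """
    cur = as_bool(current)
    if prev_final is None:
        return cur.copy(), []
    prev = as_bool(prev_final)
    if prev.shape != cur.shape:
        raise ValueError("shape mismatch between slices")
    if not 0.0 < overlap_threshold < 1.0:
        raise ValueError("overlap_threshold must lie in (0, 1)")
    xor = prev ^ cur
    labels, n = ndimage.label(cur, structure=_EIGHT)
    out = cur.copy()
    decisions = []
    for lb in range(1, n + 1):
        seg = labels == lb
        frac = float((seg & xor).sum() / seg.sum())
        removed = frac > overlap_threshold
        if removed:
            out[seg] = False
        decisions.append(SldrDecision(lb, frac, removed))
    return out, decisions


def concatenate_pve(colon_mask, fluid_mask) -> np.ndarray:
    """Final output: colon segments joined with the extracted fluid/PVE
    region, holes filled within each resulting component."""
    a, b = as_bool(colon_mask), as_bool(fluid_mask)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return ndimage.binary_fill_holes(a | b)


def run_pipeline(
    volume: CTVolume,
    net: CascadeNet,
    config: PipelineConfig | None = None,
) -> tuple[list[SliceState], list[np.ndarray]]:
    """Execute the full per-slice pipeline over a volume.

    Returns the per-slice audit states and the final masks.
    """
    config = config or PipelineConfig()
    if len(volume) == 0:
        raise ValueError("volume is empty")
    states: list[SliceState] = []
    finals: list[np.ndarray] = []
    prev_final: np.ndarray | None = None
    for i, sl in enumerate(volume):
        res = otsu_threshold(sl, n_bins=config.otsu_bins)
        IS = extract_air(sl, res)
        interior = remove_external_air(IS)
        lm = label_components(interior)
        OI = remove_lungs(interior, lm, config.lung_params)
        had_lungs = bool((OI != interior).any())
        I_mo = morphological_open(OI, config.disk_radius)
        D1 = binarize_opened(I_mo, sl, radius=config.disk_radius, n_bins=config.otsu_bins)
        D0 = detect_pve(sl, net, config.window)
        OutF = combine(D0, D1)
        if had_lungs:
            cleaned = remove_tiny_holes(OutF, config.block, config.hole_threshold_1, config.strict_hole_threshold)
        else:
            cleaned = strip_border_rows(OutF, config.strip_top, config.strip_bottom)
        OutF1 = and_with_initial(cleaned, OI)
        colon, decisions = sldr(prev_final, OutF1, config.sldr_threshold)
        colon = remove_small_segments(colon, config.hole_threshold_2, config.strict_hole_threshold)
        fluid = extract_fluid(sl, D0, config.window)
        final = concatenate_pve(colon, fluid)
        states.append(
            SliceState(
                index=i, IS=IS, OI=OI, I_mo=I_mo, D0=D0, D1=D1, OutF=OutF,
                OutF1=OutF1, fluid=fluid, final=final,
                otsu_threshold=res.threshold, had_lungs=had_lungs,
                sldr_decisions=decisions,
            )
        )
        finals.append(final)
        prev_final = final
    return states, finals
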