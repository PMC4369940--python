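"""Synthetic abdominal-CT phantom with pixel-exact ground truth.

The phantom emulates the slice content the segmentation pipeline must cope
with: external air around an elliptical body of soft tissue, a bright
spine, lungs on the first slices only, air-filled colon lumens that drift
smoothly from slice to slice (continuous), single-slice bowel blobs
(discontinuous), and opacified-fluid pools at the bottom of a subset of
lumens with a partial-volume air-fluid boundary (AFB) band between air and
fluid.

Intensities are drawn on the 16-bit unsigned scale used by the classifier:
air below 10000, soft tissue / muscle in the muscle band, bone and
opacified fluid in the high-intensity band 55000-63000, and the AFB band
in the PVE/muscle overlap band 30000-55000.  Geometry is expressed as
fractions of the slice shape so small phantoms remain valid test fixtures.

This is deliberately not an anatomically realistic CT simulation: there is
no Hounsfield-unit physics and no scanner noise model, only additive
Gaussian noise clipped to the 16-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import CTVolume, write_mask_stack

# ground-truth class labels
EXTERNAL_AIR = 0
MUSCLE = 1
BONE = 2
LUNG = 3
COLON = 4
PVE = 5
FLUID = 6
BOWEL = 7

CLASS_NAMES = {
    EXTERNAL_AIR: "external_air",
    MUSCLE: "muscle",
    BONE: "bone",
    LUNG: "lung",
    COLON: "colon",
    PVE: "pve",
    FLUID: "fluid",
    BOWEL: "bowel",
}

#: Intensity range [lo, hi) each class is drawn from before noise.
CLASS_RANGES = {
    EXTERNAL_AIR: (0, 10000),
    MUSCLE: (10000, 55000),
    BONE: (55000, 63000),
    LUNG: (0, 10000),
    COLON: (0, 10000),
    PVE: (30000, 55000),
    FLUID: (55000, 63000),
    BOWEL: (0, 10000),
}


class ParameterError(ValueError):
    """A phantom specification violates its invariants."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic abdominal volume.

    Generation is a pure function of the spec (the RNG seed is a field),
    so equal specs produce bitwise-identical volumes.
    """

    n_slices: int = 20
    slice_shape: tuple[int, int] = (512, 512)
    n_colon_segments: int = 3
    lung_slice_range: tuple[int, int] = (0, 4)   # half-open [lo, hi)
    fluid_fraction: float = 0.5
    pve_band_width: int = 3
    bowel_rate: float = 1.0
    noise_sd: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 0 or self.n_colon_segments < 0 or self.pve_band_width < 0:
            raise ParameterError("counts must be non-negative")
        if min(self.slice_shape) < 64:
            raise ParameterError("slice_shape components must be >= 64")
        if not 0.0 <= self.fluid_fraction <= 1.0:
            raise ParameterError("fluid_fraction must lie in [0, 1]")
        if self.bowel_rate < 0 or self.noise_sd < 0:
            raise ParameterError("bowel_rate and noise_sd must be non-negative")
        lo, hi = self.lung_slice_range
        if lo < 0 or hi < lo:
            raise ParameterError("lung_slice_range must be a non-negative interval")


@dataclass
class PhantomGroundTruth:
    """Per-slice boolean stacks for every ground-truth class.

    The class masks are pairwise disjoint and, except external air, subsets
    of ``body_mask``.  ``labels`` holds the full per-pixel class map.
    """

    colon_mask: np.ndarray
    fluid_mask: np.ndarray
    pve_mask: np.ndarray
    lung_mask: np.ndarray
    bowel_mask: np.ndarray
    body_mask: np.ndarray
    bone_mask: np.ndarray
    labels: np.ndarray


def _ellipse(shape, center, semi):
    """Boolean ellipse mask, clipped to the image."""
    rows, cols = shape
    cr, cc = center
    a, b = max(semi[0], 1.0), max(semi[1], 1.0)
    r0, r1 = max(int(cr - a) - 1, 0), min(int(cr + a) + 2, rows)
    c0, c1 = max(int(cc - b) - 1, 0), min(int(cc + b) + 2, cols)
    out = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    rr, cc_ = np.ogrid[r0:r1, c0:c1]
    out[r0:r1, c0:c1] = ((rr - cr) / a) ** 2 + ((cc_ - cc) / b) ** 2 <= 1.0
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomGroundTruth]:
    """Generate a synthetic volume and its pixel-exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    n, (rows, cols) = spec.n_slices, spec.slice_shape
    scale = rows  # geometry expressed as fractions of the row count

    body_center = (0.52 * rows, 0.50 * cols)
    body_semi = (0.28 * rows, 0.37 * cols)
    spine_center = (body_center[0] + 0.17 * rows, 0.50 * cols)
    spine_semi = (0.045 * scale, 0.040 * scale)
    lung_semi = (0.080 * scale, 0.070 * scale)
    lung_centers = [
        (0.36 * rows, 0.50 * cols - 0.145 * cols),
        (0.36 * rows, 0.50 * cols + 0.145 * cols),
    ]

    # per-segment colon geometry: evenly spaced around an interior ring
    # below the lung region, drifting by a clamped random walk so
    # consecutive slices overlap
    k = spec.n_colon_segments
    ring_center = (0.61 * rows, 0.50 * cols)
    ring_r = 0.155 * min(rows, cols)
    rot = rng.uniform(0, 2 * np.pi)
    angles = rot + 2 * np.pi * np.arange(max(k, 1)) / max(k, 1)
    centers = [
        np.array([ring_center[0] + ring_r * np.sin(a), ring_center[1] + ring_r * np.cos(a)])
        for a in angles[:k]
    ]
    semis = [rng.uniform(0.030 * scale, 0.048 * scale, size=2) for _ in range(k)]
    semis = [np.maximum(s, 4.0) for s in semis]

    def clamp_inside_body(center, semi):
        # keep the lumen well inside the body ellipse, off the spine, and
        # clear of the lungs (air-air adjacency would merge the regions)
        m = np.array(semi) + 0.02 * scale
        for obst_center, obst_semi in [(spine_center, spine_semi), *((c, lung_semi) for c in lung_centers)]:
            sep = np.array(obst_semi) + np.array(semi) + 0.025 * scale
            off_s = center - np.array(obst_center)
            norm_s = np.hypot(off_s[0] / sep[0], off_s[1] / sep[1])
            if norm_s < 1.0:
                denom = norm_s if norm_s > 1e-9 else 1.0
                center = np.array(obst_center) + off_s / denom
        lim = np.maximum(np.array(body_semi) - m, 1.0)
        off = center - np.array(body_center)
        norm = np.hypot(off[0] / lim[0], off[1] / lim[1])
        if norm > 1.0:
            return np.array(body_center) + off / norm
        return center

    centers = [clamp_inside_body(c, s) for c, s in zip(centers, semis)]
    has_fluid = rng.random(k) < spec.fluid_fraction if k else np.zeros(0, bool)

    labels = np.zeros((n, rows, cols), dtype=np.uint8)
    body = _ellipse((rows, cols), body_center, body_semi)
    spine = _ellipse((rows, cols), spine_center, spine_semi) & body
    lungs_template = np.zeros((rows, cols), dtype=bool)
    for c in lung_centers:
        lungs_template |= _ellipse((rows, cols), c, lung_semi)
    lungs_template &= body

    colon = np.zeros((n, rows, cols), dtype=bool)
    pve = np.zeros_like(colon)
    fluid = np.zeros_like(colon)
    bowel = np.zeros_like(colon)
    lung = np.zeros_like(colon)
    pve_row_offset = np.zeros((n, rows, cols), dtype=np.int16)  # row within band

    drift_sd = 0.004 * scale
    lung_lo, lung_hi = spec.lung_slice_range

    for i in range(n):
        lab = np.where(body, MUSCLE, EXTERNAL_AIR).astype(np.uint8)
        occupied = ~body  # never paint outside the body
        if lung_lo <= i < lung_hi:
            sel = lungs_template & ~occupied
            lab[sel] = LUNG
            lung[i] = sel
            occupied |= sel
        sel = spine & ~occupied
        lab[sel] = BONE
        occupied |= sel

        for s in range(k):
            if i > 0:
                step = rng.normal(0.0, drift_sd, size=2)
                centers[s] = clamp_inside_body(centers[s] + step, semis[s])
            lum = _ellipse((rows, cols), tuple(centers[s]), tuple(semis[s])) & ~occupied
            if not lum.any():
                continue
            occupied |= lum
            if has_fluid[s]:
                line = int(round(centers[s][0] + 0.35 * semis[s][0]))
                half = spec.pve_band_width // 2
                rr = np.arange(rows)[:, None]
                band = lum & (rr >= line - half) & (rr < line - half + spec.pve_band_width)
                below = lum & (rr >= line - half + spec.pve_band_width)
                air = lum & ~band & ~below
                lab[air] = COLON
                lab[band] = PVE
                lab[below] = FLUID
                colon[i] |= air
                pve[i] |= band
                fluid[i] |= below
                if spec.pve_band_width > 0 and band.any():
                    rr_full = np.broadcast_to(rr, lab.shape)
                    pve_row_offset[i][band] = (rr_full[band] - (line - half)).astype(np.int16)
            else:
                lab[lum] = COLON
                colon[i] |= lum

        # single-slice bowel blobs, rejected if they touch anything or the
        # previous slice's bowels (discontinuity is the point)
        n_bowel = rng.poisson(spec.bowel_rate)
        prev_bowel = bowel[i - 1] if i > 0 else np.zeros((rows, cols), bool)
        for _ in range(n_bowel):
            for _attempt in range(60):
                semi = rng.uniform(0.012 * scale, 0.024 * scale, size=2)
                semi = np.maximum(semi, 3.0)
                cr = rng.uniform(body_center[0] - body_semi[0], body_center[0] + body_semi[0])
                cc = rng.uniform(body_center[1] - body_semi[1], body_center[1] + body_semi[1])
                inflated = _ellipse((rows, cols), (cr, cc), tuple(semi + 3))
                if not inflated.any():
                    continue
                if (inflated & occupied).any() or (inflated & prev_bowel).any() or (inflated & ~body).any():
                    continue
                blob = _ellipse((rows, cols), (cr, cc), tuple(semi))
                lab[blob] = BOWEL
                bowel[i] |= blob
                occupied |= blob
                break

        labels[i] = lab

    # intensities: vectorized per class over the whole volume
    intensity = np.zeros(labels.shape, dtype=np.float64)
    air_like = np.isin(labels, (EXTERNAL_AIR, LUNG, COLON, BOWEL))
    intensity[air_like] = rng.uniform(2000, 7000, size=int(air_like.sum()))
    m = labels == MUSCLE
    # soft tissue occupies a bounded band straddling the M / P-M overlap;
    # the hard lower edge keeps the air/tissue histogram cleanly bimodal
    intensity[m] = rng.uniform(22000, 40000, size=int(m.sum()))
    hi = np.isin(labels, (BONE, FLUID))
    intensity[hi] = rng.uniform(57000, 61500, size=int(hi.sum()))
    p = labels == PVE
    if p.any():
        w = max(spec.pve_band_width - 1, 1)
        frac = np.clip(pve_row_offset[p] / w, 0.0, 1.0)
        intensity[p] = 33000 + 19000 * frac + rng.uniform(-800, 800, size=int(p.sum()))

    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    data = np.clip(np.rint(intensity), 0, 65535).astype(np.uint16)

    truth = PhantomGroundTruth(
        colon_mask=colon,
        fluid_mask=fluid,
        pve_mask=pve,
        lung_mask=lung,
        bowel_mask=bowel,
        body_mask=np.broadcast_to(body, labels.shape).copy(),
        bone_mask=labels == BONE,
        labels=labels,
    )
    return CTVolume(data), truth


def save_ground_truth(truth: PhantomGroundTruth, path) -> None:
    """Write ground truth as 8-bit label PNGs plus a JSON class manifest."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = truth.labels.shape[0]
    width = max(3, len(str(n)))
    for i in range(n):
        iio.imwrite(path / f"labels_{i + 1:0{width}d}.png", truth.labels[i])
    (path / "classes.json").write_text(json.dumps({str(v): k for v, k in CLASS_NAMES.items()}))


def speckled_mask(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    n_speckles: int = 200,
    n_blobs: int = 3,
    max_speckle_area: int = 9,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """A binary mask of a few colon-like blobs plus small speckle components.

    Used to measure the tiny-hole removal stage: each speckle is a connected
    component of area 1..max_speckle_area grown by a random walk, placed at
    least a few pixels away from all other foreground so speckles are
    individual "small dots".

    Returns the mask and the (rows, cols) index arrays of each speckle.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        center = (rng.uniform(0.2 * rows, 0.8 * rows), rng.uniform(0.2 * cols, 0.8 * cols))
        semi = (rng.uniform(20, 35), rng.uniform(20, 35))
        mask |= _ellipse(shape, center, semi)

    margin = 4  # Chebyshev clearance around each speckle
    speckles = []
    placed = 0
    guard = 0
    while placed < n_speckles and guard < n_speckles * 200:
        guard += 1
        area = int(rng.integers(1, max_speckle_area + 1))
        pts = {(0, 0)}
        while len(pts) < area:
            r, c = list(pts)[int(rng.integers(len(pts)))]
            dr, dc = ((0, 1), (0, -1), (1, 0), (-1, 0))[int(rng.integers(4))]
            pts.add((r + dr, c + dc))
        pr = np.array([p[0] for p in pts])
        pc = np.array([p[1] for p in pts])
        pr -= pr.min()
        pc -= pc.min()
        h, w = pr.max() + 1, pc.max() + 1
        r0 = int(rng.integers(margin, rows - h - margin))
        c0 = int(rng.integers(margin, cols - w - margin))
        window = mask[r0 - margin:r0 + h + margin, c0 - margin:c0 + w + margin]
        if window.any():
            continue
        mask[pr + r0, pc + c0] = True
        speckles.append((pr + r0, pc + c0))
        placed += 1
    return mask, speckles
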