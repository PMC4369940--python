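"""Air-packet extraction: per-slice Otsu thresholding and external-air removal.

Otsu's criterion selects, over all candidate cut points of the intensity
histogram, the threshold maximizing the between-class variance
``w0*w1*(mu0-mu1)^2`` (equivalently minimizing the intra-class variance).
Air is the dark class in CT, so the initial segmentation ``IS`` is the set
of pixels strictly below the threshold.  Air components 8-connected to the
image border are outside the body and are cleared.

The full 65536-level histogram is used by default so the scan is exact;
ties in the between-class variance are broken toward the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import as_bool


@dataclass
class OtsuResult:
    """Threshold, its between-class variance, and the histogram it came from.

    ``threshold`` is on the intensity scale: the lower edge of the first bin
    of the upper class.  For a constant image the histogram is degenerate;
    the threshold equals the single value (so the below-threshold mask is
    empty) and the variance is 0.
    """

    threshold: float
    between_class_variance: float
    histogram: np.ndarray
    bin_edges: np.ndarray


def otsu_threshold(slice_: np.ndarray, n_bins: int = 65536) -> OtsuResult:
    """Exhaustive Otsu threshold of one slice.

    Parameters
    ----------
    slice_ : ndarray
        2-D array of 16-bit unsigned intensities.
    n_bins : int
        Number of equal histogram bins over [0, 65536).
    """
    slice_ = np.asarray(slice_)
    if slice_.size == 0:
        raise ValueError("slice is empty")
    hist, edges = np.histogram(slice_, bins=n_bins, range=(0, 65536))
    lo, hi = slice_.min(), slice_.max()
    if lo == hi:
        return OtsuResult(float(lo), 0.0, hist, edges)

    counts = hist.astype(np.float64)
    total = counts.sum()
    p = counts / total
    omega0 = np.cumsum(p)                  # weight of class {bins <= k}
    mu_cum = np.cumsum(p * np.arange(n_bins))
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)  # cut after bin k, k < n_bins-1
    k = int(np.argmax(sigma_b))            # argmax takes the first maximum: lowest threshold
    threshold = float(edges[k + 1])        # lower edge of the upper class
    # variance is in bin-index units; rescale to intensity units
    bin_width = edges[1] - edges[0]
    return OtsuResult(threshold, float(sigma_b[k]) * bin_width**2, hist, edges)


def extract_air(slice_: np.ndarray, otsu: OtsuResult) -> np.ndarray:
    """Initial segmentation IS: pixels strictly below the Otsu threshold."""
    return np.asarray(slice_) < otsu.threshold


def remove_external_air(mask) -> np.ndarray:
    """Clear every air component 8-connected to the image border.

    Anti-extensive and idempotent; interior components are untouched.
    """
    m = as_bool(mask)
    if not m.any():
        return m.copy()
    labels, _ = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    border = np.unique(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
    border = border[border > 0]
    out = m.copy()
    if border.size:
        out[np.isin(labels, border)] = False
    return out
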