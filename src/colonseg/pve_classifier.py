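"""Opacified-fluid / partial-volume-effect detection.

CT slices mix five tissue appearances — air, liquid, soft tissue, muscle,
bone — and the detector works on 16-bit intensity categories:

====  =================  =========================================
code  range [lo, hi)     meaning
====  =================  =========================================
A     0 .. 10000         air (colon lumen, bowels, lungs, outside)
P/M   30000 .. 55000     partial-volume band or muscle
M     10000 .. 55000     muscle / soft tissue
HI    55000 .. 63000     bone or opacified fluid
====  =================  =========================================

The M and P/M ranges overlap, so :func:`categorize` returns the *set* of
categories containing a value.  For window labeling the overlap must be
resolved — under raw set semantics no window could ever present P/M
without M — so a window's category-presence uses disjoint per-pixel
classes: a pixel is evidence of M only when it can be nothing but muscle
(10000-30000).  A window is an active region for extraction iff its
presence set is one of {A}, {A, P/M}, {A, P/M, HI}; windows showing
muscle-only evidence, HI alone, or P/M alone are bone/muscle and inactive.

A cascade feed-forward network (input -> 64-unit logistic hidden layer ->
logistic output, with a direct input->output cascade connection; biases
everywhere) is trained by backpropagation on the mean squared error plus
an L2 weight penalty — the fixed-hyperparameter form of Bayesian
regularization — to reproduce those targets from per-window features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import as_bool


class Category(Enum):
    A = "A"
    PM = "PM"
    M = "M"
    HI = "HI"


#: Category intensity ranges [lo, hi) on the 16-bit scale.  HI is extended
#: past 63000 so bone-saturated values still classify as high intensity.
CATEGORY_RANGES = {
    Category.A: (0, 10000),
    Category.PM: (30000, 55000),
    Category.M: (10000, 55000),
    Category.HI: (55000, 65536),
}

#: Window presence sets labeled as active regions for extraction.
TRUE_PATTERNS = (
    frozenset({Category.A}),
    frozenset({Category.A, Category.PM}),
    frozenset({Category.A, Category.PM, Category.HI}),
)

N_FEATURES = 10  # 4 presence indicators + min/max/mean/sd + 2 coordinates


class NotTrainedError(RuntimeError):
    """Inference was requested from an untrained network."""


class TrainingDivergenceError(RuntimeError):
    """The training loss became non-finite."""


def sigmoid(x):
    """Logistic threshold function 1/(1 + exp(-x)), saturating for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def categorize(value: int) -> set[Category]:
    """All categories whose range contains ``value`` (ranges overlap)."""
    if not 0 <= value <= 65535:
        raise ValueError(f"intensity {value} outside [0, 65535]")
    return {c for c, (lo, hi) in CATEGORY_RANGES.items() if lo <= value < hi}


def pixel_class(values) -> np.ndarray:
    """Disjoint per-pixel class codes used for window presence.

    0=A (<10000), 1=M-only evidence (10000-30000), 2=P/M (30000-55000),
    3=HI (>=55000).
    """
    v = np.asarray(values)
    out = np.zeros(v.shape, dtype=np.uint8)
    out[v >= 10000] = 1
    out[v >= 30000] = 2
    out[v >= 55000] = 3
    return out


def label_window(categories_present: set[Category], pm_with_air_active: bool = True) -> bool:
    """Active/inactive target of one window from its category-presence set.

    ``pm_with_air_active=False`` switches to the variant where air together
    with P/M but no high intensity is inactive.
    """
    s = frozenset(categories_present)
    if not pm_with_air_active and s == frozenset({Category.A, Category.PM}):
        return False
    return s in TRUE_PATTERNS


_CODE_TO_CAT = [Category.A, Category.M, Category.PM, Category.HI]


def _tile_grid(shape: tuple[int, int], window: int) -> list[tuple[int, int, int, int]]:
    rows, cols = shape
    if window > rows or window > cols:
        raise ValueError(f"window {window} larger than slice {shape}")
    return [
        (r, min(r + window, rows), c, min(c + window, cols))
        for r in range(0, rows, window)
        for c in range(0, cols, window)
    ]


def window_features(slice_: np.ndarray, window: int = 8):
    """Per-tile feature vectors and category-presence indicators.

    Returns ``(positions, X, presence)``: tile top-left corners (n, 2), the
    (n, 10) feature matrix, and the (n, 4) boolean presence matrix ordered
    (A, M, PM, HI).
    """
    slice_ = np.asarray(slice_)
    rows, cols = slice_.shape
    codes = pixel_class(slice_)
    boxes = _tile_grid((rows, cols), window)
    n = len(boxes)
    positions = np.array([(b[0], b[2]) for b in boxes], dtype=np.int64)
    presence = np.zeros((n, 4), dtype=bool)
    stats = np.zeros((n, 4), dtype=np.float64)
    if rows % window == 0 and cols % window == 0:
        nr, nc = rows // window, cols // window
        v = slice_.reshape(nr, window, nc, window).transpose(0, 2, 1, 3).reshape(n, -1).astype(np.float64)
        cd = codes.reshape(nr, window, nc, window).transpose(0, 2, 1, 3).reshape(n, -1)
        for k in range(4):
            presence[:, k] = (cd == k).any(axis=1)
        stats[:, 0] = v.min(axis=1)
        stats[:, 1] = v.max(axis=1)
        stats[:, 2] = v.mean(axis=1)
        stats[:, 3] = v.std(axis=1)
    else:
        for i, (r0, r1, c0, c1) in enumerate(boxes):
            t = slice_[r0:r1, c0:c1].astype(np.float64)
            ct = codes[r0:r1, c0:c1]
            for k in range(4):
                presence[i, k] = (ct == k).any()
            stats[i] = (t.min(), t.max(), t.mean(), t.std())
    centers = positions + window / 2.0
    X = np.column_stack(
        [
            presence.astype(np.float64),
            stats[:, 0] / 65535.0,
            stats[:, 1] / 65535.0,
            stats[:, 2] / 65535.0,
            stats[:, 3] / 32767.5,
            centers[:, 0] / rows,
            centers[:, 1] / cols,
        ]
    )
    return positions, X, presence


def rule_targets(presence: np.ndarray, pm_with_air_active: bool = True) -> np.ndarray:
    """Vectorized window labels from (n, 4) presence ordered (A, M, PM, HI)."""
    a, m, pm, hi = presence.T
    active = a & ~m & (~hi | pm)
    if not pm_with_air_active:
        active &= ~(pm & ~hi)
    return active


@dataclass
class PatternSample:
    """One training pattern: a window feature vector and its binary target."""

    features: np.ndarray
    target: int


def extract_windows(slice_: np.ndarray, window: int = 8):
    """List of ``(position, PatternSample)`` with rule-generated targets."""
    positions, X, presence = window_features(slice_, window)
    y = rule_targets(presence)
    return [((int(p[0]), int(p[1])), PatternSample(x, int(t))) for p, x, t in zip(positions, X, y)]


def build_training_set(
    volume,
    window: int = 8,
    truth: np.ndarray | None = None,
    restrict: np.ndarray | None = None,
    pm_with_air_active: bool = True,
) -> list[PatternSample]:
    """Window samples over a volume, labeled by the category rules.

    When a ground-truth ``truth`` stack is supplied it overrides the rule
    targets: a window is active iff it overlaps the truth mask (the
    slice-to-ground correlation used to supervise the detector).
    ``restrict`` keeps only windows fully inside the given stack (e.g. the
    body), dropping uninformative exterior windows.
    """
    slices = list(volume)
    if not slices:
        raise ValueError("volume is empty")
    samples: list[PatternSample] = []
    for i, sl in enumerate(slices):
        positions, X, presence = window_features(sl, window)
        if truth is not None:
            t = as_bool(truth[i])
            y = np.array(
                [t[r0:r0 + window, c0:c0 + window].any() for r0, c0 in positions], dtype=bool
            )
        else:
            y = rule_targets(presence, pm_with_air_active)
        keep = np.ones(len(positions), dtype=bool)
        if restrict is not None:
            b = as_bool(restrict[i])
            keep = np.array(
                [b[r0:r0 + window, c0:c0 + window].all() for r0, c0 in positions], dtype=bool
            )
        samples.extend(PatternSample(x, int(t)) for x, t in zip(X[keep], y[keep]))
    return samples


@dataclass
class CascadeNet:
    """Cascade feed-forward network: input -> hidden -> output plus a direct
    input -> output connection; logistic units; biases on all layers."""

    w_in_hidden: np.ndarray
    b_hidden: np.ndarray
    w_hidden_out: np.ndarray
    w_in_out: np.ndarray
    b_out: float
    trained: bool = False

    @property
    def n_hidden(self) -> int:
        return self.b_hidden.size

    @property
    def n_in(self) -> int:
        return self.w_in_hidden.shape[1]

    @classmethod
    def init(cls, n_in: int = N_FEATURES, n_hidden: int = 64, seed: int = 0) -> "CascadeNet":
        """Weights and biases uniform in [-0.5, 0.5] from the seed."""
        rng = np.random.default_rng(seed)
        return cls(
            w_in_hidden=rng.uniform(-0.5, 0.5, size=(n_hidden, n_in)),
            b_hidden=rng.uniform(-0.5, 0.5, size=n_hidden),
            w_hidden_out=rng.uniform(-0.5, 0.5, size=n_hidden),
            w_in_out=rng.uniform(-0.5, 0.5, size=n_in),
            b_out=float(rng.uniform(-0.5, 0.5)),
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (0, 1) for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        H = sigmoid(X @ self.w_in_hidden.T + self.b_hidden)
        z = H @ self.w_hidden_out + X @ self.w_in_out + self.b_out
        return sigmoid(z)

    def to_json(self, path) -> None:
        payload = {
            "n_in": self.n_in,
            "n_hidden": self.n_hidden,
            "trained": self.trained,
            "w_in_hidden": self.w_in_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_hidden_out": self.w_hidden_out.tolist(),
            "w_in_out": self.w_in_out.tolist(),
            "b_out": self.b_out,
            "feature_spec": "A,M,PM,HI presence; min,max,mean,sd; row,col center (normalized)",
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "CascadeNet":
        d = json.loads(Path(path).read_text())
        return cls(
            w_in_hidden=np.array(d["w_in_hidden"]),
            b_hidden=np.array(d["b_hidden"]),
            w_hidden_out=np.array(d["w_hidden_out"]),
            w_in_out=np.array(d["w_in_out"]),
            b_out=float(d["b_out"]),
            trained=bool(d["trained"]),
        )


@dataclass
class TrainConfig:
    max_epochs: int = 1500
    error_tolerance: float = 1e-4
    l2_penalty: float = 1e-3
    learning_rate: float = 0.02
    n_hidden: int = 64
    seed: int = 0


@dataclass
class TrainReport:
    mse_history: list[float]
    final_mse: float
    regression_r: float
    best_epoch: int


def train(
    net: CascadeNet | None,
    samples: list[PatternSample],
    config: TrainConfig | None = None,
) -> tuple[CascadeNet, TrainReport]:
    """Train the network by regularized backpropagation.

    Full-batch gradients of MSE + l2_penalty * mean(w^2) (weights only, not
    biases) with adaptive-moment steps; deterministic given the seed; stops
    at ``error_tolerance`` or ``max_epochs``.
    """
    config = config or TrainConfig()
    if not samples:
        raise ValueError("training set is empty")
    X = np.array([s.features for s in samples], dtype=np.float64)
    y = np.array([s.target for s in samples], dtype=np.float64)
    if net is None:
        net = CascadeNet.init(n_in=X.shape[1], n_hidden=config.n_hidden, seed=config.seed)
    if X.shape[1] != net.n_in:
        raise ValueError(f"feature length {X.shape[1]} != network input size {net.n_in}")

    params = [net.w_in_hidden, net.b_hidden, net.w_hidden_out, net.w_in_out,
              np.array([net.b_out], dtype=np.float64)]
    is_weight = [True, False, True, True, False]
    n_weights = sum(p.size for p, w in zip(params, is_weight) if w)
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = X.shape[0]
    lam = config.l2_penalty

    mse_history: list[float] = []
    best_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        w_ih, b_h, w_ho, w_io, b_o = params
        H = sigmoid(X @ w_ih.T + b_h)
        out = sigmoid(H @ w_ho + X @ w_io + b_o[0])
        err = out - y
        mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise TrainingDivergenceError(f"loss diverged at epoch {epoch}")
        mse_history.append(mse)
        if mse <= min(mse_history):
            best_epoch = epoch
        if mse < config.error_tolerance:
            break

        dz = (2.0 / n) * err * out * (1.0 - out)
        g_who = H.T @ dz
        g_wio = X.T @ dz
        g_bo = np.array([dz.sum()])
        dH = np.outer(dz, w_ho) * H * (1.0 - H)
        g_wih = dH.T @ X
        g_bh = dH.sum(axis=0)
        grads = [g_wih, g_bh, g_who, g_wio, g_bo]
        for j, (p, g, w) in enumerate(zip(params, grads, is_weight)):
            if w:
                g = g + (2.0 * lam / n_weights) * p
            m_state[j] = beta1 * m_state[j] + (1 - beta1) * g
            v_state[j] = beta2 * v_state[j] + (1 - beta2) * g**2
            mhat = m_state[j] / (1 - beta1**epoch)
            vhat = v_state[j] / (1 - beta2**epoch)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

    net.b_out = float(params[4][0])
    net.trained = True
    out = net.forward(X)
    final_mse = float(np.mean((out - y) ** 2))
    if np.std(out) > 0 and np.std(y) > 0:
        regression_r = float(np.corrcoef(out, y)[0, 1])
    else:
        regression_r = 0.0
    return net, TrainReport(mse_history, final_mse, regression_r, best_epoch)


def detect_pve(slice_: np.ndarray, net: CascadeNet, window: int = 8) -> np.ndarray:
    """D0 mask: the union of windows the network marks active (output >= 0.5)."""
    if not net.trained:
        raise NotTrainedError("detect_pve requires a trained network")
    positions, X, _ = window_features(slice_, window)
    out = net.forward(X)
    mask = np.zeros(np.asarray(slice_).shape, dtype=bool)
    for (r0, c0), o in zip(positions, out):
        if o >= 0.5:
            mask[r0:r0 + window, c0:c0 + window] = True
    return mask


def extract_fluid(slice_: np.ndarray, d0, window: int = 8) -> np.ndarray:
    """Opacified fluid plus its partial-volume band, from the D0 detection.

    High-intensity pixels are either bone or liquid; liquid is the one
    lying under the air-fluid boundary, i.e. beneath a vertical
    air -> P/M -> HI intensity layering.  Within the active (D0) region,
    P/M pixels vertically connected to an air-adjacent P/M pixel form
    boundary-band candidates; HI pixels directly below such a candidate
    seed the pool and are propagated through the 8-connected HI class,
    covering the pool interior.  The band pixels connected to the pool are
    returned with it.  Bone never sits under an air/P-M layering, so it is
    never seeded.
    """
    slice_ = np.asarray(slice_)
    d0 = as_bool(d0)
    codes = pixel_class(slice_)
    # the air/P-M boundary evidence is gated by the network's active
    # region; the HI pool interior is reached by propagation from it
    air = (codes == 0) & d0
    pm = (codes == 2) & d0
    hi = codes == 3
    if not (pm.any() and hi.any() and air.any()):
        return np.zeros(slice_.shape, dtype=bool)
    below = np.zeros_like(air)
    below[1:] = air[:-1]           # pixels with air directly above
    vertical = np.zeros((3, 3), dtype=bool)
    vertical[:, 1] = True
    band_candidates = ndimage.binary_propagation(pm & below, structure=vertical, mask=pm)
    under_band = np.zeros_like(air)
    under_band[1:] = band_candidates[:-1]
    seeds = hi & under_band
    if not seeds.any():
        return np.zeros(slice_.shape, dtype=bool)
    fluid = ndimage.binary_propagation(seeds, structure=np.ones((3, 3)), mask=hi)
    over_fluid = np.zeros_like(air)
    over_fluid[:-1] = fluid[1:]
    band = ndimage.binary_propagation(band_candidates & over_fluid, structure=np.ones((3, 3)), mask=band_candidates)
    return fluid | band
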