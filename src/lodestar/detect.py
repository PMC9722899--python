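"""Multi-object detection from feature maps, and frame-to-frame trace linking.

A trained network applied to an arbitrarily large image yields position maps
that are locally constant near each object and a weight map that marks
informative pixels.  Detection combines the weight map ``w`` with a
clustering metric ``b`` (the inverse of the summed local 3x3 variance of the
feature channels — predictions that agree with their neighbours score high)
into a score map ``w^alpha * b^(1-alpha)``.  Prominence-filtered local maxima
above a score quantile are candidate detections; each is refined to sub-pixel
accuracy by a weighted average of the position maps in a small window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.optimize import linear_sum_assignment
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima

from .model import FeatureMapStack, _sigmoid, forward, position_maps
from .nn import Sequential

__all__ = [
    "DetectParams",
    "clustering_map",
    "score_map",
    "local_maxima",
    "refine",
    "detect",
    "link_traces",
    "weighted_variance",
]


@dataclass(frozen=True)
class DetectParams:
    """Detection tuning knobs.

    ``alpha`` weighs the weight map against the clustering metric
    (``beta = 1 - alpha`` unless given); low alpha (0.1) suits homogeneous
    particles, alpha up to 1 morphologically variable objects.  The score
    threshold is a quantile of all scores (0.99 by default); ``prominence``
    is the h-maxima depth as a fraction of the score range.
    """

    alpha: float = 0.1
    beta: float | None = None
    quantile: float = 0.99
    prominence: float = 1e-3
    window: int = 3
    eps_b: float = 1e-6
    border_margin: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")

    @property
    def beta_(self) -> float:
        return 1.0 - self.alpha if self.beta is None else self.beta


def _channel_maps(stack: FeatureMapStack) -> np.ndarray:
    """(n, m, C-1) decoded feature channels (top-left positions + extras)."""
    x, y = position_maps(stack, convention="top-left")
    return np.concatenate([x[..., None], y[..., None], stack.extras], axis=-1)


def clustering_map(stack: FeatureMapStack, eps_b: float = 1e-6) -> np.ndarray:
    """Inverse local-variance clustering metric ``b``.

    ``b^-1`` sums, over the decoded feature channels, the 3x3 local variance
    (local mean of squares minus squared local mean); ``b`` is its inverse,
    clamped at ``1/eps_b`` where the variance vanishes.
    """
    chi = _channel_maps(stack)
    binv = np.zeros(chi.shape[:2])
    for c in range(chi.shape[-1]):
        mean = uniform_filter(chi[..., c], size=3, mode="nearest")
        mean_sq = uniform_filter(chi[..., c] ** 2, size=3, mode="nearest")
        binv += np.maximum(mean_sq - mean**2, 0.0)
    return 1.0 / np.maximum(binv, eps_b)


def weighted_variance(stack: FeatureMapStack) -> float:
    """Self-consistency statistic: weight-averaged variance of the decoded
    feature channels around their pooled means.

    A model evaluated on data resembling its training distribution clusters
    its position predictions tightly where the weight map is large, giving a
    variance orders of magnitude below that on unfamiliar data — the basis
    of the method's discriminative power.
    """
    from .model import eval_weights

    chi = _channel_maps(stack)
    w = eval_weights(stack.rho)
    mean = (chi * w[..., None]).sum(axis=(0, 1))
    return float(((chi - mean) ** 2 * w[..., None]).sum())


def score_map(weights: np.ndarray, b: np.ndarray, params: DetectParams = DetectParams()) -> np.ndarray:
    """Geometric combination ``w^alpha * b^beta`` of the two detection metrics."""
    w = np.asarray(weights, dtype=float)
    b = np.asarray(b, dtype=float)
    if w.shape != b.shape:
        raise ValueError("weight and clustering maps must share shape")
    if np.any(w < 0) or np.any(b < 0):
        raise ValueError("detection metrics must be non-negative")
    return w**params.alpha * b**params.beta_

def local_maxima(score: np.ndarray, params: DetectParams = DetectParams()) -> np.ndarray:
    """Prominent local maxima of the score map above the quantile threshold.

    Returns integer ``(row, col)`` feature-map coordinates; may be empty.
    """
    score = np.asarray(score, dtype=float)
    rng_ = score.max() - score.min()
    if rng_ <= 0:
        return np.zeros((0, 2), dtype=int)
    h = params.prominence * score.max()
    peaks = h_maxima(score, h)
    thresh = np.quantile(score, params.quantile)
    n, m = score.shape
    bm = params.border_margin
    coords = []
    for region in regionprops(label(peaks)):
        r, c = (int(round(v)) for v in region.centroid)
        if score[r, c] > thresh and bm <= r < n - bm and bm <= c < m - bm:
            coords.append((r, c))
    return np.asarray(coords, dtype=int).reshape(-1, 2)


def refine(
    candidates: np.ndarray,
    stack: FeatureMapStack,
    params: DetectParams = DetectParams(),
) -> pd.DataFrame:
    """Sub-pixel refinement: weighted average of the decoded channels in a
    window around each candidate (weights renormalized within the window).

    Returns a detections table with columns x, y (input px, top-left
    convention), one column per extra channel, and score (window weight mass).
    Candidates whose window carries no weight are dropped.
    """
    chi = _channel_maps(stack)
    w = _sigmoid(stack.rho)
    n, m = w.shape
    rows = []
    for r, c in np.asarray(candidates, dtype=int).reshape(-1, 2):
        r0, r1 = max(r - params.window, 0), min(r + params.window + 1, n)
        c0, c1 = max(c - params.window, 0), min(c + params.window + 1, m)
        ww = w[r0:r1, c0:c1]
        mass = ww.sum()
        if mass <= 0:
            continue
        vals = (chi[r0:r1, c0:c1] * ww[..., None]).sum(axis=(0, 1)) / mass
        rec = {"x": vals[0], "y": vals[1], "score": mass}
        for e in range(stack.n_extras):
            rec[f"extra{e}"] = vals[2 + e]
        rows.append(rec)
    cols = ["x", "y"] + [f"extra{e}" for e in range(stack.n_extras)] + ["score"]
    return pd.DataFrame(rows, columns=cols)


def detect(
    network: Sequential,
    image,
    params: DetectParams = DetectParams(),
    normalize: bool = True,
) -> pd.DataFrame:
    """Full detection pipeline on one image (2D array or ComplexField planes).

    Deterministic given the weights and the image: forward pass, clustering
    map, score map, prominent maxima above the quantile, then sub-pixel
    refinement.
    """
    from .simulate import ComplexField

    if isinstance(image, ComplexField):
        img = image.planes()
    else:
        img = np.asarray(image, dtype=float)
        if normalize and img.ndim == 2:
            from .training import normalize_intensity

            img = normalize_intensity(img)
    if min(img.shape[:2]) < 16:
        raise ValueError("image smaller than the network's useful receptive field")
    stack = forward(network, img)
    b = clustering_map(stack, params.eps_b)
    w = _sigmoid(stack.rho)
    score = score_map(w, b, params)
    cand = local_maxima(score, params)
    return refine(cand, stack, params)


def link_traces(
    detections: pd.DataFrame,
    max_dist: float,
    min_length: int = 1,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Greedy frame-pair linking by minimum-total-distance assignment.

    ``detections`` must carry ``frame``, ``x``, ``y`` columns (positions in
    px; ``max_dist`` in the same length units as ``pixel_size`` per px).
    Consecutive frames are linked by linear sum assignment with pairs beyond
    ``max_dist`` forbidden; unmatched detections start new traces and traces
    shorter than ``min_length`` frames are discarded.  Returns the input
    table with a ``trace_id`` column, filtered and sorted by (trace, frame).
    """
    det = detections.reset_index(drop=True).copy()
    det["trace_id"] = -1
    next_id = 0
    prev_idx: list[int] = []
    big = 1e12
    for frame in sorted(det["frame"].unique()):
        cur_idx = det.index[det["frame"] == frame].tolist()
        if prev_idx:
            prev_pos = det.loc[prev_idx, ["x", "y"]].to_numpy(float) * pixel_size
            cur_pos = det.loc[cur_idx, ["x", "y"]].to_numpy(float) * pixel_size
            cost = np.linalg.norm(prev_pos[:, None, :] - cur_pos[None, :, :], axis=-1)
            cost = np.where(cost <= max_dist, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] < big:
                    det.loc[cur_idx[c], "trace_id"] = det.loc[prev_idx[r], "trace_id"]
        for i in cur_idx:
            if det.loc[i, "trace_id"] < 0:
                det.loc[i, "trace_id"] = next_id
                next_id += 1
        prev_idx = cur_idx
    lengths = det.groupby("trace_id").size()
    keep = lengths.index[lengths >= min_length]
    out = det[det["trace_id"].isin(keep)].sort_values(["trace_id", "frame"])
    return out.reset_index(drop=True)
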