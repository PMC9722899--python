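"""Evaluation metrics: localization RMSE, detection matching and F1,
and a covariance-based single-trace diffusion estimator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "rmse",
    "match_detections",
    "f1",
    "diffusion_coefficient",
]


@dataclass(frozen=True)
class MatchResult:
    """Counts from matching predictions against ground truth."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def rmse(predictions: np.ndarray, truth: np.ndarray, pairs=None) -> float:
    """Root mean squared Euclidean position error over matched pairs.

    With ``pairs=None`` rows are paired in order (requires equal lengths).
    """
    pred = np.asarray(predictions, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if pairs is None:
        if len(pred) != len(tru):
            raise ValueError("unpaired inputs must have equal length")
        pairs = [(i, i) for i in range(len(pred))]
    if len(pairs) == 0:
        raise ValueError("need at least one matched pair")
    d2 = [np.sum((pred[i] - tru[j]) ** 2) for i, j in pairs]
    return float(np.sqrt(np.mean(d2)))


def match_detections(
    preds: np.ndarray,
    truth,
    mode: str = "distance",
    threshold: float = 2.0,
) -> MatchResult:
    """Match predicted positions against ground truth.

    ``mode='mask'``: ``truth`` is an integer-labelled mask image.  A
    prediction falling inside a labelled region is a true positive for that
    object; every additional prediction in the same region is a false
    positive, as is any prediction on background; unmatched objects are
    false negatives.

    ``mode='distance'``: ``truth`` is an ``(n, 2)`` position array; one-to-one
    minimum-total-distance assignment with pairs beyond ``threshold`` px
    forbidden.
    """
    pred = np.asarray(preds, dtype=float).reshape(-1, 2)
    if mode == "mask":
        mask = np.asarray(truth)
        if mask.dtype.kind not in "iu":
            raise ValueError("mask mode requires an integer-labelled mask image")
        labels = set(np.unique(mask)) - {0}
        hit: dict[int, int] = {}
        fp = 0
        pairs = []
        for idx, (x, y) in enumerate(pred):
            r, c = int(round(x)), int(round(y))
            lab = int(mask[r, c]) if (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) else 0
            if lab == 0 or lab in hit:
                fp += 1
            else:
                hit[lab] = idx
                pairs.append((idx, lab))
        tp = len(hit)
        fn = len(labels) - tp
        return MatchResult(tp, fp, fn, tuple(pairs))
    if mode != "distance":
        raise ValueError("mode must be 'mask' or 'distance'")
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(pred) == 0 or len(tru) == 0:
        return MatchResult(0, len(pred), len(tru))
    cost = np.linalg.norm(pred[:, None, :] - tru[None, :, :], axis=-1)
    big = 1e12
    ri, ci = linear_sum_assignment(np.where(cost <= threshold, cost, big))
    pairs = tuple((int(r), int(c)) for r, c in zip(ri, ci) if cost[r, c] <= threshold)
    tp = len(pairs)
    return MatchResult(tp, len(pred) - tp, len(tru) - tp, pairs)


def f1(match: MatchResult) -> float:
    """F1 score ``2 TP / (2 TP + FP + FN)``."""
    denom = 2 * match.tp + match.fp + match.fn
    if denom == 0:
        raise ValueError("no predictions and no truth: F1 undefined")
    return 2.0 * match.tp / denom


def diffusion_coefficient(positions: np.ndarray, frame_interval: float, pixel_size: float = 1.0):
    """Covariance-based diffusion estimator per axis.

    For frame-to-frame displacements ``d_n`` (um) of a trace sampled every
    ``frame_interval`` seconds,

        D = ( <d^2>/2 + <d_n d_{n+1}> ) / frame_interval

    per axis, which is unbiased under static localization noise (the
    negative lag-1 covariance induced by the noise cancels its contribution
    to the squared displacement).  Returns an array of per-axis D (um^2/s).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    if pos.shape[0] < 10:
        raise ValueError("trace too short for a covariance estimate (need >= 10 points)")
    disp = np.diff(pos * pixel_size, axis=0)
    msd = (disp**2).mean(axis=0)
    lag1 = (disp[:-1] * disp[1:]).mean(axis=0)
    return (msd / 2.0 + lag1) / frame_interval
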