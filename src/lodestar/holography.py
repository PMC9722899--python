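"""Physical quantities from the extra network channels.

The propagation-symmetry channel reads out an axial position (with an
optional immersion-mismatch correction) and the signal-scale channel reads
out a polarizability once calibrated against a particle of known size and
refractive index via the Clausius-Mossotti relation.  Traces can be
classified as added tracer particles vs. biological material by
colocalization with an independent fluorescence channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PolarizabilityCalibration",
    "axial_position",
    "reference_polarizability",
    "polarizability_from_logscale",
    "classify_by_fluorescence",
]

#: apparent-depth correction for an oil objective imaging into water
OIL_WATER_CORRECTION = 1.128


@dataclass(frozen=True)
class PolarizabilityCalibration:
    """Anchors the (gauge-free) log-scale channel to absolute polarizability:
    a reference log-scale reading paired with the known polarizability
    (um^3) of the calibration population."""

    reference_logscale: float
    reference_polarizability: float
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if self.reference_polarizability <= 0:
            raise ValueError("reference polarizability must be positive")


def axial_position(z, correction: float = 1.0):
    """Correct a measured axial position for refractive-index mismatch.

    The apparent depth under an oil-immersion objective observing into an
    aqueous medium is compressed; multiplying by ``n_oil / n_medium``
    (1.128 for standard immersion oil and water) restores the physical
    position.  Linear, so applicable to scalars or arrays.
    """
    return np.multiply(z, correction)


def reference_polarizability(radius: float, n_p: float, n_m: float) -> float:
    """Clausius-Mossotti (real) polarizability of a homogeneous sphere.

        alpha = 3 V (n_p^2 - n_m^2) / (n_p^2 + 2 n_m^2),   V = 4/3 pi r^3

    ``radius`` in um, result in um^3.  Index-matched particles legitimately
    return zero.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_p < 1 or n_m < 1:
        raise ValueError("refractive indices must be >= 1")
    volume = 4.0 / 3.0 * np.pi * radius**3
    return 3.0 * volume * (n_p**2 - n_m**2) / (n_p**2 + 2.0 * n_m**2)


def polarizability_from_logscale(logscale, cal: PolarizabilityCalibration):
    """Convert log-scale channel readings to polarizability (um^3).

    The scale channel is equivariant only to *relative* signal scale, so
    ``alpha = alpha_ref * exp(logscale - logscale_ref)``.  Accepts scalars or
    arrays; per-trace values are conventionally the unweighted mean over the
    trace's detections.
    """
    return cal.reference_polarizability * np.exp(np.asarray(logscale, dtype=float) - cal.reference_logscale)


def classify_by_fluorescence(
    traces: pd.DataFrame,
    fluo_detections: pd.DataFrame,
    radius: float,
    hi_frac: float = 0.95,
    lo_frac: float = 0.05,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Label traces by colocalization with fluorescence detections.

    A detection is flagged colocalized if a fluorescence detection in the
    same frame lies within ``radius`` (length units; positions are px times
    ``pixel_size``).  A trace with flagged fraction > ``hi_frac`` is labelled
    ``'particle'``, below ``lo_frac`` ``'biological'``, otherwise
    ``'unlabelled'``.  Returns the trace table with ``colocalized`` and
    ``label`` columns added.
    """
    out = traces.copy()
    out["colocalized"] = False
    for frame, group in out.groupby("frame"):
        fl = fluo_detections[fluo_detections["frame"] == frame]
        if len(fl) == 0:
            continue
        fpos = fl[["x", "y"]].to_numpy(float) * pixel_size
        tpos = group[["x", "y"]].to_numpy(float) * pixel_size
        dist = np.linalg.norm(tpos[:, None, :] - fpos[None, :, :], axis=-1)
        out.loc[group.index, "colocalized"] = dist.min(axis=1) <= radius
    frac = out.groupby("trace_id")["colocalized"].mean()
    label = pd.Series("unlabelled", index=frac.index, dtype=object)
    label[frac > hi_frac] = "particle"
    label[frac < lo_frac] = "biological"
    out["label"] = out["trace_id"].map(label)
    return out
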