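"""Cramer-Rao lower bound on localization error under Poisson noise.

For a detector with expected photon counts ``nu(theta)`` per pixel and pure
shot noise, the Fisher information is

    I(theta) = sum_k (d nu_k / d theta)^T (d nu_k / d theta) / nu_k

with ``theta = (x, y, orientation)``.  Derivatives are central finite
differences of the anti-aliased (supersampled, box-integrated) rendering, so
``nu`` is a smooth function of sub-pixel position.  The bound on the
localization RMSE is ``sqrt((dx^2 + dy^2)/2)`` with the per-parameter
variances read off the diagonal of the inverse information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import GridSpec, ShapeSpec, render_shape

__all__ = ["FisherSetup", "fisher_information", "rmse_bound", "shape_crlb"]

#: shape kinds whose image is rotation invariant, making orientation
#: unidentifiable (its Fisher block is singular by construction)
ROTATIONALLY_SYMMETRIC = frozenset({"point", "sphere", "annulus"})


@dataclass(frozen=True)
class FisherSetup:
    """Numerical configuration for the Fisher-information evaluation:
    rendering oversampling factor, position finite-difference step (one
    fine-grid px by default) and orientation step in rad."""

    oversample: int = 10
    step_xy: float | None = None
    step_angle: float = 1e-2
    include_orientation: bool = True

    def __post_init__(self) -> None:
        if self.oversample < 2:
            raise ValueError("oversampling factor must be >= 2")
        if self.step_xy is not None and self.step_xy <= 0:
            raise ValueError("finite-difference step must be positive")

    @property
    def position_step(self) -> float:
        return 1.0 / self.oversample if self.step_xy is None else self.step_xy


def fisher_information(render, theta, setup: FisherSetup = FisherSetup()) -> np.ndarray:
    """Fisher information matrix by central differences.

    ``render(theta)`` must return the expected detector image for parameter
    vector ``theta = (x, y[, orientation])``; all entries must be strictly
    positive.  The returned matrix is symmetric positive semi-definite.
    """
    theta = np.asarray(theta, dtype=float)
    nu = np.asarray(render(theta), dtype=float)
    if np.any(nu <= 0):
        raise ValueError("expected image must be strictly positive")
    steps = [setup.position_step, setup.position_step, setup.step_angle][: len(theta)]
    derivs = []
    for i, step in enumerate(steps):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        derivs.append((np.asarray(render(tp)) - np.asarray(render(tm))) / (2.0 * step))
    n = len(derivs)
    info = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            info[i, j] = info[j, i] = float((derivs[i] * derivs[j] / nu).sum())
    return info


def rmse_bound(info: np.ndarray) -> float:
    """Localization RMSE bound ``sqrt((var_x + var_y)/2)`` from a Fisher matrix."""
    info = np.asarray(info, dtype=float)
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        # identify which diagonal direction carries (almost) no information
        names = ["x", "y", "orientation"][: info.shape[0]]
        worst = names[int(np.argmin(np.diag(info)))]
        raise np.linalg.LinAlgError(
            f"singular Fisher information: parameter {worst!r} is unidentifiable; "
            "drop it (e.g. orientation of a rotationally symmetric shape)"
        )
    cov = np.linalg.inv(info)
    return float(np.sqrt((cov[0, 0] + cov[1, 1]) / 2.0))


def shape_crlb(
    spec: ShapeSpec,
    snr: float,
    grid: GridSpec = GridSpec(),
    position=None,
    orientation: float = 0.0,
    setup: FisherSetup = FisherSetup(),
) -> float:
    """CRLB (px) for localizing one rendered shape at a given SNR.

    The shape amplitude is set from the SNR convention
    ``amplitude = snr * sqrt(background)``.  For rotationally symmetric
    shapes the orientation parameter is dropped from ``theta`` (it carries
    no information and would make the matrix singular); for all others it is
    included and its uncertainty is marginalized by the matrix inverse.
    """
    if position is None:
        position = ((grid.height - 1) / 2.0, (grid.width - 1) / 2.0)
    amp = snr * np.sqrt(spec.background)
    spec = replace(spec, amplitude=amp)
    with_angle = setup.include_orientation and spec.kind not in ROTATIONALLY_SYMMETRIC

    def render(theta):
        ang = theta[2] if len(theta) > 2 else orientation
        return render_shape(spec, theta[:2], ang, grid, setup.oversample)

    theta = [*position, orientation] if with_angle else list(position)
    return rmse_bound(fisher_information(render, theta, setup))
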