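"""Synthetic microscopy imagery with exact ground truth.

Everything the rest of the package is validated against is generated here:
noiseless expected-intensity images of simple object shapes, shot-noise
corrupted observations, multi-particle scenes, and weak-scatterer complex
holograms with additive complex Gaussian noise.

Coordinate convention
---------------------
Positions are 0-based ``(x, y)`` pixel coordinates where ``x`` runs along the
first (row) axis and ``y`` along the second (column) axis, measured from the
center of the top-left pixel.  Orientation angles are counter-clockwise about
the shape center, in radians.

Rendering is anti-aliased: shapes are evaluated analytically on a grid
supersampled by an integer factor (default 10) and box-integrated down to
detector pixels, so that expected images are smooth functions of sub-pixel
position.  This also makes finite-difference Fisher-information calculations
well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridSpec",
    "ShapeSpec",
    "SceneTruth",
    "OpticalConfig",
    "ComplexField",
    "SHAPE_KINDS",
    "default_shape",
    "render_shape",
    "corrupt_with_noise",
    "render_scene",
    "simulate_hologram",
    "propagate_field",
    "rescale_scatter",
    "simulate_brownian_trace",
]


@dataclass(frozen=True)
class GridSpec:
    """Detector pixel grid: ``height x width`` pixels of ``pixel_size`` length units."""

    height: int = 64
    width: int = 64
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("grid must be at least 16x16 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


SHAPE_KINDS = ("point", "sphere", "annulus", "ellipse", "crescent")


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry and photometry of one simulated object.

    ``amplitude`` is the peak expected photon count above background of the
    noiseless profile (profile is normalized to unit peak on the fine grid);
    ``background`` is the uniform expected background level, which must be
    positive so the Poisson model is well defined everywhere.
    """

    kind: str = "point"
    psf_sigma: float = 2.0
    radius: float = 6.0
    inner_radius: float = 4.0
    outer_radius: float = 7.0
    semi_axes: tuple[float, float] = (8.0, 4.0)
    cut_radius: float = 5.0
    cut_offset: float = 3.0
    amplitude: float = 100.0
    background: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {SHAPE_KINDS}")
        if self.background <= 0:
            raise ValueError("background must be > 0 (Poisson noise must be well-defined)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for name in ("psf_sigma", "radius", "inner_radius", "outer_radius", "cut_radius", "cut_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be > 0")

    def extent(self) -> float:
        """Rough object radius in px, used for bounds checks."""
        if self.kind == "point":
            return 4.0 * self.psf_sigma
        if self.kind == "sphere":
            return self.radius + 4.0 * self.psf_sigma
        if self.kind == "annulus":
            return self.outer_radius + 4.0 * self.psf_sigma
        if self.kind == "ellipse":
            return max(self.semi_axes) + 4.0 * self.psf_sigma
        return self.outer_radius + 4.0 * self.psf_sigma  # crescent


def default_shape(kind: str, **overrides) -> ShapeSpec:
    """The default geometry for each shape family (all lengths in px)."""
    defaults = {
        "point": dict(psf_sigma=2.0),
        "sphere": dict(radius=6.0, psf_sigma=1.0),
        "annulus": dict(inner_radius=4.0, outer_radius=7.0, psf_sigma=1.0),
        "ellipse": dict(semi_axes=(8.0, 4.0), psf_sigma=1.0),
        "crescent": dict(outer_radius=7.0, cut_radius=5.0, cut_offset=3.0, psf_sigma=1.0),
    }
    kw = dict(defaults[kind])
    kw.update(overrides)
    return ShapeSpec(kind=kind, **kw)


@dataclass
class SceneTruth:
    """Ground-truth particle table. One row per particle.

    Columns: x, y (px), orientation (rad), and optionally z (um), scale
    (signal-scale factor), radius (um) and refractive_index.
    """

    table: pd.DataFrame

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "SceneTruth":
        df = pd.DataFrame.from_records(records)
        for col, default in (("orientation", 0.0), ("z", 0.0), ("scale", 1.0)):
            if col not in df.columns:
                df[col] = default
        return cls(df)

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)


@dataclass(frozen=True)
class OpticalConfig:
    """Holographic imaging configuration.

    Defaults follow a HeNe off-axis holography setup: 633 nm illumination,
    NA 1.3 oil objective, 114 nm effective pixel, aqueous medium.
    All lengths in microns.
    """

    wavelength: float = 0.633
    numerical_aperture: float = 1.3
    n_medium: float = 1.33
    n_oil: float = 1.5
    pixel_size: float = 0.114

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.numerical_aperture <= 0:
            raise ValueError("numerical aperture must be positive")

    @property
    def k_medium(self) -> float:
        return 2.0 * np.pi * self.n_medium / self.wavelength


@dataclass
class ComplexField:
    """A complex scalar field sampled on a pixel grid, stored as two planes.

    ``background`` is the nominal unscattered field (1+0j for a normalized
    hologram, 0 for background-suppressed modulated recordings);
    ``sigma`` is the per-plane noise standard deviation actually applied.
    """

    real: np.ndarray
    imag: np.ndarray
    background: complex = 1.0 + 0.0j
    sigma: float = 0.0
    pixel_size: float = 0.114

    def __post_init__(self) -> None:
        if self.real.shape != self.imag.shape:
            raise ValueError("real and imaginary planes must share dimensions")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @classmethod
    def from_complex(cls, z: np.ndarray, **kw) -> "ComplexField":
        return cls(np.ascontiguousarray(z.real), np.ascontiguousarray(z.imag), **kw)

    def planes(self) -> np.ndarray:
        """(H, W, 2) array of background-referenced planes fed to the network."""
        return np.stack([self.real - self.background.real, self.imag - self.background.imag], axis=-1)


# ---------------------------------------------------------------------------
# intensity shapes
# ---------------------------------------------------------------------------

def _fine_coords(grid: GridSpec, oversample: int) -> tuple[np.ndarray, np.ndarray]:
    # fine-pixel centers; detector pixel p covers [p-0.5, p+0.5]
    n = oversample
    u = (np.arange(grid.height * n) + 0.5) / n - 0.5
    v = (np.arange(grid.width * n) + 0.5) / n - 0.5
    return u[:, None], v[None, :]


def _edge(dist: np.ndarray, h: float) -> np.ndarray:
    """Anti-aliased step: 0 -> 1 linear ramp over one fine pixel around the edge."""
    return np.clip(dist / h + 0.5, 0.0, 1.0)


def _indicator(spec: ShapeSpec, a: np.ndarray, b: np.ndarray, h: float) -> np.ndarray:
    """Shape indicator in the shape frame (a along the orientation axis),
    with edges anti-aliased over the fine-pixel scale ``h`` so integrated
    area is smooth in sub-pixel position."""
    if spec.kind == "sphere":
        return _edge(spec.radius - np.hypot(a, b), h)
    if spec.kind == "annulus":
        rho = np.hypot(a, b)
        return _edge(spec.outer_radius - rho, h) * _edge(rho - spec.inner_radius, h)
    if spec.kind == "ellipse":
        sa, sb = spec.semi_axes
        f = np.sqrt((a / sa) ** 2 + (b / sb) ** 2)
        grad = np.sqrt(a**2 / sa**4 + b**2 / sb**4)
        dist = np.where(grad > 0, (1.0 - f) * f / np.maximum(grad, 1e-12), sa)
        return _edge(dist, h)
    if spec.kind == "crescent":
        rho = np.hypot(a, b)
        cut = np.hypot(a - spec.cut_offset, b)
        return _edge(spec.outer_radius - rho, h) * _edge(cut - spec.cut_radius, h)
    raise ValueError(spec.kind)  # pragma: no cover - guarded by ShapeSpec


@lru_cache(maxsize=64)
def _canonical_peak(spec: ShapeSpec, oversample: int) -> float:
    """Peak of the smoothed unit-indicator profile, computed once per spec in
    the shape frame so normalization is independent of sub-pixel position and
    orientation (keeps integrated flux translation invariant)."""
    half = spec.extent() + 2.0
    n = int(np.ceil(2 * half * oversample))
    u = (np.arange(n) + 0.5) / oversample - half
    a = u[:, None] + 0.0 * u[None, :]
    b = u[None, :] + 0.0 * u[:, None]
    ind = _indicator(spec, a, b, 1.0 / oversample)
    prof = gaussian_filter(ind, sigma=spec.psf_sigma * oversample, mode="constant")
    peak = float(prof.max())
    if peak <= 0:
        raise ValueError("shape renders to nothing")
    return peak


def _profile_fine(spec: ShapeSpec, position, orientation: float, grid: GridSpec, oversample: int) -> np.ndarray:
    """Unit-peak shape profile on the supersampled grid."""
    u, v = _fine_coords(grid, oversample)
    du = u - position[0]
    dv = v - position[1]
    c, s = np.cos(orientation), np.sin(orientation)
    # rotate into the shape frame (counter-clockwise orientation of the shape)
    a = c * du + s * dv
    b = -s * du + c * dv

    if spec.kind == "point":
        return np.exp(-(a**2 + b**2) / (2.0 * spec.psf_sigma**2))  # unit peak, smooth
    ind = _indicator(spec, a, b, 1.0 / oversample)
    prof = gaussian_filter(ind, sigma=spec.psf_sigma * oversample, mode="constant")
    return prof / _canonical_peak(spec, oversample)


def render_shape(
    spec: ShapeSpec,
    position: Sequence[float],
    orientation: float = 0.0,
    grid: GridSpec = GridSpec(),
    oversample: int = 10,
) -> np.ndarray:
    """Noiseless expected photon counts for one object.

    Returns a strictly positive (background included) ``height x width``
    float image.  The shape profile is normalized to unit peak on the fine
    grid, so ``background + amplitude`` is the peak expected signal.
    """
    x, y = float(position[0]), float(position[1])
    if not (0 <= x <= grid.height - 1 and 0 <= y <= grid.width - 1):
        raise ValueError(f"position {position} outside the grid")
    if 2 * spec.extent() > min(grid.height, grid.width):
        raise ValueError("shape larger than the grid")
    prof = _profile_fine(spec, (x, y), orientation, grid, oversample)
    fine = spec.background + spec.amplitude * prof
    h, w = grid.height, grid.width
    nu = fine.reshape(h, oversample, w, oversample).mean(axis=(1, 3))
    return nu


def corrupt_with_noise(
    nu: np.ndarray,
    snr: float,
    rng: np.random.Generator,
    background: float | None = None,
) -> np.ndarray:
    """Shot-noise corrupted observation at a target SNR.

    The expected image is rescaled about the background so that
    ``(peak - background) / sqrt(background) = snr`` and then one Poisson
    sample is drawn per pixel.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("expected intensity must be strictly positive")
    if snr <= 0:
        raise ValueError("snr must be positive")
    bg = float(nu.min()) if background is None else float(background)
    peak = float(nu.max())
    if peak <= bg:
        raise ValueError("image has no signal above background")
    scale = snr * np.sqrt(bg) / (peak - bg)
    expected = bg + (nu - bg) * scale
    return rng.poisson(expected).astype(float)


def render_scene(
    truth: SceneTruth,
    specs: Sequence[ShapeSpec] | ShapeSpec,
    grid: GridSpec = GridSpec(),
    snr: float | None = 10.0,
    rng: np.random.Generator | None = None,
    oversample: int = 10,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a multi-particle scene over one shared background.

    Expected intensities of all particles add above a single background
    (taken from the first spec) before noise is applied.  With ``snr=None``
    the noiseless expected image is returned.
    """
    if len(truth) == 0:
        raise ValueError("scene must contain at least one particle")
    if isinstance(specs, ShapeSpec):
        specs = [specs] * len(truth)
    if len(specs) != len(truth):
        raise ValueError("one ShapeSpec per particle required")
    bg = specs[0].background
    nu = np.full((grid.height, grid.width), bg, dtype=float)
    for (_, row), spec in zip(truth.table.iterrows(), specs):
        single = render_shape(
            replace(spec, background=bg),
            (row["x"], row["y"]),
            float(row.get("orientation", 0.0)),
            grid,
            oversample,
        )
        nu += (single - bg) * float(row.get("scale", 1.0))
    if snr is None:
        return nu, truth
    if rng is None:
        raise ValueError("rng required when snr is given")
    return corrupt_with_noise(nu, snr, rng, background=bg), truth


# ---------------------------------------------------------------------------
# weak-scatterer holography
# ---------------------------------------------------------------------------

def _freq_grids(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    qx = 2 * np.pi * np.fft.fftfreq(shape[0], d=pixel_size)
    qy = 2 * np.pi * np.fft.fftfreq(shape[1], d=pixel_size)
    return qx[:, None], qy[None, :]


def _propagation_phase(shape, dz: float, optics: OpticalConfig) -> np.ndarray:
    """Carrier-referenced angular-spectrum phase factor for distance dz (um)."""
    qx, qy = _freq_grids(shape, optics.pixel_size)
    q2 = qx**2 + qy**2
    k = optics.k_medium
    kz2 = k**2 - q2
    prop = kz2 > 0
    kz = np.sqrt(np.where(prop, kz2, 0.0))
    # reference to the carrier so a plane-wave background is invariant
    phase = np.where(prop, np.exp(1j * dz * (kz - k)), 0.0 + 0.0j)
    return phase


def propagate_field(fld: ComplexField, dz: float, optics: OpticalConfig) -> ComplexField:
    """Numerically refocus a field by ``dz`` (um) with the angular-spectrum method.

    Evanescent components are suppressed; the phase is referenced to the
    carrier so the plane-wave background is unchanged.  Energy of the
    propagating band is conserved, and propagation by ``+dz`` then ``-dz``
    is the identity on that band.
    """
    z = fld.values
    spec = np.fft.fft2(z)
    out = np.fft.ifft2(spec * _propagation_phase(z.shape, dz, optics))
    return ComplexField.from_complex(
        out, background=fld.background, sigma=fld.sigma, pixel_size=fld.pixel_size
    )


def rescale_scatter(fld: ComplexField, s: float) -> ComplexField:
    """Scale the scattered part of the field by ``s``, leaving the background fixed."""
    if s <= 0:
        raise ValueError("scale factor must be positive")
    bg = fld.background
    z = bg + s * (fld.values - bg)
    return ComplexField.from_complex(z, background=bg, sigma=fld.sigma, pixel_size=fld.pixel_size)


# scattered-field amplitude per unit polarizability (1/um^3); arbitrary but
# fixed gauge relating the Clausius-Mossotti polarizability to the hologram
# contrast of the weak-scatterer model.
SCATTER_PER_POLARIZABILITY = 16.0


def _point_response(shape, position, dz: float, optics: OpticalConfig) -> np.ndarray:
    """Diffraction-limited complex point response, unit peak at focus."""
    qx, qy = _freq_grids(shape, optics.pixel_size)
    q2 = qx**2 + qy**2
    q_na = 2 * np.pi * optics.numerical_aperture / optics.wavelength
    pupil = (q2 <= q_na**2).astype(complex)
    # in-plane shift (positions in px -> physical length)
    px = optics.pixel_size
    shift = np.exp(-1j * (qx * position[0] * px + qy * position[1] * px))
    spec = pupil * shift * _propagation_phase(shape, dz, optics)
    psf = np.fft.ifft2(spec)
    # normalize so an in-focus centered response has unit peak magnitude
    norm = np.fft.ifft2(pupil)[0, 0].real
    return psf / norm


def simulate_hologram(
    truth: SceneTruth,
    optics: OpticalConfig = OpticalConfig(),
    snr: float | None = 20.0,
    rng: np.random.Generator | None = None,
    grid: GridSpec = GridSpec(64, 64, 0.114),
    background: complex = 1.0 + 0.0j,
) -> tuple[ComplexField, SceneTruth]:
    """Weak-scatterer hologram of sub-wavelength spheres.

    The field is ``background + sum_p s_p * i * a(r - r_p; z_p)`` where ``a``
    is the diffraction-limited complex point response refocused to the
    particle's axial position ``z_p`` and ``s_p`` is proportional to the
    particle's Clausius-Mossotti polarizability (times any per-particle
    ``scale`` factor in the truth table).  Additive complex Gaussian noise is
    scaled so that ``max|I| / sqrt(sigma_Re^2 + sigma_Im^2) = snr``.
    """
    if optics.numerical_aperture >= optics.n_medium:
        raise ValueError("numerical aperture must be below the medium index")
    from .holography import reference_polarizability  # local to avoid cycle

    shape = (grid.height, grid.width)
    z = np.full(shape, complex(background))
    for _, row in truth.table.iterrows():
        if "radius" in truth.table.columns and np.isfinite(row.get("radius", np.nan)):
            alpha = reference_polarizability(
                float(row["radius"]), float(row["refractive_index"]), optics.n_medium
            )
            s_p = SCATTER_PER_POLARIZABILITY * alpha
        else:
            s_p = 0.2
        s_p *= float(row.get("scale", 1.0))
        dz = float(row.get("z", 0.0))
        if abs(dz) > 10.0:
            raise ValueError("particle z must be within +-10 um of focus")
        resp = _point_response(shape, (row["x"], row["y"]), dz, optics)
        z = z + s_p * 1j * resp
    sigma = 0.0
    if snr is not None:
        if rng is None:
            raise ValueError("rng required when snr is given")
        sigma = float(np.abs(z).max()) / (snr * np.sqrt(2.0))
        z = z + rng.normal(0.0, sigma, shape) + 1j * rng.normal(0.0, sigma, shape)
    return (
        ComplexField.from_complex(z, background=complex(background), sigma=sigma, pixel_size=optics.pixel_size),
        truth,
    )


# ---------------------------------------------------------------------------
# Brownian traces (for diffusion-estimator validation)
# ---------------------------------------------------------------------------

def simulate_brownian_trace(
    d_coeff: float,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    n_dim: int = 1,
    loc_noise: float = 0.0,
) -> np.ndarray:
    """Positions (um) of a Brownian walk with diffusion ``d_coeff`` (um^2/s)."""
    steps = rng.normal(0.0, np.sqrt(2.0 * d_coeff * dt), size=(n_steps, n_dim))
    pos = np.cumsum(steps, axis=0)
    if loc_noise > 0:
        pos = pos + rng.normal(0.0, loc_noise, size=pos.shape)
    return pos
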