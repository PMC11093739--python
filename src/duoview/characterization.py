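"""Optical characterization: Gaussian profile fits, beam and PSF metrics.

The light-sheet waist, Rayleigh length and effective NA are derived from a
Gaussian fit ``f(x) = a + b exp(-(x - mu)^2 / (2 sigma^2))`` to measured
intensity line profiles; bead stacks yield lateral/axial PSF FWHMs from the
same fit applied to line profiles through each bead.

Conventions: the beam waist ``w0`` is the 1/e^2 intensity radius, so
``w0 = 2 sigma`` of the intensity profile; ``FWHM = 2 sigma sqrt(2 ln 2)``;
``NA_eff = n lambda / (pi w0)``; ``z_r = pi w0^2 n / lambda``.  All lengths
in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .errors import ConvergenceError, EmptyResultError, ValidationError
from .stack import VolumeStack

#: FWHM of a Gaussian per unit standard deviation.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class GaussianFit:
    """Least-squares parameters of ``a + b exp(-(x-mu)^2 / (2 sigma^2))``."""

    a: float
    b: float
    mu: float
    sigma: float
    rss: float

    @property
    def fwhm(self) -> float:
        return fwhm_from_sigma(self.sigma)


@dataclass
class BeamMeasurement:
    """Gaussian-beam summary derived from a waist-profile fit."""

    w0: float
    z_r: float
    na_eff: float
    n: float
    wavelength: float

    def __post_init__(self) -> None:
        for name in ("w0", "z_r", "na_eff", "n", "wavelength"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not self.na_eff < self.n:
            raise ValidationError("NA_eff must be below the refractive index")


@dataclass
class PSFMeasurement:
    """Bead-averaged lateral/axial FWHM of the detection PSF."""

    fwhm_lateral: float
    fwhm_axial: float
    n_beads: int
    depth: float = 0.0


def _gauss(x, a, b, mu, sigma):
    return a + b * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(xs: np.ndarray, ys: np.ndarray) -> GaussianFit:
    """Fit ``a + b exp(-(x-mu)^2/(2 sigma^2))`` to a line profile.

    Initialised from moments (offset from the minimum, mean from the argmax,
    width from the second moment of the offset-subtracted profile); ``sigma``
    is constrained positive.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("xs and ys must be equal-length 1D arrays")
    if xs.size < 5:
        raise ValidationError(f"need at least 5 samples, got {xs.size}")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValidationError("profile contains non-finite values")
    if np.ptp(ys) == 0:
        raise ValidationError("constant profile: Gaussian fit is degenerate")

    a0 = float(ys.min())
    b0 = float(ys.max() - ys.min())
    mu0 = float(xs[np.argmax(ys)])
    weights = np.clip(ys - a0, 0, None)
    wsum = weights.sum()
    if wsum > 0:
        var = float(np.sum(weights * (xs - mu0) ** 2) / wsum)
        sigma0 = math.sqrt(var) if var > 0 else float(np.ptp(xs)) / 10
    else:  # pragma: no cover - ptp check above keeps wsum > 0
        sigma0 = float(np.ptp(xs)) / 10
    sigma0 = max(sigma0, 1e-6)

    try:
        popt, _ = curve_fit(
            _gauss,
            xs,
            ys,
            p0=(a0, b0, mu0, sigma0),
            bounds=([-np.inf, 0, -np.inf, 1e-12], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except RuntimeError as exc:
        rss = float(np.sum((ys - _gauss(xs, a0, b0, mu0, sigma0)) ** 2))
        raise ConvergenceError(
            f"Gaussian fit did not converge (initial rss {rss:.3g})"
        ) from exc
    a, b, mu, sigma = popt
    sigma = abs(float(sigma))
    rss = float(np.sum((ys - _gauss(xs, a, b, mu, sigma)) ** 2))
    return GaussianFit(a=float(a), b=float(b), mu=float(mu), sigma=sigma, rss=rss)


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: ``2 sigma sqrt(2 ln 2)``."""
    if not sigma > 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    return FWHM_FACTOR * sigma


def beam_waist_from_sigma(sigma_intensity: float) -> float:
    """1/e^2 beam radius of a Gaussian beam with intensity stdev ``sigma``."""
    if not sigma_intensity > 0:
        raise ValidationError(f"sigma must be > 0, got {sigma_intensity}")
    return 2.0 * sigma_intensity


def effective_na(n: float, wavelength: float, w0: float) -> float:
    """Effective numerical aperture ``n lambda / (pi w0)`` of the beam."""
    if not (n > 0 and wavelength > 0 and w0 > 0):
        raise ValidationError("n, wavelength and w0 must all be positive")
    return n * wavelength / (math.pi * w0)


def rayleigh_length(w0: float, n: float, wavelength: float) -> float:
    """Rayleigh length ``pi w0^2 n / lambda`` of a Gaussian beam."""
    if not (n > 0 and wavelength > 0 and w0 > 0):
        raise ValidationError("w0, n and wavelength must all be positive")
    return math.pi * w0**2 * n / wavelength


def beam_width(z: np.ndarray, w0: float, z0: float, z_r: float) -> np.ndarray:
    """Gaussian-beam width ``w(z) = w0 sqrt(1 + ((z - z0)/z_r)^2)``."""
    z = np.asarray(z, dtype=float)
    return w0 * np.sqrt(1.0 + ((z - z0) / z_r) ** 2)


def fit_beam_profile(
    zs: np.ndarray, widths: np.ndarray, n: float = 1.33, wavelength: float = 0.488
) -> BeamMeasurement:
    """Fit measured per-z beam widths to recover waist and Rayleigh length.

    This is the empirical route to ``z_r`` (where the width reaches
    ``w0 sqrt(2)``); :func:`rayleigh_length` is the closed-form alternative
    from ``w0`` alone.
    """
    zs = np.asarray(zs, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if zs.size < 5:
        raise ValidationError("need at least 5 width samples")
    w0_0 = float(widths.min())
    z0_0 = float(zs[np.argmin(widths)])
    zr_0 = max(float(np.ptp(zs)) / 4, 1e-6)
    popt, _ = curve_fit(beam_width, zs, widths, p0=(w0_0, z0_0, zr_0), maxfev=20000)
    w0, _, z_r = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    return BeamMeasurement(
        w0=w0,
        z_r=z_r,
        na_eff=effective_na(n, wavelength, w0),
        n=n,
        wavelength=wavelength,
    )


def field_of_view(n_pixels: int, pixel_spacing: float) -> float:
    """Side length of the camera field of view: ``n_pixels * pixel_spacing``."""
    if not n_pixels > 0:
        raise ValidationError(f"n_pixels must be > 0, got {n_pixels}")
    if not pixel_spacing > 0:
        raise ValidationError(f"pixel_spacing must be > 0, got {pixel_spacing}")
    return n_pixels * pixel_spacing


def _line_profile(data: np.ndarray, peak: tuple[int, int, int], axis: int, half: int):
    """Axis-aligned intensity profile through a voxel, clipped at borders."""
    idx = list(peak)
    n = data.shape[axis]
    lo, hi = max(0, peak[axis] - half), min(n, peak[axis] + half + 1)
    sl = [slice(p, p + 1) for p in peak]
    sl[axis] = slice(lo, hi)
    values = data[tuple(sl)].ravel()
    return np.arange(lo, hi, dtype=float), values


def measure_psf(
    stack: VolumeStack,
    threshold: float,
    *,
    exclusion_radius: int = 3,
    half_window: int = 8,
    depth: float = 0.0,
) -> PSFMeasurement:
    """Average lateral/axial FWHM over isolated beads in a bead-field stack.

    Local maxima above ``threshold`` are treated as bead candidates; beads
    within ``exclusion_radius`` voxels of each other or clipped by the stack
    border (within ``half_window`` along x or z) are discarded.  A line
    profile along x and along z through each remaining bead is fitted with
    :func:`fit_gaussian` and converted to FWHM in µm via the voxel spacing.
    """
    data = stack.data
    if data.max() <= threshold:
        raise EmptyResultError("no voxels above threshold: no beads detected")
    peaks = peak_local_max(
        data, min_distance=exclusion_radius, threshold_abs=threshold
    )
    if peaks.size == 0:
        raise EmptyResultError("no local maxima above threshold")

    # drop peaks closer than the exclusion radius to a brighter peak
    # (peak_local_max enforces min_distance per axis; recheck euclidean)
    keep = []
    dropped_overlap = 0
    for i, p in enumerate(peaks):
        d = np.linalg.norm((peaks - p), axis=1)
        close = (d > 0) & (d < exclusion_radius)
        if np.any(close & (np.arange(len(peaks)) < i)):
            dropped_overlap += 1
            continue
        keep.append(p)

    sz, sy, sx = stack.spacing
    fwhm_lat, fwhm_ax = [], []
    for p in keep:
        z, y, x = (int(v) for v in p)
        if not (
            half_window <= z < data.shape[0] - half_window
            and half_window <= x < data.shape[2] - half_window
        ):
            continue  # clipped by the border
        try:
            xs, ys = _line_profile(data, (z, y, x), axis=2, half=half_window)
            lat = fit_gaussian(xs * sx, ys)
            xs, ys = _line_profile(data, (z, y, x), axis=0, half=half_window)
            ax = fit_gaussian(xs * sz, ys)
        except (ValidationError, ConvergenceError):
            continue
        fwhm_lat.append(lat.fwhm)
        fwhm_ax.append(ax.fwhm)

    if not fwhm_lat:
        raise EmptyResultError("no bead profile could be fitted")
    return PSFMeasurement(
        fwhm_lateral=float(np.mean(fwhm_lat)),
        fwhm_axial=float(np.mean(fwhm_ax)),
        n_beads=len(fwhm_lat),
        depth=depth,
    )
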